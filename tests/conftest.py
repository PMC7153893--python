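import numpy as np
import pandas as pd
import pytest

from befish.cohort import (SET1, SET2, CellRecord, CellState, ClinicalRecord,
                           Cohort, OutcomeRecord)
from befish.simulate import SimulationParams, generate_cohort


def make_states(panel, state_rows, patient_id="P1"):
    """CellState list from rows of per-probe state strings (panel order)."""
    return [
        CellState(patient_id, panel.panel_id, i + 1,
                  dict(zip(panel.probes, row)))
        for i, row in enumerate(state_rows)
    ]


def toy_cohort(n_cells=50):
    """Two-patient cohort with both panels, all-normal cells, one progressor."""
    cells = []
    for pid in ("P1", "P2"):
        for panel in (SET1, SET2):
            for i in range(n_cells):
                cells.append(CellRecord(pid, panel.panel_id, i + 1,
                                        {p: 2 for p in panel.probes}))
    clinical = [
        ClinicalRecord("P1", 55.0, "M", 2.0, 4.0, 26.0,
                       "never", True, "community", "none"),
        ClinicalRecord("P2", 70.0, "M", 6.0, 8.0, 30.0,
                       "current_or_former", True, "academic", "none"),
    ]
    outcomes = [
        OutcomeRecord("P1", 90.0, False, "none"),
        OutcomeRecord("P2", 30.0, True, "HGD"),
    ]
    return Cohort(cells=cells, clinical=clinical, outcomes=outcomes)


@pytest.fixture(scope="session")
def synthetic_cohort():
    """One default synthetic cohort, shared across tests (seed 101)."""
    return generate_cohort(SimulationParams(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller synthetic cohort for LOO / pipeline tests (seed 7)."""
    params = SimulationParams(n_patients=90, seed=7,
                              target_event_fraction=0.2)
    return generate_cohort(params)


def survival_frame(n, rng, beta=0.0):
    """Simple exponential survival data with one standard-normal covariate."""
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(beta * x))
    c = rng.exponential(1.5, size=n)
    return pd.DataFrame({
        "x": x,
        "followup_months": np.minimum(t, c),
        "progressed": t <= c,
    }, index=[f"S{i}" for i in range(n)])
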