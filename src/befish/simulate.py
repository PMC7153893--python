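"""Synthetic surveillance cohorts with known ground truth.

Emulates a multi-center non-dysplastic Barrett's esophagus cohort as the
analysis expects it: per-cell FISH signal counts for two four-probe panels,
baseline clinical covariates, and prospectively observed progression to
HGD/EAC under censoring.  Defaults target the marginal structure of the
study cohort: 334 patients, >= 50 scored cells per panel, ~9.6%
progressors, median follow-up ~86.5 months.

Generative model, per patient:

1. latent clone structure per panel — K ~ 1 + Poisson(lambda) clones, the
   first being the diploid all-normal ancestor; each further clone draws a
   loss/normal/gain state per probe (aberration probability per probe,
   direction biased per probe); clone proportions ~ Dirichlet with the
   ancestral clone favored;
2. cells — a multinomial draw of cells over clones; a clone's signature
   maps deterministically to signal counts (normal=2, loss=1, gain=3);
3. clinical covariates matched to the reported cohort margins (age
   N(60,10) truncated >18, C-length a discretized Gamma with median ~2 cm,
   M = C + positive offset, BMI N(27.2,3.8), etc.);
4. survival — exponential event times with log-hazard
   beta_age*(age-60) + beta_c*(C-2) + beta_nc*(NC-0.04), where NC is the
   normalized clone score *measured* on the generated set-2 cells over all
   four probes; censoring is Uniform(53,120) months (median 86.5) capped
   administratively at 120.  The baseline rate is solved numerically so the
   expected progressor fraction equals the target (default 9.6%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .cohort import (SET1, SET2, CellRecord, ClinicalRecord, Cohort,
                     MarkerPanel, OutcomeRecord, write_cell_table,
                     write_clinical_table)

__all__ = ["SimulationParams", "CloneProfile", "generate_patient_cells",
           "generate_cohort", "write_cohort"]

STATE_TO_COUNT = {-1: 1, 0: 2, 1: 3}  # loss / normal / gain -> signal count

# probability that an aberration is a gain rather than a loss, per probe
DEFAULT_GAIN_BIAS = {
    "CDKN2A": 0.1, "TP53": 0.15, "ERBB2": 0.75, "CEP17": 0.65,
    "CEP7": 0.8, "20q": 0.8, "c-MYC": 0.8,
}


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the generator; defaults are the study conditions."""

    n_patients: int = 334
    cells_min: int = 50
    cells_max: int = 120
    # clone structure
    clone_mean_extra: float = 2.0          # K = 1 + Poisson(this)
    dirichlet_alpha_ancestor: float = 5.0
    dirichlet_alpha_other: float = 1.0
    aberration_prob: float = 0.15          # per probe, per non-ancestral clone
    # clinical margins
    age_mean: float = 60.0
    age_sd: float = 10.0
    age_min: float = 18.0
    c_gamma_shape: float = 1.1
    c_gamma_scale: float = 2.6
    m_offset_mean: float = 1.0             # m = c + 1 + Poisson(mean)
    bmi_mean: float = 27.2
    bmi_sd: float = 3.8
    male_p: float = 0.808
    smoking_p: float = 0.706
    ppi_p: float = 0.994
    community_p: float = 0.659
    # hazard
    beta_age: float = float(np.log(1.1))   # per year
    beta_c: float = float(np.log(1.1))     # per cm
    beta_nc: float = 120.0                 # per unit normalized clone score
    target_event_fraction: float = 0.096
    admin_censor_months: float = 120.0
    dropout_low_months: float = 53.0       # Uniform(low, admin): median 86.5
    eac_fraction: float = 0.5              # EAC vs HGD among progressors
    seed: int = 0


@dataclass(frozen=True)
class CloneProfile:
    """Latent clone structure of one patient for one panel."""

    panel_id: str
    proportions: np.ndarray                # (K,), sums to 1
    states: np.ndarray                     # (K, 4) ints in {-1, 0, +1}

    def __post_init__(self) -> None:
        if abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("clone proportions must sum to 1")


def _draw_clone_profile(rng: np.random.Generator, panel: MarkerPanel,
                        p: SimulationParams) -> CloneProfile:
    k = 1 + rng.poisson(p.clone_mean_extra)
    states = np.zeros((k, 4), dtype=int)
    for j in range(1, k):
        for i, probe in enumerate(panel.probes):
            if rng.random() < p.aberration_prob:
                gain = rng.random() < DEFAULT_GAIN_BIAS[probe]
                states[j, i] = 1 if gain else -1
    alpha = np.full(k, p.dirichlet_alpha_other)
    alpha[0] = p.dirichlet_alpha_ancestor
    props = rng.dirichlet(alpha)
    return CloneProfile(panel.panel_id, props, states)


def generate_patient_cells(profile: CloneProfile, n_cells: int,
                           seed: int | np.random.Generator,
                           patient_id: str = "P",
                           panel: MarkerPanel | None = None
                           ) -> list[CellRecord]:
    """Draw cells multinomially from a clone profile."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    panel = panel or (SET1 if profile.panel_id == "set1" else SET2)
    counts_per_clone = rng.multinomial(n_cells, profile.proportions)
    records: list[CellRecord] = []
    idx = 1
    for clone_states, m in zip(profile.states, counts_per_clone):
        sig = {probe: STATE_TO_COUNT[s]
               for probe, s in zip(panel.probes, clone_states)}
        for _ in range(m):
            records.append(CellRecord(patient_id, panel.panel_id, idx, sig))
            idx += 1
    return records


def _measured_nc(profile: CloneProfile, clone_cells: np.ndarray) -> float:
    """Normalized clone score actually observable in the drawn cells."""
    observed = clone_cells > 0
    # distinct *signatures*: clones with identical states collapse
    sigs = {tuple(s) for s, seen in zip(profile.states, observed) if seen}
    return len(sigs) / int(clone_cells.sum())


def generate_cohort(params: SimulationParams = SimulationParams()
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground-truth table, reproducibly.

    Returns ``(cohort, truth)`` where ``truth`` has one row per patient:
    the latent clone counts, the measured set-2 normalized clone score used
    in the hazard, the true linear predictor, and the uncensored event time.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    width = len(str(n))

    cells: list[CellRecord] = []
    clinical: list[ClinicalRecord] = []
    truth_rows: list[dict] = []
    lps = np.empty(n)
    ages = np.empty(n)
    c_lens = np.empty(n)
    ncs = np.empty(n)
    k1s = np.empty(n, int)
    k2s = np.empty(n, int)

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        age = float(np.clip(rng.normal(p.age_mean, p.age_sd), p.age_min, None))
        c_len = float(np.round(rng.gamma(p.c_gamma_shape, p.c_gamma_scale)))
        m_len = c_len + 1.0 + float(rng.poisson(p.m_offset_mean))
        bmi = float(rng.normal(p.bmi_mean, p.bmi_sd))
        sex = "M" if rng.random() < p.male_p else "F"
        smoking = ("current_or_former" if rng.random() < p.smoking_p
                   else "never")
        ppi = bool(rng.random() < p.ppi_p)
        hospital = "community" if rng.random() < p.community_p else "academic"
        clinical.append(ClinicalRecord(pid, age, sex, c_len, m_len, bmi,
                                       smoking, ppi, hospital, "none"))

        nc2 = 0.0
        for panel in (SET1, SET2):
            profile = _draw_clone_profile(rng, panel, p)
            n_cells = int(rng.integers(p.cells_min, p.cells_max + 1))
            clone_counts = rng.multinomial(n_cells, profile.proportions)
            idx = 1
            for clone_states, m in zip(profile.states, clone_counts):
                sig = {probe: STATE_TO_COUNT[s]
                       for probe, s in zip(panel.probes, clone_states)}
                for _ in range(m):
                    cells.append(CellRecord(pid, panel.panel_id, idx, sig))
                    idx += 1
            if panel is SET1:
                k1s[i] = profile.proportions.size
            else:
                k2s[i] = profile.proportions.size
                nc2 = _measured_nc(profile, clone_counts)

        ages[i], c_lens[i], ncs[i] = age, c_len, nc2
        lps[i] = (p.beta_age * (age - p.age_mean)
                  + p.beta_c * (c_len - 2.0)
                  + p.beta_nc * (nc2 - 0.04))

    censor = rng.uniform(p.dropout_low_months, p.admin_censor_months, size=n)
    theta = np.exp(lps)

    def expected_events(lam0: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam0 * theta * censor)))

    hi = 10.0
    if expected_events(hi) < p.target_event_fraction:
        raise RuntimeError(
            f"cannot calibrate baseline hazard: even rate {hi}/month yields "
            f"expected event fraction {expected_events(hi):.3f} < target "
            f"{p.target_event_fraction}")
    lam0 = brentq(lambda l: expected_events(l) - p.target_event_fraction,
                  1e-10, hi, xtol=1e-12)

    t_event = rng.exponential(1.0 / (lam0 * theta))
    progressed = t_event <= censor
    followup = np.where(progressed, t_event, censor)
    is_eac = rng.random(n) < p.eac_fraction

    outcomes = []
    for i, c in enumerate(clinical):
        ptype = ("EAC" if is_eac[i] else "HGD") if progressed[i] else "none"
        outcomes.append(OutcomeRecord(c.patient_id, float(followup[i]),
                                      bool(progressed[i]), ptype))
        truth_rows.append({
            "patient_id": c.patient_id, "age": ages[i], "c_length": c_lens[i],
            "nc_set2": ncs[i], "n_clones_set1": k1s[i],
            "n_clones_set2": k2s[i], "linear_predictor": lps[i],
            "event_time_true": t_event[i], "censor_time": censor[i],
            "baseline_rate": lam0,
        })

    cohort = Cohort(cells=cells, clinical=clinical, outcomes=outcomes)
    cohort.validate()
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    return cohort, truth


def write_cohort(cohort: Cohort, truth: pd.DataFrame, outdir: str | Path,
                 params: SimulationParams | None = None) -> dict[str, Path]:
    """Emit cells_set1/cells_set2/clinical/truth CSVs (+ params echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for panel in (SET1, SET2):
        recs = [r for r in cohort.cells if r.panel_id == panel.panel_id]
        path = outdir / f"cells_{panel.panel_id}.csv"
        write_cell_table(recs, path, panel)
        paths[f"cells_{panel.panel_id}"] = path
    paths["clinical"] = outdir / "clinical.csv"
    write_clinical_table(cohort.clinical, cohort.outcomes, paths["clinical"])
    paths["truth"] = outdir / "truth.csv"
    truth.to_csv(paths["truth"])
    if params is not None:
        paths["params"] = outdir / "params-echo.yaml"
        with open(paths["params"], "w") as fh:
            yaml.safe_dump(asdict(params), fh, sort_keys=True)
    return paths
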