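"""Clone definitions and clonal-diversity indices.

A *clone* is a distinct combination of per-probe states (loss / normal /
gain) over a chosen marker subset; the clone-size abundance of a patient is
the distribution of scored cells over those combinations.  Five diversity
indices summarize an abundance:

* Shannon index            S   = -sum_i p_i ln p_i  (nats)
* Simpson index            S'  =  sum_i p_i^2
* inverse Simpson          S_i = 1 / S'
* complement Simpson       S_c = 1 - S'
* normalized clone score   NC  = R / N

with p_i the proportion of cells in clone i, R the number of distinct
clones and N the number of cells scored.  The Shannon index is reported
with its conventional non-negative sign (-sum p ln p), even though it is
sometimes written without the leading minus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CellState, Cohort, MarkerPanel, state_frame

__all__ = [
    "CloneAbundance",
    "DiversityScores",
    "INDEX_NAMES",
    "clone_abundance",
    "abundance_from_counts",
    "diversity_indices",
    "marker_subsets",
    "diversity_matrix",
    "diversity_matrix_tidy",
]

INDEX_NAMES = ("shannon", "simpson", "inverse_simpson",
               "complement_simpson", "normalized_clone")


@dataclass(frozen=True)
class CloneAbundance:
    """Clone-size distribution of one patient over a marker subset."""

    marker_subset: tuple[str, ...]
    clone_counts: dict[tuple, int]
    N: int
    R: int
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.R != len(self.clone_counts) or self.R < 1:
            raise ValueError("R must equal the number of distinct clones (>= 1)")
        if sum(self.clone_counts.values()) != self.N:
            raise ValueError("clone counts must sum to N")
        if abs(float(self.p.sum()) - 1.0) > 1e-12 or (self.p <= 0).any():
            raise ValueError("proportions must be positive and sum to 1")


@dataclass(frozen=True)
class DiversityScores:
    shannon: float
    simpson: float
    inverse_simpson: float
    complement_simpson: float
    normalized_clone: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def clone_abundance(states: Sequence[CellState],
                    subset: Sequence[str]) -> CloneAbundance:
    """Tally cells into clones over ``subset``, ignoring all other probes.

    All states must belong to one patient and panel; cells identical on the
    subset share a clone.
    """
    if not states:
        raise ValueError("no cells to tally")
    subset = tuple(subset)
    if not subset:
        raise ValueError("marker subset is empty")
    panel_probes = set(states[0].states)
    unknown = [m for m in subset if m not in panel_probes]
    if unknown:
        raise ValueError(f"probes not in panel: {unknown}")
    counts: dict[tuple, int] = {}
    for s in states:
        sig = tuple(s.states[m] for m in subset)
        counts[sig] = counts.get(sig, 0) + 1
    return abundance_from_counts(counts, subset)


def abundance_from_counts(counts: dict[tuple, int],
                          subset: Sequence[str]) -> CloneAbundance:
    n = sum(counts.values())
    p = np.array(sorted(counts.values(), reverse=True), dtype=float) / n
    return CloneAbundance(tuple(subset), dict(counts), n, len(counts), p)


def diversity_indices(ab: CloneAbundance) -> DiversityScores:
    p = ab.p
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p ** 2).sum())
    return DiversityScores(
        shannon=shannon,
        simpson=simpson,
        inverse_simpson=1.0 / simpson,
        complement_simpson=1.0 - simpson,
        normalized_clone=ab.R / ab.N,
    )


def marker_subsets(panel: MarkerPanel,
                   k_range: Iterable[int] = (1, 2, 3, 4)) -> list[tuple[str, ...]]:
    """All marker subsets of sizes in ``k_range``, in combinatorial order."""
    out: list[tuple[str, ...]] = []
    for k in sorted(set(k_range)):
        if not 1 <= k <= len(panel.probes):
            raise ValueError(f"subset size {k} out of range for panel")
        out.extend(itertools.combinations(panel.probes, k))
    return out


def diversity_matrix(cohort: Cohort, panel: MarkerPanel,
                     indices: Sequence[str] = INDEX_NAMES,
                     k_range: Iterable[int] = (1, 2, 3, 4),
                     normal_count: int = 2) -> pd.DataFrame:
    """Patient x (subset, index) diversity table for one panel.

    Columns are named ``"<index>:<probe1>/<probe2>/..."``.  Patients without
    cells for the panel are omitted.
    """
    bad = [i for i in indices if i not in INDEX_NAMES]
    if bad:
        raise ValueError(f"unknown diversity indices: {bad}")
    subsets = marker_subsets(panel, k_range)
    sf = state_frame(cohort, panel, normal_count=normal_count)
    rows: dict[str, dict[str, float]] = {}
    for pid, grp in sf.groupby("patient_id", sort=True):
        row: dict[str, float] = {}
        for subset in subsets:
            sigs = grp[list(subset)].apply(tuple, axis=1)
            counts = sigs.value_counts().to_dict()
            scores = diversity_indices(abundance_from_counts(counts, subset))
            label = "/".join(subset)
            for idx in indices:
                row[f"{idx}:{label}"] = getattr(scores, idx)
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def diversity_matrix_tidy(matrix: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Long-format export: patient_id, panel, subset, index_name, value."""
    long = matrix.reset_index().melt(id_vars="patient_id",
                                     var_name="column", value_name="value")
    parts = long["column"].str.split(":", n=1, expand=True)
    long["index_name"] = parts[0]
    long["subset"] = parts[1]
    long["panel"] = panel.panel_id
    return long[["patient_id", "panel", "subset", "index_name", "value"]]
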