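"""Individual genomic marker scores and the aneusomy ploidy surrogate.

Each marker score is the percentage of scored cells carrying a particular
aberration (probe + direction), e.g. "CDKN2A loss" or "CEP7 gain", used as a
continuous covariate.  Aneusomy — a surrogate for DNA-ploidy change — is the
unweighted mean of three percentages: cells with an abnormal CEP17 count in
each of the two panels, and cells with an abnormal CEP7 count.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import CellState, Cohort, SET1, SET2, state_frame

__all__ = ["marker_score", "aneusomy_score", "marker_score_table",
           "TABLE_MARKERS"]

# marker names as reported, probe + direction
TABLE_MARKERS = [
    ("CEP7 gain", "set2", "CEP7", "gain"),
    ("c-MYC gain", "set2", "c-MYC", "gain"),
    ("CEP17 gain", "set2", "CEP17", "gain"),
    ("CEP17 loss", "set2", "CEP17", "loss"),
    ("20q gain", "set2", "20q", "gain"),
    ("CEP7 loss", "set2", "CEP7", "loss"),
    ("ERBB2 gain", "set1", "ERBB2", "gain"),
    ("CDKN2A loss", "set1", "CDKN2A", "loss"),
    ("TP53 loss", "set1", "TP53", "loss"),
]


def marker_score(states: Sequence[CellState], marker: str, direction: str) -> float:
    """Percent of cells whose ``marker`` probe is in state ``direction``."""
    if not states:
        raise ValueError("no cells")
    if direction not in ("loss", "gain"):
        raise ValueError(f"direction must be loss or gain, got {direction!r}")
    hits = sum(1 for s in states if s.states[marker] == direction)
    return 100.0 * hits / len(states)


def aneusomy_score(states_set1: Sequence[CellState],
                   states_set2: Sequence[CellState]) -> float:
    """Mean of %abnormal CEP17 (set 1), %abnormal CEP17 (set 2), %abnormal CEP7."""
    if not states_set1:
        raise ValueError("panel set1 missing")
    if not states_set2:
        raise ValueError("panel set2 missing")

    def pct_abnormal(states: Sequence[CellState], probe: str) -> float:
        hits = sum(1 for s in states if s.states[probe] != "normal")
        return 100.0 * hits / len(states)

    return (pct_abnormal(states_set1, "CEP17")
            + pct_abnormal(states_set2, "CEP17")
            + pct_abnormal(states_set2, "CEP7")) / 3.0


def marker_score_table(cohort: Cohort, normal_count: int = 2) -> pd.DataFrame:
    """Wide patient x marker table of scores (columns named as reported).

    Includes the nine directional probe scores and the pooled "Aneusomy"
    column; the latter is NaN for patients missing either panel.
    """
    sf1 = state_frame(cohort, SET1, normal_count=normal_count)
    sf2 = state_frame(cohort, SET2, normal_count=normal_count)
    frames = {"set1": sf1, "set2": sf2}
    out: dict[str, pd.Series] = {}
    for name, panel_id, probe, direction in TABLE_MARKERS:
        sf = frames[panel_id]
        if sf.empty:
            continue
        want = -1 if direction == "loss" else 1
        grp = sf.groupby("patient_id")[probe]
        out[name] = grp.apply(lambda s: 100.0 * (s == want).mean())

    def pct_abn(sf: pd.DataFrame, probe: str) -> pd.Series:
        return sf.groupby("patient_id")[probe].apply(
            lambda s: 100.0 * (s != 0).mean())

    if not sf1.empty and not sf2.empty:
        out["Aneusomy"] = (pct_abn(sf1, "CEP17") + pct_abn(sf2, "CEP17")
                           + pct_abn(sf2, "CEP7")) / 3.0
    df = pd.DataFrame(out)
    df.index.name = "patient_id"
    return df
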