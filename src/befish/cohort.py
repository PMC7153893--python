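"""Cohort data model for per-cell FISH scoring and clinical follow-up tables.

A study cohort consists of three tables:

* per-cell FISH signal counts — one row per scored Barrett cell, with integer
  signal counts for the four probes of one hybridization panel
  (set 1: CDKN2A, TP53, ERBB2, CEP17; set 2: CEP7, CEP17, 20q, c-MYC);
* clinical baseline covariates (age, sex, Prague C/M segment lengths, BMI,
  smoking, PPI use, hospital type, baseline dysplasia grade);
* prospective outcome (follow-up months, progression to HGD or EAC).

Raw signal counts are mapped to a categorical per-probe state
(loss / normal / gain) relative to the disomic reference of two signals per
nucleus; that categorical profile is what downstream clone definitions use.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MarkerPanel",
    "SET1",
    "SET2",
    "PANELS",
    "CellRecord",
    "CellState",
    "ClinicalRecord",
    "OutcomeRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "read_cell_table",
    "write_cell_table",
    "read_clinical_table",
    "write_clinical_table",
    "classify_cell_states",
    "classify_cells",
    "state_frame",
    "apply_inclusion_filters",
]

LOSS, NORMAL, GAIN = "loss", "normal", "gain"

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "c_length", "m_length", "bmi",
    "smoking", "ppi", "hospital", "baseline_dysplasia",
    "followup_months", "progressed", "progression_type",
]


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """Rows violate a domain invariant; message lists offending rows."""


@dataclass(frozen=True)
class MarkerPanel:
    """A FISH hybridization panel of exactly four probes."""

    panel_id: str
    probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.probes) != 4:
            raise ValueError(f"panel {self.panel_id!r} must have 4 probes")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError(f"panel {self.panel_id!r} has duplicate probes")


SET1 = MarkerPanel("set1", ("CDKN2A", "TP53", "ERBB2", "CEP17"))
SET2 = MarkerPanel("set2", ("CEP7", "CEP17", "20q", "c-MYC"))
PANELS: dict[str, MarkerPanel] = {"set1": SET1, "set2": SET2}


@dataclass(frozen=True)
class CellRecord:
    """Signal counts for one scored cell of one patient and panel."""

    patient_id: str
    panel_id: str
    cell_index: int
    counts: Mapping[str, int]


@dataclass(frozen=True)
class CellState:
    """Per-probe loss/normal/gain classification of one cell."""

    patient_id: str
    panel_id: str
    cell_index: int
    states: Mapping[str, str]


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age: float
    sex: str                 # "M" / "F"
    c_length: float          # Prague C, cm
    m_length: float          # Prague M, cm
    bmi: float
    smoking: str             # "never" / "current_or_former"
    ppi: bool
    hospital: str            # "community" / "academic"
    baseline_dysplasia: str  # "none" / "LGD" / "HGD"


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    followup_months: float
    progressed: bool
    progression_type: str    # "none" / "HGD" / "EAC"


@dataclass
class Cohort:
    """A validated bundle of per-cell, clinical and outcome records."""

    cells: list[CellRecord]
    clinical: list[ClinicalRecord]
    outcomes: list[OutcomeRecord]
    _cells_frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        clin_ids = [c.patient_id for c in self.clinical]
        if len(set(clin_ids)) != len(clin_ids):
            raise ValidationError("duplicate patient_id in clinical records")
        out_ids = [o.patient_id for o in self.outcomes]
        if len(set(out_ids)) != len(out_ids):
            raise ValidationError("duplicate patient_id in outcome records")
        if set(out_ids) != set(clin_ids):
            raise ValidationError("clinical and outcome patient sets differ")
        missing = {c.patient_id for c in self.cells} - set(clin_ids)
        if missing:
            raise ValidationError(
                f"cell records for patients absent from clinical table: {sorted(missing)}"
            )
        for o in self.outcomes:
            if o.progressed != (o.progression_type != "none"):
                raise ValidationError(
                    f"{o.patient_id}: progressed flag inconsistent with progression_type"
                )
            if not o.followup_months > 0:
                raise ValidationError(f"{o.patient_id}: followup_months must be > 0")
        for c in self.clinical:
            if c.c_length > c.m_length:
                raise ValidationError(
                    f"{c.patient_id}: c_length {c.c_length} exceeds m_length {c.m_length}"
                )

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.clinical]

    def cells_frame(self) -> pd.DataFrame:
        """Per-cell counts as a tidy frame (one probe-count column per probe)."""
        if self._cells_frame is None:
            rows = []
            for r in self.cells:
                row = {"patient_id": r.patient_id, "panel_id": r.panel_id,
                       "cell_index": r.cell_index}
                row.update(r.counts)
                rows.append(row)
            self._cells_frame = pd.DataFrame(rows)
        return self._cells_frame

    def clinical_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(c) for c in self.clinical])
        return df.set_index("patient_id")

    def outcomes_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(o) for o in self.outcomes])
        return df.set_index("patient_id")

    def cells_per_patient(self, panel: MarkerPanel) -> pd.Series:
        cf = self.cells_frame()
        if cf.empty:
            return pd.Series(dtype=int)
        sub = cf[cf["panel_id"] == panel.panel_id]
        return sub.groupby("patient_id").size()


# ---------------------------------------------------------------------------
# readers / writers

def read_cell_table(path: str | Path | io.TextIOBase, panel: MarkerPanel) -> list[CellRecord]:
    """Read a per-cell FISH scoring CSV for one panel.

    Expected header: ``patient_id,panel_id,cell_index,<probe1>,...,<probe4>``
    in panel order.  Rows with missing or negative counts raise
    :class:`ValidationError` naming the offending 1-based data row.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["patient_id", "panel_id", "cell_index", *panel.probes]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    records: list[CellRecord] = []
    bad: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        counts: dict[str, int] = {}
        ok = True
        for probe in panel.probes:
            raw = d[probe]
            try:
                val = int(raw)
            except (TypeError, ValueError):
                bad.append(f"row {i}: non-integer count {raw!r} for {probe}")
                ok = False
                continue
            if val < 0:
                bad.append(f"row {i}: negative count {val} for {probe}")
                ok = False
                continue
            counts[probe] = val
        if not ok:
            continue
        records.append(
            CellRecord(str(d["patient_id"]), str(d["panel_id"]),
                       int(d["cell_index"]), counts)
        )
    if bad:
        raise ValidationError("; ".join(bad))
    return records


def write_cell_table(records: Sequence[CellRecord], path: str | Path,
                     panel: MarkerPanel) -> None:
    rows = [
        {"patient_id": r.patient_id, "panel_id": r.panel_id,
         "cell_index": r.cell_index, **{p: r.counts[p] for p in panel.probes}}
        for r in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "panel_id", "cell_index",
                                *panel.probes]).to_csv(path, index=False)


def read_clinical_table(path: str | Path | io.TextIOBase
                        ) -> tuple[list[ClinicalRecord], list[OutcomeRecord]]:
    """Read the joined clinical + outcome CSV; validate domain invariants."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id: {dupes}")
    clinical: list[ClinicalRecord] = []
    outcomes: list[OutcomeRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        if row["c_length"] > row["m_length"]:
            errors.append(f"{pid}: c_length > m_length")
        progressed = _as_bool(row["progressed"])
        ptype = str(row["progression_type"])
        if progressed != (ptype != "none"):
            errors.append(f"{pid}: progressed={progressed} but progression_type={ptype}")
        clinical.append(ClinicalRecord(
            pid, float(row["age"]), str(row["sex"]), float(row["c_length"]),
            float(row["m_length"]), float(row["bmi"]), str(row["smoking"]),
            _as_bool(row["ppi"]), str(row["hospital"]),
            str(row["baseline_dysplasia"]),
        ))
        outcomes.append(OutcomeRecord(pid, float(row["followup_months"]),
                                      progressed, ptype))
    if errors:
        raise ValidationError("; ".join(errors))
    return clinical, outcomes


def write_clinical_table(clinical: Sequence[ClinicalRecord],
                         outcomes: Sequence[OutcomeRecord],
                         path: str | Path) -> None:
    out_by_id = {o.patient_id: o for o in outcomes}
    rows = []
    for c in clinical:
        o = out_by_id[c.patient_id]
        rows.append({**vars(c), "followup_months": o.followup_months,
                     "progressed": o.progressed,
                     "progression_type": o.progression_type})
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


# ---------------------------------------------------------------------------
# state classification

def classify_cell_states(cell: CellRecord, normal_count: int = 2,
                         normal_counts: Mapping[str, int] | None = None) -> CellState:
    """Map raw signal counts to loss/normal/gain per probe.

    The disomic reference is ``normal_count`` signals (default 2); counts
    strictly below are losses, strictly above gains.  ``normal_counts`` may
    override the reference per probe.
    """
    states = {}
    for probe, n in cell.counts.items():
        ref = normal_counts.get(probe, normal_count) if normal_counts else normal_count
        states[probe] = LOSS if n < ref else (GAIN if n > ref else NORMAL)
    return CellState(cell.patient_id, cell.panel_id, cell.cell_index, states)


def classify_cells(cells: Iterable[CellRecord], normal_count: int = 2,
                   normal_counts: Mapping[str, int] | None = None) -> list[CellState]:
    return [classify_cell_states(c, normal_count, normal_counts) for c in cells]


def state_frame(cohort: Cohort, panel: MarkerPanel,
                normal_count: int = 2) -> pd.DataFrame:
    """Vectorized per-cell state table for one panel.

    Returns a frame with ``patient_id``, ``cell_index`` and one column per
    probe holding -1 (loss) / 0 (normal) / +1 (gain).
    """
    cf = cohort.cells_frame()
    if cf.empty:
        return pd.DataFrame(columns=["patient_id", "cell_index", *panel.probes])
    sub = cf[cf["panel_id"] == panel.panel_id]
    out = sub[["patient_id", "cell_index"]].copy()
    for probe in panel.probes:
        counts = sub[probe].astype(int)
        out[probe] = (counts > normal_count).astype(int) - (counts < normal_count).astype(int)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# inclusion filters

def apply_inclusion_filters(cohort: Cohort, min_cells: int = 50,
                            min_followup_months: float = 6.0,
                            panels: Sequence[MarkerPanel] = (SET1, SET2),
                            ) -> tuple[Cohort, pd.DataFrame]:
    """Apply the study inclusion rules and return (filtered cohort, log).

    Excluded are patients with baseline dysplasia, fewer than ``min_cells``
    scored cells in any panel under analysis, or progression at or before
    ``min_followup_months``.  The log has one row per exclusion with columns
    ``patient_id`` and ``reason``.  Idempotent.
    """
    counts = {p.panel_id: cohort.cells_per_patient(p) for p in panels}
    out_by_id = {o.patient_id: o for o in cohort.outcomes}
    keep: set[str] = set()
    log_rows: list[dict] = []
    for c in cohort.clinical:
        pid = c.patient_id
        o = out_by_id[pid]
        if c.baseline_dysplasia != "none":
            log_rows.append({"patient_id": pid,
                             "reason": f"baseline dysplasia {c.baseline_dysplasia}"})
            continue
        short = [p.panel_id for p in panels
                 if counts[p.panel_id].get(pid, 0) < min_cells]
        if short:
            log_rows.append({"patient_id": pid,
                             "reason": f"insufficient cells in {','.join(short)}"})
            continue
        if o.progressed and o.followup_months <= min_followup_months:
            log_rows.append({"patient_id": pid,
                             "reason": f"progressed at {o.followup_months:g} months"})
            continue
        keep.add(pid)
    filtered = Cohort(
        cells=[r for r in cohort.cells if r.patient_id in keep],
        clinical=[c for c in cohort.clinical if c.patient_id in keep],
        outcomes=[o for o in cohort.outcomes if o.patient_id in keep],
    )
    log = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    return filtered, log
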