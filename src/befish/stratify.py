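"""Leave-one-out risk scoring and cut-off-based risk stratification.

Each patient's prognostic risk score is exp(linear predictor) from a Cox
model trained on all *other* patients (leave-one-out cross-validation),
with covariates centered at the training fold's means.  Sweeping a binary
cut-off over the scores splits the cohort into high-risk (score >= cutoff)
and low-risk groups; for each cut-off the 2x2 confusion table against
observed progression yields sensitivity, specificity, predictive values and
likelihood ratios, and the groups are compared by Kaplan–Meier curves with
a log-rank test.  Annual progression rates are events per 100 person-years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import ModelSpec, fit_cox

__all__ = [
    "ConfusionStats",
    "KMCurve",
    "LogrankResult",
    "loo_risk_scores",
    "confusion_at_cutoff",
    "cutoff_sweep",
    "select_cutoff",
    "km_logrank",
    "annual_progression_rate",
]

Z95 = stats.norm.ppf(0.975)


def loo_risk_scores(features: pd.DataFrame, outcomes: pd.DataFrame,
                    spec: ModelSpec,
                    duration_col: str = "followup_months",
                    event_col: str = "progressed") -> pd.Series:
    """Leave-one-out risk score per patient.

    For each patient the model is refit on the remaining n-1 patients and
    the held-out patient is scored as exp(linear predictor centered at the
    training fold's covariate means).  Deterministic; any non-convergent
    fold raises naming the held-out patient.
    """
    ids = list(features.index)
    scores = {}
    for pid in ids:
        rest = [q for q in ids if q != pid]
        try:
            with warnings.catch_warnings():
                # the per-fold refits would repeat the events-per-covariate
                # warning n times; the full-data fit already surfaces it
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_cox(features.loc[rest], outcomes.loc[rest], spec,
                              duration_col=duration_col, event_col=event_col)
        except RuntimeError as exc:
            raise RuntimeError(f"leave-one-out fold for patient {pid!r} "
                               f"failed: {exc}") from exc
        scores[pid] = float(fit.predict_risk(features.loc[[pid]]).iloc[0])
    out = pd.Series(scores, name="risk_score")
    return out.reindex(features.index)


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    z2 = Z95 ** 2
    denom = 1 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = Z95 * np.sqrt(p * (1 - p) / n + z2 / (4 * n ** 2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def _lr_ci(lr: float, a: int, m: int, b: int, n: int) -> tuple[float, float]:
    # log-method (Simel) CI for a likelihood ratio built from a/m over b/n
    if not np.isfinite(lr) or lr <= 0 or a == 0 or b == 0:
        return (np.nan, np.nan)
    se = np.sqrt((1 - a / m) / a + (1 - b / n) / b)
    return (float(lr * np.exp(-Z95 * se)), float(lr * np.exp(Z95 * se)))


@dataclass(frozen=True)
class ConfusionStats:
    """2x2 diagnostics of high-risk (score >= cutoff) vs progression."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    lr_pos_ci: tuple[float, float]
    lr_neg_ci: tuple[float, float]

    def as_row(self) -> dict:
        return {"cutoff": self.cutoff, "TP": self.tp, "FP": self.fp,
                "TN": self.tn, "FN": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv,
                "lr_pos": self.lr_pos, "lr_neg": self.lr_neg}


def confusion_from_counts(cutoff: float, tp: int, fp: int, tn: int,
                          fn: int) -> ConfusionStats:
    """Diagnostic statistics from a 2x2 table; undefined ratios are NaN."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    if np.isnan(sens) or np.isnan(spec):
        lr_pos = lr_neg = np.nan
    else:
        lr_pos = sens / (1 - spec) if spec < 1 else np.nan
        lr_neg = (1 - sens) / spec if spec > 0 else np.nan
    return ConfusionStats(
        cutoff, tp, fp, tn, fn, sens, spec, ppv, npv, lr_pos, lr_neg,
        sensitivity_ci=_wilson_ci(tp, tp + fn),
        specificity_ci=_wilson_ci(tn, tn + fp),
        ppv_ci=_wilson_ci(tp, tp + fp),
        npv_ci=_wilson_ci(tn, tn + fn),
        lr_pos_ci=_lr_ci(lr_pos, tp, tp + fn, fp, fp + tn),
        lr_neg_ci=_lr_ci(lr_neg, fn, tp + fn, tn, fp + tn),
    )


def confusion_at_cutoff(scores: pd.Series, progressed: pd.Series,
                        cutoff: float) -> ConfusionStats:
    """Stratify at ``cutoff`` (high-risk = score >= cutoff) and tabulate."""
    scores, progressed = scores.align(progressed, join="inner")
    high = scores.values >= cutoff
    prog = progressed.values.astype(bool)
    tp = int((high & prog).sum())
    fp = int((high & ~prog).sum())
    fn = int((~high & prog).sum())
    tn = int((~high & ~prog).sum())
    return confusion_from_counts(cutoff, tp, fp, tn, fn)


def cutoff_sweep(scores: pd.Series, progressed: pd.Series) -> pd.DataFrame:
    """Confusion statistics at every distinct score plus -inf/+inf anchors."""
    prog = progressed.astype(bool)
    if prog.all() or not prog.any():
        raise ValueError("sweep needs at least one progressor and one non-progressor")
    cutoffs = [-np.inf, *np.unique(scores.values), np.inf]
    rows = [confusion_at_cutoff(scores, prog, c).as_row() for c in cutoffs]
    return pd.DataFrame(rows)


def select_cutoff(sweep: pd.DataFrame, target_sensitivity: float) -> float:
    """Largest cut-off whose sensitivity still reaches ``target_sensitivity``."""
    ok = sweep[sweep["sensitivity"] >= target_sensitivity]
    if ok.empty:
        raise ValueError(f"no cut-off achieves sensitivity >= {target_sensitivity}")
    return float(ok["cutoff"].max())


@dataclass(frozen=True)
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "group": self.group})


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float


def km_logrank(outcomes: pd.DataFrame, groups: pd.Series,
               duration_col: str = "followup_months",
               event_col: str = "progressed"
               ) -> tuple[dict[str, KMCurve], LogrankResult]:
    """Kaplan–Meier curves per group and the two-sample log-rank test.

    With no events in either group the log-rank statistic is undefined and
    is reported as NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = groups.reindex(outcomes.index)
    labels = sorted(groups.unique(), key=str)
    if len(labels) < 2:
        raise ValueError("both groups must be non-empty")
    curves: dict[str, KMCurve] = {}
    total_events = 0
    for lab in labels:
        sub = outcomes[groups == lab]
        if sub.empty:
            raise ValueError(f"group {lab!r} is empty")
        km = KaplanMeierFitter().fit(sub[duration_col], sub[event_col])
        tbl = km.event_table
        total_events += int(sub[event_col].sum())
        curves[str(lab)] = KMCurve(
            group=str(lab),
            times=km.survival_function_.index.values,
            survival=km.survival_function_.iloc[:, 0].values,
            at_risk=tbl["at_risk"].reindex(km.survival_function_.index).values,
        )
    if total_events == 0:
        return curves, LogrankResult(np.nan, len(labels) - 1, np.nan)
    res = multivariate_logrank_test(outcomes[duration_col], groups,
                                    outcomes[event_col])
    return curves, LogrankResult(float(res.test_statistic),
                                 len(labels) - 1, float(res.p_value))


def annual_progression_rate(outcomes: pd.DataFrame,
                            mask: pd.Series | np.ndarray | None = None,
                            duration_col: str = "followup_months",
                            event_col: str = "progressed") -> float:
    """Events per 100 person-years: 100 * events / sum(months / 12)."""
    sub = outcomes if mask is None else outcomes[np.asarray(mask, bool)]
    if sub.empty:
        raise ValueError("no patients selected")
    years = sub[duration_col].sum() / 12.0
    if years <= 0:
        raise ValueError("zero total follow-up time")
    return float(100.0 * sub[event_col].astype(bool).sum() / years)
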