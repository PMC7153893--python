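"""Bootstrap model selection by out-of-bag integrated time-dependent AUC.

Candidate Cox models are compared by drawing B bootstrap resamples of the
cohort; each resample trains the model, the excluded (out-of-bag) patients
form the test set, and discrimination is summarized by the integrated
time-dependent AUC (iAUC) of the model's risk score on the test set.
Models are ranked by median out-of-bag iAUC (higher is better), ties broken
by median training AIC (lower is better).

The iAUC here is the incident/dynamic time-dependent AUC: at each observed
event time t, cases are the patients who progress exactly at t and controls
those still event-free beyond t; AUC(t) is the probability that a case
outranks a control.  The curve is integrated over event times up to a
horizon tau with Kaplan–Meier-derived weights w(t) ∝ 2·f(t)·S(t),
normalized to sum to one, so times where events are both likely and
discrimination is still meaningful dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cox import CoxFit, ModelSpec, fit_cox

__all__ = [
    "BootstrapEval",
    "time_dependent_iauc",
    "iauc_for_fit",
    "bootstrap_evaluate",
    "rank_models",
]


def _km_survival(time: np.ndarray, event: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival evaluated at the distinct event times."""
    from lifelines import KaplanMeierFitter
    km = KaplanMeierFitter().fit(time, event)
    ts = np.unique(time[event])
    surv = km.survival_function_at_times(ts).values
    return ts, surv


def time_dependent_iauc(scores: np.ndarray, time: np.ndarray,
                        event: np.ndarray, tau: float | None = None) -> float:
    """Integrated incident/dynamic AUC of ``scores`` on survival data.

    Higher scores must indicate higher hazard.  ``tau`` limits the event
    times entering the integral (default: the largest observed time).
    Raises if no event occurs at or before ``tau``.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if tau is None:
        tau = float(time.max())
    ts, surv = _km_survival(time, event)
    keep = ts <= tau
    ts, surv = ts[keep], surv[keep]
    if len(ts) == 0:
        raise ValueError(f"no events at or before tau={tau}")
    # KM jump f(t) at each event time; S(t-) is the previous survival value
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    f = surv_prev - surv
    aucs, weights = [], []
    for t_j, f_j, s_j in zip(ts, f, surv):
        case_scores = scores[event & (time == t_j)]
        ctrl_scores = scores[time > t_j]
        if len(ctrl_scores) == 0:
            continue
        ctrl_sorted = np.sort(ctrl_scores)
        lt = np.searchsorted(ctrl_sorted, case_scores, side="left")
        le = np.searchsorted(ctrl_sorted, case_scores, side="right")
        wins = lt + 0.5 * (le - lt)
        aucs.append(wins.sum() / (len(case_scores) * len(ctrl_scores)))
        weights.append(2.0 * f_j * s_j)
    if not aucs:
        raise ValueError("no usable event time had controls at risk")
    w = np.asarray(weights)
    if w.sum() == 0:  # all mass at the last event time with S=0
        w = np.ones_like(w)
    return float(np.average(aucs, weights=w))


def iauc_for_fit(fit: CoxFit, test_features: pd.DataFrame,
                 test_outcomes: pd.DataFrame, tau: float | None = None,
                 duration_col: str = "followup_months",
                 event_col: str = "progressed") -> float:
    scores = fit.predict_risk(test_features).values
    return time_dependent_iauc(scores,
                               test_outcomes[duration_col].values,
                               test_outcomes[event_col].values.astype(bool),
                               tau=tau)


@dataclass
class BootstrapEval:
    """Per-replicate bootstrap evaluation of one model spec."""

    spec_id: str
    iaucs: np.ndarray          # out-of-bag iAUC, one per replicate
    aics: np.ndarray           # training AIC, one per replicate
    B: int
    seed: int
    n_redrawn: int             # degenerate resamples that were redrawn
    n_failed: int              # resamples where the fit failed

    @property
    def median_iauc(self) -> float:
        return float(np.median(self.iaucs))

    @property
    def iqr_iauc(self) -> tuple[float, float]:
        return tuple(np.percentile(self.iaucs, [25, 75]))

    @property
    def median_aic(self) -> float:
        return float(np.median(self.aics))

    @property
    def iqr_aic(self) -> tuple[float, float]:
        return tuple(np.percentile(self.aics, [25, 75]))

    def summary_row(self) -> dict:
        lo_i, hi_i = self.iqr_iauc
        lo_a, hi_a = self.iqr_aic
        return {"model_id": self.spec_id, "median_iAUC": self.median_iauc,
                "iAUC_q25": lo_i, "iAUC_q75": hi_i,
                "median_AIC": self.median_aic, "AIC_q25": lo_a,
                "AIC_q75": hi_a, "B": self.B, "seed": self.seed,
                "n_redrawn": self.n_redrawn, "n_failed": self.n_failed}


def bootstrap_evaluate(features: pd.DataFrame, outcomes: pd.DataFrame,
                       spec: ModelSpec, B: int = 1000, seed: int = 0,
                       tau: float | None = None,
                       duration_col: str = "followup_months",
                       event_col: str = "progressed",
                       max_redraw_factor: int = 20) -> BootstrapEval:
    """Out-of-bag bootstrap evaluation of one model.

    Each replicate draws n patients with replacement as the training set and
    evaluates the trained model's iAUC on the excluded patients.  Replicates
    whose training or out-of-bag set has no usable event are redrawn (and
    counted); replicate seeds derive from ``seed`` and a replicate counter,
    so results are reproducible and independent of execution order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids = np.asarray(features.index)
    n = len(ids)
    out = outcomes.loc[ids]
    if tau is None:
        tau = float(np.percentile(out[duration_col], 95))
    iaucs, aics = [], []
    n_redrawn = n_failed = 0
    b = 0
    attempts = 0
    max_attempts = max_redraw_factor * B
    while len(iaucs) < B:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"model {spec.spec_id!r}: exceeded {max_attempts} bootstrap "
                f"attempts ({n_failed} failed fits, {n_redrawn} degenerate "
                f"resamples) for B={B}")
        rng = np.random.default_rng([seed, b])
        b += 1
        idx = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, bool)
        oob_mask[np.unique(idx)] = False
        oob_ids = ids[oob_mask]
        train_ids = ids[idx]
        tr_out = out.iloc[idx]
        te_out = out.loc[oob_ids]
        te_events = te_out[event_col].astype(bool) & (te_out[duration_col] <= tau)
        if not tr_out[event_col].any() or len(oob_ids) == 0 or not te_events.any():
            n_redrawn += 1
            continue
        tr_feat = features.iloc[idx]
        try:
            with warnings.catch_warnings():
                # resamples with few events would re-trigger the events-per-
                # covariate guard on every replicate; warn once at call level
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_cox(tr_feat.reset_index(drop=True),
                              tr_out.reset_index(drop=True), spec,
                              duration_col=duration_col, event_col=event_col)
            iauc = iauc_for_fit(fit, features.loc[oob_ids], te_out, tau=tau,
                                duration_col=duration_col, event_col=event_col)
        except (RuntimeError, ValueError):
            n_failed += 1
            if n_failed > max(10, attempts // 2):
                raise RuntimeError(
                    f"model {spec.spec_id!r} failed on more than half of "
                    f"{attempts} bootstrap resamples")
            continue
        iaucs.append(iauc)
        aics.append(fit.aic)
    return BootstrapEval(spec.spec_id, np.asarray(iaucs), np.asarray(aics),
                         B=B, seed=seed, n_redrawn=n_redrawn, n_failed=n_failed)


def rank_models(evals: Sequence[BootstrapEval]) -> pd.DataFrame:
    """Rank models: median iAUC descending, ties by lower median AIC."""
    if not evals:
        raise ValueError("no evaluations to rank")
    df = pd.DataFrame([e.summary_row() for e in evals])
    df = df.sort_values(["median_iAUC", "median_AIC", "model_id"],
                        ascending=[False, True, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)
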