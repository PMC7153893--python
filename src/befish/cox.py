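"""Cox proportional-hazards fitting with spline covariates and model tests.

Thin, opinionated layer over ``lifelines.CoxPHFitter`` (Efron tie handling,
Newton–Raphson) that adds what the surrounding risk-stratification pipeline
needs: natural-cubic-spline expansion of covariates, per-coefficient Wald
and overall Wald / likelihood-ratio tests, AIC, nested-model chi-square
comparison, and held-out risk prediction with training-mean centering.

A ``ModelSpec`` lists base covariates (at most ``max_covariates``, default 3
— roughly one covariate per ten observed events, guarding against
overfitting in low-event cohorts); each may be expanded into a natural
cubic spline basis of ``spline_df`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Covariate",
    "ModelSpec",
    "CoxFit",
    "fit_cox",
    "spline_basis",
    "NaturalSplineBasis",
    "compare_nested",
    "efron_partial_loglik",
]

Z95 = 1.96  # normal quantile used for reported 95% CIs


@dataclass(frozen=True)
class Covariate:
    name: str
    source: str = "clinical"  # clinical | marker | diversity
    spline: bool = False
    spline_df: int = 3


@dataclass(frozen=True)
class ModelSpec:
    spec_id: str
    covariates: tuple[Covariate, ...]
    max_covariates: int = 3

    def __post_init__(self) -> None:
        if len(self.covariates) > self.max_covariates:
            raise ValueError(
                f"model {self.spec_id!r} has {len(self.covariates)} base covariates; "
                f"at most {self.max_covariates} are allowed to prevent overfitting "
                f"relative to the number of events"
            )
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"model {self.spec_id!r} repeats a covariate")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)


class NaturalSplineBasis:
    """Natural cubic spline basis, fit once, reusable on new data.

    ``df`` basis columns with no constant in their span (a constant
    direction would make the Cox information matrix singular).  Knots:
    boundary knots at the training range, interior knots at equally spaced
    quantiles, ``df + 1`` knots in total.  Uses the truncated-power natural
    basis N_1(x) = x, N_{k+1}(x) = d_k(x) - d_{K-1}(x) with
    d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3] / (t_K - t_k); beyond the
    boundary knots the basis extrapolates linearly, as a natural spline
    must.
    """

    def __init__(self, df: int = 3):
        if df < 2:
            raise ValueError("spline_df must be >= 2")
        self.df = df
        self.knots: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> pd.DataFrame:
        x = np.asarray(x, dtype=float)
        if len(np.unique(x)) < self.df + 1:
            raise ValueError(
                f"need more than {self.df} distinct values for a df={self.df} "
                f"natural spline, got {len(np.unique(x))}"
            )
        probs = np.linspace(0, 1, self.df + 1)
        knots = np.quantile(x, probs)
        knots = np.unique(knots)
        if len(knots) < self.df + 1:
            raise ValueError("degenerate quantile knots; too many tied values")
        self.knots = knots
        return self.transform(x)

    def transform(self, x: np.ndarray) -> pd.DataFrame:
        if self.knots is None:
            raise RuntimeError("basis not fitted")
        x = np.asarray(x, dtype=float)
        t = self.knots
        K = len(t)

        def d(k: int) -> np.ndarray:
            num = (np.maximum(x - t[k], 0.0) ** 3
                   - np.maximum(x - t[K - 1], 0.0) ** 3)
            return num / (t[K - 1] - t[k])

        cols = {"ns1": x}
        d_last = d(K - 2)
        for k in range(K - 2):
            cols[f"ns{k + 2}"] = d(k) - d_last
        return pd.DataFrame(cols)


def spline_basis(x: np.ndarray, df: int) -> pd.DataFrame:
    """Natural cubic spline basis of ``x`` with ``df`` columns."""
    return NaturalSplineBasis(df).fit(x)


@dataclass
class CoxFit:
    """A fitted Cox model plus everything needed to score new patients."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    wald_p: pd.Series
    wald_p_overall: float
    lr_p: float
    log_likelihood: float
    null_log_likelihood: float
    aic: float
    n: int
    n_events: int
    training_means: pd.Series = field(repr=False)
    _bases: dict = field(default_factory=dict, repr=False)
    _variance: np.ndarray | None = field(default=None, repr=False)

    def design_matrix(self, features: pd.DataFrame) -> pd.DataFrame:
        return _build_design(features, self.spec, self._bases, fit=False)

    def linear_predictor(self, features: pd.DataFrame) -> pd.Series:
        """Linear predictor for new patients, centered at training means."""
        if len(self.beta) == 0:
            return pd.Series(0.0, index=features.index)
        X = self.design_matrix(features)
        Xc = X[self.beta.index] - self.training_means[self.beta.index]
        return pd.Series(Xc.values @ self.beta.values, index=features.index)

    def predict_risk(self, features: pd.DataFrame) -> pd.Series:
        """Risk score exp(centered linear predictor)."""
        return np.exp(self.linear_predictor(features))

    def summary_frame(self) -> pd.DataFrame:
        """Per-coefficient report: HR, 95% CI, Wald p (layout of Tables 2-5)."""
        return pd.DataFrame({
            "coef": self.beta, "se": self.se, "HR": self.hazard_ratios,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p_wald": self.wald_p,
        })


def _build_design(features: pd.DataFrame, spec: ModelSpec, bases: dict,
                  fit: bool) -> pd.DataFrame:
    cols: list[pd.DataFrame | pd.Series] = []
    for cov in spec.covariates:
        if cov.name not in features.columns:
            raise KeyError(f"covariate {cov.name!r} not in feature table")
        x = features[cov.name].astype(float)
        if x.isna().any():
            missing = features.index[x.isna()].tolist()
            raise ValueError(f"missing values for {cov.name!r}: {missing[:5]}")
        if cov.spline:
            if fit:
                basis = NaturalSplineBasis(cov.spline_df)
                block = basis.fit(x.values)
                bases[cov.name] = basis
            else:
                block = bases[cov.name].transform(x.values)
            block.columns = [f"{cov.name}:{c}" for c in block.columns]
            block.index = features.index
            cols.append(block)
        else:
            cols.append(x.rename(cov.name))
    if not cols:
        return pd.DataFrame(index=features.index)
    return pd.concat(cols, axis=1)


def fit_cox(features: pd.DataFrame, outcomes: pd.DataFrame, spec: ModelSpec,
            duration_col: str = "followup_months",
            event_col: str = "progressed") -> CoxFit:
    """Maximize the Efron partial likelihood for ``spec`` on aligned tables.

    ``features`` and ``outcomes`` are indexed by patient id; only patients
    present in both are used.  Constant (zero-variance) design columns are
    dropped; if nothing remains the null (0-coefficient) model is returned
    with ``lr_p = 1``.
    """
    ids = features.index.intersection(outcomes.index)
    if len(ids) < len(features):
        features = features.loc[ids]
    out = outcomes.loc[ids]
    t = out[duration_col].astype(float).values
    e = out[event_col].astype(bool).values
    n, n_events = len(ids), int(e.sum())
    if n_events == 0:
        raise ValueError("no events in the data; cannot fit a Cox model")
    if len(spec.covariates) > max(1, n_events / 10):
        warnings.warn(
            f"model {spec.spec_id!r}: {len(spec.covariates)} covariates for "
            f"{n_events} events exceeds the 1-per-10-events guideline",
            stacklevel=2)

    bases: dict = {}
    X = _build_design(features, spec, bases, fit=True)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]

    ll0 = efron_partial_loglik(np.empty((n, 0)), t, e, np.empty(0))
    if X.shape[1] == 0:
        empty = pd.Series(dtype=float)
        return CoxFit(spec, empty, empty, empty, empty, empty, empty,
                      wald_p_overall=1.0, lr_p=1.0, log_likelihood=ll0,
                      null_log_likelihood=ll0, aic=-2 * ll0, n=n,
                      n_events=n_events, training_means=empty, _bases=bases)

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = X.copy()
    df["__t"] = t
    df["__e"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df.reset_index(drop=True), duration_col="__t", event_col="__e",
                fit_options={"precision": 1e-9, "max_steps": 500})
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox fit for model {spec.spec_id!r} did not converge: {exc}") from exc

    beta = cph.params_.copy()
    se = cph.standard_errors_.copy()
    hr = np.exp(beta)
    ci_lo = np.exp(beta - Z95 * se)
    ci_hi = np.exp(beta + Z95 * se)
    wald_p = pd.Series(2 * stats.norm.sf(np.abs(beta / se)), index=beta.index)

    V = np.asarray(cph.variance_matrix_)
    k = len(beta)
    try:
        w_stat = float(beta.values @ np.linalg.solve(V, beta.values))
        wald_overall = float(stats.chi2.sf(w_stat, k))
    except np.linalg.LinAlgError:
        wald_overall = float("nan")
    ll = float(cph.log_likelihood_)
    lr_p = float(stats.chi2.sf(2 * (ll - ll0), k))
    means = X.mean()

    return CoxFit(spec, beta, se, hr, ci_lo, ci_hi, wald_p,
                  wald_p_overall=wald_overall, lr_p=lr_p, log_likelihood=ll,
                  null_log_likelihood=ll0, aic=-2 * ll + 2 * k, n=n,
                  n_events=n_events, training_means=means, _bases=bases,
                  _variance=V)


def efron_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                         beta: np.ndarray) -> float:
    """Efron-approximation Cox partial log-likelihood at ``beta``."""
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    eta = X @ np.asarray(beta, float) if X.shape[1] else np.zeros(len(time))
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event]):
        d_mask = event & (time == t)
        r_mask = time >= t
        d = int(d_mask.sum())
        sum_d = theta[d_mask].sum()
        sum_r = theta[r_mask].sum()
        ll += eta[d_mask].sum()
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_d)
    return float(ll)


def compare_nested(fit_small: CoxFit, fit_large: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio (anova) chi-square test of nested Cox fits.

    Returns ``(chi2, df, p)``; the caller keeps the larger model when
    ``p <= 0.05`` (it has the higher log-likelihood by construction).
    """
    if (fit_small.n, fit_small.n_events) != (fit_large.n, fit_large.n_events):
        raise ValueError("nested comparison requires the same patients")
    small_names = set(fit_small.spec.names)
    large_names = set(fit_large.spec.names)
    if not small_names <= large_names:
        raise ValueError(
            f"models are not nested: {sorted(small_names - large_names)} "
            f"absent from the larger model")
    df = len(fit_large.beta) - len(fit_small.beta)
    if df < 0:
        raise ValueError("larger model has fewer parameters than smaller")
    chi2 = max(0.0, 2 * (fit_large.log_likelihood - fit_small.log_likelihood))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p
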