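"""Leave-one-out scoring, cut-off diagnostics, KM curves and log-rank test."""

import numpy as np
import pandas as pd
import pytest

from befish.cox import Covariate, ModelSpec
from befish.stratify import (annual_progression_rate, confusion_at_cutoff,
                             confusion_from_counts, cutoff_sweep, km_logrank,
                             loo_risk_scores, select_cutoff)

from conftest import survival_frame


def outcome_frame(times, events):
    return pd.DataFrame({"followup_months": times,
                         "progressed": np.asarray(events, bool)},
                        index=[f"P{i}" for i in range(len(times))])


class TestLooRiskScores:
    def test_constant_covariates_give_equal_scores(self):
        feat = pd.DataFrame({"x": [2.0] * 8}, index=[f"P{i}" for i in range(8)])
        out = outcome_frame([5, 8, 3, 9, 2, 7, 6, 4],
                            [1, 0, 1, 0, 1, 0, 1, 0])
        scores = loo_risk_scores(feat, out, ModelSpec("c", (Covariate("x"),)))
        assert scores.nunique() == 1

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        df = survival_frame(40, rng, beta=0.8)
        spec = ModelSpec("m", (Covariate("x"),))
        a = loo_risk_scores(df[["x"]], df, spec)
        perm = df.sample(frac=1, random_state=5)
        b = loo_risk_scores(perm[["x"]], perm, spec)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index(),
                                       rtol=1e-9)

    def test_scores_computed_without_own_patient(self):
        # an extreme outlier patient cannot drag its own training fold
        rng = np.random.default_rng(1)
        df = survival_frame(30, rng, beta=1.0)
        df.loc[df.index[0], "x"] = 50.0
        spec = ModelSpec("m", (Covariate("x"),))
        scores = loo_risk_scores(df[["x"]], df, spec)
        assert np.isfinite(scores).all()

    def test_informative_scores_outrank_null(self, small_cohort):
        from befish.pipeline import NC_SET2_COLUMN, assemble_features
        from lifelines.utils import concordance_index
        cohort, truth = small_cohort
        feat = assemble_features(cohort)
        feat[NC_SET2_COLUMN] = truth["nc_set2"]
        out = cohort.outcomes_frame()
        spec = ModelSpec("inf", (Covariate("age"), Covariate("c_length"),
                                 Covariate(NC_SET2_COLUMN)))
        scores = loo_risk_scores(feat, out, spec)
        c_inf = concordance_index(out["followup_months"], -scores,
                                  out["progressed"])
        assert c_inf > 0.5


class TestConfusionStats:
    def test_identities_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 40, size=4)
            s = confusion_from_counts(0.0, tp, fp, tn, fn)
            assert s.sensitivity == pytest.approx(tp / (tp + fn))
            assert s.specificity == pytest.approx(tn / (tn + fp))
            assert s.ppv == pytest.approx(tp / (tp + fp))
            assert s.npv == pytest.approx(tn / (tn + fn))
            assert s.lr_pos == pytest.approx(s.sensitivity / (1 - s.specificity))
            assert s.lr_neg == pytest.approx((1 - s.sensitivity) / s.specificity)

    def test_ppv_bayes_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 40, size=4))
            s = confusion_from_counts(0.0, tp, fp, tn, fn)
            prev = (tp + fn) / (tp + fp + tn + fn)
            bayes_ppv = (s.sensitivity * prev) / (
                s.sensitivity * prev + (1 - s.specificity) * (1 - prev))
            assert s.ppv == pytest.approx(bayes_ppv, abs=1e-12)

    def test_perfect_separation(self):
        scores = pd.Series([10, 11, 12, 1, 2, 3],
                           index=[f"P{i}" for i in range(6)])
        prog = pd.Series([True, True, True, False, False, False],
                         index=scores.index)
        s = confusion_at_cutoff(scores, prog, 5.0)
        assert (s.sensitivity, s.specificity, s.ppv, s.npv) == (1, 1, 1, 1)

    def test_degenerate_cutoff_reports_nan_not_error(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        prog = pd.Series([False, False], index=["a", "b"])
        s = confusion_at_cutoff(scores, prog, 10.0)
        assert np.isnan(s.sensitivity) and np.isnan(s.ppv)

    def test_wilson_ci_contains_point_estimate(self):
        s = confusion_from_counts(0.0, 29, 188, 114, 3)
        lo, hi = s.ppv_ci
        assert lo < s.ppv < hi
        lo, hi = s.npv_ci
        assert lo < s.npv < hi


class TestCutoffSweep:
    @pytest.fixture()
    def scored(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=60),
                           index=[f"P{i}" for i in range(60)])
        prog = pd.Series(rng.random(60) < 0.3, index=scores.index)
        if not prog.any():
            prog.iloc[0] = True
        return scores, prog

    def test_anchors(self, scored):
        scores, prog = scored
        sweep = cutoff_sweep(scores, prog)
        low = sweep.iloc[0]
        high = sweep.iloc[-1]
        assert (low["sensitivity"], low["specificity"]) == (1.0, 0.0)
        assert (high["sensitivity"], high["specificity"]) == (0.0, 1.0)

    def test_monotonicity(self, scored):
        scores, prog = scored
        sweep = cutoff_sweep(scores, prog)
        assert (np.diff(sweep["sensitivity"]) <= 1e-12).all()
        assert (np.diff(sweep["specificity"]) >= -1e-12).all()

    def test_identities_at_every_sweep_point(self, scored):
        scores, prog = scored
        sweep = cutoff_sweep(scores, prog)
        n_prog, n_non = int(prog.sum()), int((~prog).sum())
        for _, r in sweep.iterrows():
            assert r["TP"] + r["FN"] == n_prog
            assert r["TN"] + r["FP"] == n_non

    def test_select_cutoff_largest_reaching_target(self, scored):
        scores, prog = scored
        sweep = cutoff_sweep(scores, prog)
        cut = select_cutoff(sweep, 0.9)
        s = confusion_at_cutoff(scores, prog, cut)
        assert s.sensitivity >= 0.9
        higher = sweep[sweep["cutoff"] > cut]
        assert (higher["sensitivity"] < 0.9).all()


class TestKMLogrank:
    def test_hand_computed_product_limit(self):
        # times 2,4,4,6,8 with events 1,1,0,1,0:
        # S(2)=4/5; at t=4 one event among 4 at risk -> S=4/5*3/4=3/5;
        # at t=6 one event among 2 at risk -> S=3/5*1/2=3/10
        out = outcome_frame([2, 4, 4, 6, 8], [1, 1, 0, 1, 0])
        out["grp"] = "a"
        out2 = out.copy()
        out2.index = [f"Q{i}" for i in range(5)]
        out2["grp"] = "b"
        both = pd.concat([out, out2])
        curves, _ = km_logrank(both, both["grp"])
        km = curves["a"]
        surv = dict(zip(km.times, km.survival))
        assert surv[2.0] == pytest.approx(4 / 5)
        assert surv[4.0] == pytest.approx(3 / 5)
        assert surv[6.0] == pytest.approx(3 / 10)

    def test_identical_groups_chi2_zero(self):
        out = outcome_frame([2, 4, 4, 6, 8, 2, 4, 4, 6, 8],
                            [1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=out.index)
        _, lr = km_logrank(out, groups)
        assert lr.chi2 == pytest.approx(0.0, abs=1e-10)
        assert lr.p == pytest.approx(1.0, abs=1e-10)

    def test_no_events_reports_nan(self):
        out = outcome_frame([5, 6, 7, 8], [0, 0, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=out.index)
        curves, lr = km_logrank(out, groups)
        assert np.isnan(lr.p)
        for c in curves.values():
            assert (c.survival == 1.0).all()

    def test_empty_group_error(self):
        out = outcome_frame([5, 6], [1, 0])
        groups = pd.Series(["a", "a"], index=out.index)
        with pytest.raises(ValueError):
            km_logrank(out, groups)

    def test_logrank_matches_permutation_null(self):
        # small toy: compare the chi-square p with a Monte-Carlo permutation p
        rng = np.random.default_rng(6)
        times = rng.exponential(10, size=24)
        events = rng.random(24) < 0.8
        groups = np.array(["a"] * 12 + ["b"] * 12)
        out = outcome_frame(times, events)

        def stat(g):
            _, lr = km_logrank(out, pd.Series(g, index=out.index))
            return lr.chi2

        observed = stat(groups)
        perm_ge = 0
        reps = 500
        for _ in range(reps):
            perm_ge += stat(rng.permutation(groups)) >= observed - 1e-12
        perm_p = perm_ge / reps
        _, lr = km_logrank(out, pd.Series(groups, index=out.index))
        assert perm_p == pytest.approx(lr.p, abs=0.08)


class TestAnnualProgressionRate:
    def test_ten_patients_one_event(self):
        out = outcome_frame([12.0] * 10, [1] + [0] * 9)
        assert annual_progression_rate(out) == pytest.approx(10.0)

    def test_zero_events(self):
        out = outcome_frame([24.0] * 5, [0] * 5)
        assert annual_progression_rate(out) == 0.0

    def test_group_filter(self):
        out = outcome_frame([12.0] * 4, [1, 1, 0, 0])
        mask = np.array([True, True, False, False])
        assert annual_progression_rate(out, mask) == pytest.approx(100.0)
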