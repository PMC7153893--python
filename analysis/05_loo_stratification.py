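"""Leave-one-out risk scores, cut-off sweep and risk-group stratification.

Scores every patient with a Cox model trained on the other n-1 patients
(age + C-length + normalized clone score over the set-2 markers), sweeps
binary cut-offs, picks the largest cut-off reaching 0.90 sensitivity, and
reports the 2x2 diagnostics, annual progression rates per risk group and
the Kaplan–Meier / log-rank comparison.  Writes risk_scores.csv,
cutoff_sweep.csv, stratification.csv, km_curves.csv and km_curves.png.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from importlib import import_module

from befish.cohort import apply_inclusion_filters
from befish.cox import Covariate, ModelSpec
from befish.pipeline import NC_SET2_COLUMN, assemble_features
from befish.stratify import (annual_progression_rate, confusion_at_cutoff,
                             cutoff_sweep, km_logrank, loo_risk_scores,
                             select_cutoff)

load_cohort = import_module("02_diversity_markers").load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"
TARGET_SENSITIVITY = 0.90


def main() -> None:
    cohort, _ = apply_inclusion_filters(load_cohort())
    div2 = pd.read_csv(ROOT / "diversity_set2_wide.csv",
                       index_col="patient_id")
    feat = assemble_features(cohort, diversity=div2)
    out = cohort.outcomes_frame()

    spec = ModelSpec("clinical+NC_set2",
                     (Covariate("age"), Covariate("c_length"),
                      Covariate(NC_SET2_COLUMN)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = loo_risk_scores(feat, out, spec)
    scores.rename("score").to_csv(ROOT / "risk_scores.csv")

    sweep = cutoff_sweep(scores, out["progressed"])
    sweep.to_csv(ROOT / "cutoff_sweep.csv", index=False)
    cutoff = select_cutoff(sweep, TARGET_SENSITIVITY)
    stats = confusion_at_cutoff(scores, out["progressed"], cutoff)

    high = scores >= cutoff
    rate_high = annual_progression_rate(out, high)
    rate_low = annual_progression_rate(out, ~high)
    curves, lr = km_logrank(out, high.map({True: "high", False: "low"}))
    pd.concat([c.as_frame() for c in curves.values()]).to_csv(
        ROOT / "km_curves.csv", index=False)

    row = stats.as_row()
    row.update(annual_rate_high=rate_high, annual_rate_low=rate_low,
               logrank_chi2=lr.chi2, logrank_p=lr.p)
    pd.DataFrame([row]).to_csv(ROOT / "stratification.csv", index=False)

    print(f"cut-off (largest with sensitivity >= {TARGET_SENSITIVITY}): "
          f"{cutoff:.4g}")
    print(f"high risk {int(high.sum())} patients "
          f"({stats.tp} progressors), low risk {int((~high).sum())} "
          f"({stats.fn} progressors)")
    print(f"sensitivity {stats.sensitivity:.2f}, "
          f"specificity {stats.specificity:.2f}, PPV {stats.ppv:.2f} "
          f"(95% CI {stats.ppv_ci[0]:.2f}-{stats.ppv_ci[1]:.2f}), "
          f"NPV {stats.npv:.2f} "
          f"(95% CI {stats.npv_ci[0]:.2f}-{stats.npv_ci[1]:.2f})")
    print(f"LR+ {stats.lr_pos:.2f}, LR- {stats.lr_neg:.2f}")
    print(f"annual progression rate: high {rate_high:.2f}%/yr, "
          f"low {rate_low:.2f}%/yr; log-rank p = {lr.p:.2e}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, curve in curves.items():
            ax.step(curve.times, curve.survival, where="post",
                    label=f"{name} risk")
        ax.set_xlabel("months of follow-up")
        ax.set_ylabel("progression-free proportion")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(ROOT / "km_curves.png", dpi=120)
        print(f"KM plot: {ROOT / 'km_curves.png'}")
    except Exception as exc:  # plotting is a convenience, not a result
        print(f"(KM plot skipped: {exc})")


if __name__ == "__main__":
    main()
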