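"""Bootstrap out-of-bag model comparison and nested spline tests.

Evaluates the candidate multivariate Cox models (each <= 3 covariates) by
B=200 bootstrap replicates: out-of-bag integrated time-dependent AUC and
training AIC, ranked by median iAUC with AIC tie-break.  Also runs the
nested spline-vs-linear anova for the winning model's covariates.
Writes results/model_ranking.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from importlib import import_module

from befish.cohort import apply_inclusion_filters
from befish.cox import compare_nested, fit_cox
from befish.pipeline import (NC_SET2_COLUMN, assemble_features,
                             default_candidate_models)
from befish.selection import bootstrap_evaluate, rank_models

load_cohort = import_module("02_diversity_markers").load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"
B = 200
SEED = 1


def main() -> None:
    cohort, _ = apply_inclusion_filters(load_cohort())
    div2 = pd.read_csv(ROOT / "diversity_set2_wide.csv",
                       index_col="patient_id")
    div1 = pd.read_csv(ROOT / "diversity_set1_wide.csv",
                       index_col="patient_id")
    collide = div1.columns.intersection(div2.columns)
    div = pd.concat([div1.rename(columns={c: f"{c}@set1" for c in collide}),
                     div2], axis=1)
    feat = assemble_features(cohort, diversity=div)
    out = cohort.outcomes_frame()

    candidates = default_candidate_models()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        evals = [bootstrap_evaluate(feat, out, spec, B=B, seed=SEED)
                 for spec in candidates]
    ranking = rank_models(evals)
    ranking.to_csv(ROOT / "model_ranking.csv", index=False)
    print(ranking.round(3).to_string(index=False))

    # spline-vs-linear anova for the clinical+NC model
    by_id = {s.spec_id: s for s in candidates}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lin = fit_cox(feat, out, by_id["clinical+NC_set2"])
        spl = fit_cox(feat, out, by_id["clinical_spline_age+NC_set2"])
    chi2, df, p = compare_nested(lin, spl)
    keep = "spline" if p <= 0.05 else "linear"
    print(f"\nspline-vs-linear (age), clinical+NC model: "
          f"chi2={chi2:.2f}, df={df}, p={p:.3f} -> keep {keep}")


if __name__ == "__main__":
    main()
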