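"""Univariate Cox screen of clinical, marker and diversity covariates.

For every candidate covariate fits a one-covariate Cox model and reports
HR, 95% CI, Wald and likelihood-ratio p-values; covariates with Wald
p <= 0.05 are retained, 0.05 < p <= 0.10 flagged borderline (still
eligible for multivariate modeling).  Writes results/univariate_screen.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from befish.cohort import apply_inclusion_filters
from befish.pipeline import (NC_SET1_3M_COLUMN, NC_SET2_COLUMN,
                             assemble_features, univariate_screen)

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

load_cohort = import_module("02_diversity_markers").load_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, _ = apply_inclusion_filters(load_cohort())
    div1 = pd.read_csv(ROOT / "diversity_set1_wide.csv",
                       index_col="patient_id")
    div2 = pd.read_csv(ROOT / "diversity_set2_wide.csv",
                       index_col="patient_id")
    collide = div1.columns.intersection(div2.columns)
    div = pd.concat([div1.rename(columns={c: f"{c}@set1" for c in collide}),
                     div2], axis=1)
    mks = pd.read_csv(ROOT / "marker_scores.csv", index_col="patient_id")
    feat = assemble_features(cohort, diversity=div, markers=mks)
    out = cohort.outcomes_frame()

    covs = (["age", "c_length", "m_length", "bmi"] + list(mks.columns)
            + [NC_SET2_COLUMN, NC_SET1_3M_COLUMN])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tbl = univariate_screen(feat, out, covs)
    tbl.to_csv(ROOT / "univariate_screen.csv", index=False)
    kept = tbl[tbl["status"].isin(["significant", "borderline"])]
    print(tbl.round(4).to_string(index=False))
    print(f"\nretained for multivariate modeling "
          f"({len(kept)}): {', '.join(kept['variable'])}")


if __name__ == "__main__":
    main()
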