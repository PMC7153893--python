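"""Compute clonal-diversity scores and individual marker scores.

Reads the cohort from results/cohort/, applies the inclusion filters,
computes the patient x (marker subset, index) diversity matrices for both
FISH panels (15 subsets x 5 indices each) and the individual marker /
aneusomy score table, and writes them under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from befish.cohort import (SET1, SET2, Cohort, apply_inclusion_filters,
                           read_cell_table, read_clinical_table)
from befish.diversity import diversity_matrix, diversity_matrix_tidy
from befish.markers import marker_score_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_cohort() -> Cohort:
    d = ROOT / "cohort"
    cells = (read_cell_table(d / "cells_set1.csv", SET1)
             + read_cell_table(d / "cells_set2.csv", SET2))
    clinical, outcomes = read_clinical_table(d / "clinical.csv")
    c = Cohort(cells=cells, clinical=clinical, outcomes=outcomes)
    c.validate()
    return c


def main() -> None:
    cohort = load_cohort()
    kept, log = apply_inclusion_filters(cohort)
    print(f"inclusion filters: kept {len(kept.clinical)} of "
          f"{len(cohort.clinical)} patients; exclusions: {len(log)}")
    log.to_csv(ROOT / "exclusions.csv", index=False)

    for panel in (SET1, SET2):
        mat = diversity_matrix(kept, panel)
        mat.to_csv(ROOT / f"diversity_{panel.panel_id}_wide.csv")
        diversity_matrix_tidy(mat, panel).to_csv(
            ROOT / f"diversity_{panel.panel_id}.csv", index=False)
        nc_col = f"normalized_clone:{'/'.join(panel.probes)}"
        print(f"{panel.panel_id}: {mat.shape[0]} patients x {mat.shape[1]} "
              f"columns; median 4-marker NC {mat[nc_col].median():.4f}")

    mks = marker_score_table(kept)
    mks.to_csv(ROOT / "marker_scores.csv")
    print("marker score medians (%):")
    print(mks.median().round(2).to_string())


if __name__ == "__main__":
    main()
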