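#!/usr/bin/env python
"""Leave-one-out selection of the retained SVD dimensionality Q.

Loads the planted cohort written by 01_simulate_cohorts.py, sweeps Q over
1..10, and tabulates the cross-validated canonical correlation per Q for the
planted score.  Expected picture: the CV correlation jumps to its plateau at
Q=1 (the planted signal is rank one) and stays flat — the argmax can land
anywhere on the plateau, which is why the downstream scripts also record Q.

Writes results/analysis/cv_selection.tsv.
"""

from pathlib import Path

import pandas as pd

from skelcca import align_subjects, load_behavior_table, load_skeleton_dataset, loocv_select_q

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohorts" / "planted"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    dataset = load_skeleton_dataset(COHORT / "features.nii.gz", COHORT / "mask.nii.gz")
    table = load_behavior_table(COHORT / "subjects.tsv", ["score"], ["age", "gender"])
    dataset, table = align_subjects(dataset, table)

    sel = loocv_select_q(dataset, table.score("score"), range(1, 11))
    df = pd.DataFrame(
        {"q": sorted(sel.cv_correlations),
         "cv_correlation": [sel.cv_correlations[q] for q in sorted(sel.cv_correlations)]}
    )
    df["selected"] = df["q"] == sel.selected_q
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "cv_selection.tsv", sep="\t", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    print(f"\nselected Q = {sel.selected_q} "
          f"(CV correlation {sel.cv_correlations[sel.selected_q]:.3f})")


if __name__ == "__main__":
    main()
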