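"""SVM-RFE panel selection between IUP and PUC.

Recursive feature elimination around an RBF-kernel support-vector
classifier ranks the whole quantified proteome by discriminative power;
the stratified cross-validated error curve picks the smallest panel at
the minimum error, and the panel is shortlisted by combining the
elimination order with the t-test FDR order.
"""

from pathlib import Path

import pandas as pd

from invpap import (
    choose_panel,
    read_abundance_table,
    read_metadata,
    shortlist_candidates,
    svm_rfe_rank,
)

SEED = 20260929
OUT = Path("results")


def main() -> None:
    m = read_abundance_table(OUT / "preprocessed.tsv", log_transformed=True)
    groups = read_metadata(OUT / "data" / "metadata.tsv")
    ttest = pd.read_csv(OUT / "ttest_IUP_vs_PUC.tsv", sep="\t")

    ranking = svm_rfe_rank(m, groups, "IUP", "PUC", cv_folds=5, seed=SEED)
    ranking.as_frame().to_csv(OUT / "feature_ranking.tsv", sep="\t", index=False)
    curve = pd.DataFrame(
        sorted(ranking.error_curve.items()), columns=["panel_size", "cv_error"]
    )
    curve.to_csv(OUT / "error_curve.tsv", sep="\t", index=False)

    panel = choose_panel(ranking)
    err = ranking.error_curve[ranking.chosen_panel_size]
    print(f"minimum CV error {err:.1%} reached at panel size "
          f"{ranking.chosen_panel_size} (of {len(ranking.ordered_proteins)} proteins)")

    shortlist = shortlist_candidates(ranking, ttest, k=5)
    pd.DataFrame({"rank": range(1, len(shortlist) + 1), "protein": shortlist}).to_csv(
        OUT / "shortlist.tsv", sep="\t", index=False
    )
    print(f"panel: {', '.join(panel[:10])}{' ...' if len(panel) > 10 else ''}")
    print(f"shortlist (ML rank + t-test FDR): {', '.join(shortlist)}")

    truth = pd.read_csv(OUT / "data" / "abundance_truth.tsv", sep="\t").set_index("protein")
    planted_top = sum(
        truth.at[p, "true_class"] != "background" for p in ranking.ordered_proteins[:10]
    )
    print(f"{planted_top} of the top 10 ranked proteins are planted markers")


if __name__ == "__main__":
    main()
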