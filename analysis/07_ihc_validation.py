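"""IHC validation statistics on the independent cohort.

Per-specimen H-scores from the per-cell intensity bins, Mann-Whitney
comparison of IUP vs PUC with inverted growth, AUROC, the
Youden-optimal H-score cutoff, and Clopper-Pearson exact 95% CIs for
sensitivity and specificity at that cutoff.
"""

from pathlib import Path

from invpap import hscores_by_specimen, ihc_validation_report, mannwhitney_compare
from invpap.ihc import read_cell_table

OUT = Path("results")


def main() -> None:
    cells = read_cell_table(OUT / "data" / "ihc_cells.csv")
    hs = hscores_by_specimen(cells)
    hs.to_csv(OUT / "hscores.tsv", sep="\t", index=False)
    med = hs.groupby("diagnosis")["h_score"].median()
    print("median H-scores: "
          + ", ".join(f"{d} {v:.0f}" for d, v in med.items()))

    u, p = mannwhitney_compare(
        hs["h_score"], hs["diagnosis"], "IUP", "PUC_inverted"
    )
    print(f"Mann-Whitney U = {u:.0f}, two-sided p = {p:.2e}")

    roc = ihc_validation_report(hs)
    print(f"AUROC {roc.auc:.3f} (p = {roc.p_value:.2e} vs 0.5)")
    print(f"Youden-optimal cutoff: H-score {roc.cutoff:.1f}")
    print(f"sensitivity {roc.sensitivity:.0f}% "
          f"(95% CI {roc.sens_ci[0]:.1f}-{roc.sens_ci[1]:.1f}%), "
          f"specificity {roc.specificity:.0f}% "
          f"(95% CI {roc.spec_ci[0]:.1f}-{roc.spec_ci[1]:.1f}%)")

    with open(OUT / "ihc_validation.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"mannwhitney_U\t{u}\nmannwhitney_p\t{p}\n")
        fh.write(f"auroc\t{roc.auc}\nauroc_p\t{roc.p_value}\n")
        fh.write(f"cutoff\t{roc.cutoff}\n")
        fh.write(f"sensitivity_pct\t{roc.sensitivity}\n")
        fh.write(f"sens_ci_low\t{roc.sens_ci[0]}\nsens_ci_high\t{roc.sens_ci[1]}\n")
        fh.write(f"specificity_pct\t{roc.specificity}\n")
        fh.write(f"spec_ci_low\t{roc.spec_ci[0]}\nspec_ci_high\t{roc.spec_ci[1]}\n")


if __name__ == "__main__":
    main()
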