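"""Differential expression with permutation FDR.

One-way permutation ANOVA across IUP/PUC/NU defines the differentially
expressed proteins (DEPs); the two-group permutation t-test between IUP
and PUC feeds the later biomarker shortlist.  Both use 1,000 label
permutations and control the FDR at q < 0.05.
"""

from pathlib import Path

from invpap import (
    PermutationConfig,
    permutation_anova,
    permutation_ttest,
    read_abundance_table,
    read_metadata,
)

SEED = 20260929
OUT = Path("results")


def main() -> None:
    m = read_abundance_table(OUT / "preprocessed.tsv", log_transformed=True)
    groups = read_metadata(OUT / "data" / "metadata.tsv")
    cfg = PermutationConfig(n_permutations=1000, seed=SEED)

    anova = permutation_anova(m, groups, cfg, ("IUP", "PUC", "NU"))
    anova.to_csv(OUT / "anova.tsv", sep="\t", index=False)
    print(f"ANOVA: {int(anova['significant'].sum())} DEPs of {len(anova)} "
          f"proteins at q < {cfg.fdr_level}")

    ttest = permutation_ttest(m, groups, "IUP", "PUC", cfg)
    ttest.to_csv(OUT / "ttest_IUP_vs_PUC.tsv", sep="\t", index=False)
    up = int(((ttest["significant"]) & (ttest["log2_fc"] > 0)).sum())
    down = int(((ttest["significant"]) & (ttest["log2_fc"] < 0)).sum())
    print(f"IUP vs PUC t-test: {up} proteins higher in IUP, {down} higher in PUC "
          f"at q < {cfg.fdr_level}")


if __name__ == "__main__":
    main()
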