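"""Generate the synthetic study cohorts.

Writes every input the discovery workflow consumes, at the study's
scale: a 31-sample discovery proteome (9 IUP / 12 PUC / 10 NU, 5,000
proteins, 40 planted markers per signature class, MNAR dropout), a
41-specimen IHC validation cohort (25 IUP / 16 PUC with inverted
growth), a 405-patient survival cohort, and antibody staining profiles
for the planted markers (a few deliberately discordant with the
proteomic fold change, so the concordance screen has something to
exclude).  Ground-truth sidecars record what was planted.
"""

from pathlib import Path

from invpap import (
    AbundanceSimSpec,
    IhcSimSpec,
    SurvivalSimSpec,
    simulate_abundance,
    simulate_hpa_profiles,
    simulate_ihc,
    simulate_survival,
)
from invpap.simulate import profiles_to_frame

SEED = 20260929
DATA = Path("results/data")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    spec = AbundanceSimSpec(seed=SEED)  # 5,000 proteins, 40 planted per class
    m, groups, truth = simulate_abundance(spec)
    table = m.data.copy()
    table.index.name = "protein"
    table.to_csv(DATA / "abundance.tsv", sep="\t", na_rep="NA")
    groups.rename_axis("sample_id").reset_index().to_csv(
        DATA / "metadata.tsv", sep="\t", index=False
    )
    truth.to_csv(DATA / "abundance_truth.tsv", sep="\t", index=False)
    missing = float(m.data.isna().to_numpy().mean())
    print(f"discovery proteome: {m.n_proteins} proteins x {m.n_samples} samples, "
          f"{missing:.1%} missing, planted {int((truth['true_class'] != 'background').sum())} markers")

    # staining profiles for the planted markers; two of the IUP-overexpressed
    # ones get atlas profiles contradicting the proteome
    planted = truth[truth["true_class"] != "background"]
    up = planted.loc[planted["true_class"] == "NU_like_up", "protein"].tolist()
    regimes = {p: "concordant" for p in planted["protein"]}
    for p in up[:2]:
        regimes[p] = "discordant"
    profiles, hpa_truth, _ = simulate_hpa_profiles(
        planted["protein"].tolist(), regimes, seed=SEED + 1
    )
    profiles_to_frame(profiles).to_csv(DATA / "hpa_profiles.tsv", sep="\t", index=False)
    hpa_truth.to_csv(DATA / "hpa_truth.tsv", sep="\t", index=False)
    n_disc = sum(r == "discordant" for r in regimes.values())
    print(f"staining profiles: {len(profiles)} proteins, {n_disc} planted discordant")

    # validation cohort with per-specimen staining heterogeneity so the
    # H-score distributions overlap like real cohorts do
    ihc_spec = IhcSimSpec(seed=SEED + 2, dirichlet_concentration=15.0)
    cells, ihc_truth = simulate_ihc(ihc_spec)
    cells.to_csv(DATA / "ihc_cells.csv", index=False)
    ihc_truth.to_csv(DATA / "ihc_truth.tsv", sep="\t", index=False)
    print(f"IHC cohort: {cells['specimen_id'].nunique()} specimens, "
          f"{ihc_spec.cells_per_specimen} cells each; expected H-scores "
          f"{ihc_truth['expected_h_score'].tolist()}")

    # survival cohort: six genes of interest, two prognostic
    surv_spec = SurvivalSimSpec(
        seed=SEED + 3,
        log_hr={"OGDH_like": 0.38, "PYGB_like": 0.25, "NULL_1": 0.0,
                "NULL_2": 0.0, "NULL_3": 0.0, "NULL_4": 0.0},
    )
    cohort = simulate_survival(surv_spec)
    cohort.to_csv(DATA / "survival.tsv", sep="\t", index=False)
    print(f"survival cohort: {len(cohort)} patients, "
          f"{int(cohort['event'].sum())} events "
          f"({1 - cohort['event'].mean():.0%} censored)")


if __name__ == "__main__":
    main()
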