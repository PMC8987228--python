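import numpy as np
import pandas as pd
import pytest

from invpap import (
    AbundanceMatrix,
    AbundanceSimSpec,
    PermutationConfig,
    PreprocessConfig,
    filter_by_presence,
    impute_missing,
    log_and_normalize,
    simulate_abundance,
)

SIG_CLASSES = ("NU_like_up", "NU_like_down", "PUC_like_up", "PUC_like_down")


def matrix_from_array(values, log_transformed=True, prefix="P", samples=None):
    """Build an AbundanceMatrix from a 2-D array (proteins x samples)."""
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i + 1:03d}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"S{j + 1:02d}" for j in range(values.shape[1])]
    return AbundanceMatrix(
        pd.DataFrame(values, index=ids, columns=samples), log_transformed=log_transformed
    )


def two_group_matrix(rng, n_proteins=20, n_a=5, n_b=5, shift=None, prefix="P"):
    """i.i.d. normal matrix with group labels A/B; optional per-protein shift
    added to group A."""
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    X = rng.normal(0.0, 1.0, (n_proteins, n_a + n_b))
    if shift is not None:
        X[:, :n_a] += np.asarray(shift)[:, None]
    m = matrix_from_array(X, samples=samples, prefix=prefix)
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return m, groups


@pytest.fixture(scope="session")
def small_sim():
    """Small planted discovery cohort shared across tests: 300 proteins,
    10 planted per class, study group sizes, preprocessed and imputed."""
    spec = AbundanceSimSpec(
        n_proteins=300,
        planted_counts={c: 10 for c in SIG_CLASSES},
        seed=11,
    )
    m_raw, groups, truth = simulate_abundance(spec)
    cfg = PreprocessConfig(seed=11)
    m = impute_missing(log_and_normalize(filter_by_presence(m_raw, cfg), cfg), cfg)
    return {"raw": m_raw, "matrix": m, "groups": groups, "truth": truth, "spec": spec}


@pytest.fixture()
def perm_cfg():
    return PermutationConfig(n_permutations=1000, seed=5)


def write_bundle(root, seed=13, n_proteins=200):
    """Write a complete synthetic input bundle and return its RunConfig.

    Planted NU-like-up proteins (higher in IUP than PUC, like the
    glycogen-phosphorylase marker the screen is meant to find) get
    concordant staining profiles except two planted discordant ones.
    """
    from invpap import (
        IhcSimSpec,
        RunConfig,
        SurvivalSimSpec,
        simulate_hpa_profiles,
        simulate_ihc,
        simulate_survival,
    )
    from invpap.simulate import profiles_to_frame

    root.mkdir(parents=True, exist_ok=True)
    spec = AbundanceSimSpec(
        n_proteins=n_proteins,
        planted_counts={c: 10 for c in SIG_CLASSES},
        seed=seed,
    )
    m, groups, truth = simulate_abundance(spec)
    data = m.data.copy()
    data.index.name = "protein"
    data.to_csv(root / "abundance.tsv", sep="\t", na_rep="NA")
    groups.rename_axis("sample_id").reset_index().to_csv(
        root / "metadata.tsv", sep="\t", index=False
    )
    truth.to_csv(root / "truth.tsv", sep="\t", index=False)

    up = truth.loc[truth["true_class"] == "NU_like_up", "protein"].tolist()
    others = truth.loc[
        truth["true_class"].isin(["NU_like_down", "PUC_like_up", "PUC_like_down"]),
        "protein",
    ].tolist()
    regimes = {p: "concordant" for p in up + others}
    for p in up[:2]:
        regimes[p] = "discordant"
    profiles, _, _ = simulate_hpa_profiles(up + others, regimes, seed=seed + 1)
    profiles_to_frame(profiles).to_csv(root / "hpa_profiles.tsv", sep="\t", index=False)

    cells, _ = simulate_ihc(IhcSimSpec(seed=seed + 2))
    cells.to_csv(root / "ihc_cells.csv", index=False)

    surv = simulate_survival(
        SurvivalSimSpec(seed=seed + 3, log_hr={"GENE_A": 0.25, "GENE_B": 0.0})
    )
    surv.to_csv(root / "survival.tsv", sep="\t", index=False)

    return RunConfig(
        abundance_path=str(root / "abundance.tsv"),
        metadata_path=str(root / "metadata.tsv"),
        out_dir=str(root / "out"),
        hpa_profiles_path=str(root / "hpa_profiles.tsv"),
        ihc_cells_path=str(root / "ihc_cells.csv"),
        survival_path=str(root / "survival.tsv"),
        survival_genes=["GENE_A", "GENE_B"],
        preprocess=PreprocessConfig(seed=seed),
        permutation=PermutationConfig(seed=seed),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full discovery run on the default synthetic bundle, shared by
    the end-to-end and acceptance tests."""
    from invpap import run_pipeline

    root = tmp_path_factory.mktemp("bundle")
    cfg = write_bundle(root)
    result = run_pipeline(cfg)
    return root, cfg, result
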