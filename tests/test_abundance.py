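"""Abundance matrix I/O, presence filtering, transformation, imputation
and PCA embedding."""

import numpy as np
import pandas as pd
import pytest

from invpap import (
    AbundanceMatrix,
    ParseError,
    PreprocessConfig,
    ValidationError,
    filter_by_presence,
    impute_missing,
    log_and_normalize,
    pca_embed,
    read_abundance_table,
)

from conftest import matrix_from_array


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadAbundanceTable:
    def test_parses_small_table_with_missing_cell(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            "protein\tS1\tS2\nA\t1.5\t2.0\nB\tNA\t3.0\nC\t4.0\t5.0\n",
        )
        m = read_abundance_table(p)
        assert m.values.shape == (3, 2)
        assert np.isnan(m.data.loc["B", "S1"])
        assert m.data.notna().sum().sum() == 5

    def test_configurable_missing_tokens(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", "protein\tS1\nA\t0\nB\t2\n")
        m = read_abundance_table(p, missing_tokens={"0"})
        assert np.isnan(m.data.loc["A", "S1"])

    @pytest.mark.parametrize(
        "content,err,fragment",
        [
            ("", ParseError, "empty"),
            ("protein\tS1\tS2\nA\t1.0\n", ParseError, "line 2"),
            ("protein\tS1\nA\tx1\n", ParseError, "line 2"),
            ("protein\tS1\nA\t1\nA\t2\n", ValidationError, "duplicate"),
        ],
    )
    def test_malformed_input_rejected(self, tmp_path, content, err, fragment):
        p = write_tsv(tmp_path / "t.tsv", content)
        with pytest.raises(err, match=fragment):
            read_abundance_table(p)


class TestPresenceFilter:
    def test_inclusive_boundary_and_strict_removal(self):
        # 2/10 = 0.20 passes the >=20% rule; 6/31 ~ 0.194 does not
        row_keep = [1.0] * 2 + [np.nan] * 8
        m = matrix_from_array([row_keep], log_transformed=False)
        cfg = PreprocessConfig()
        assert filter_by_presence(m, cfg).n_proteins == 1

        row_drop = [1.0] * 6 + [np.nan] * 25
        m31 = matrix_from_array([row_drop], log_transformed=False)
        assert filter_by_presence(m31, cfg).n_proteins == 0

    def test_planted_presence_counts(self):
        # presence counts {31, 7, 6, 0} of 31 -> exactly 2 proteins survive
        rows = []
        for count in (31, 7, 6, 0):
            rows.append([1.0] * count + [np.nan] * (31 - count))
        m = matrix_from_array(rows, log_transformed=False)
        kept = filter_by_presence(m, PreprocessConfig())
        assert kept.protein_ids == ["P001", "P002"]

    def test_idempotent_and_order_preserving(self, small_sim):
        cfg = PreprocessConfig()
        once = filter_by_presence(small_sim["raw"], cfg)
        twice = filter_by_presence(once, cfg)
        assert once.protein_ids == twice.protein_ids
        order = {p: i for i, p in enumerate(small_sim["raw"].protein_ids)}
        assert sorted(once.protein_ids, key=order.__getitem__) == once.protein_ids
        frac = once.presence_counts() / once.n_samples
        assert (frac >= cfg.min_presence_fraction).all()

    def test_empty_matrix_rejected(self):
        m = AbundanceMatrix(pd.DataFrame(dtype=float))
        with pytest.raises(ValidationError):
            filter_by_presence(m, PreprocessConfig())


class TestLogAndNormalize:
    def test_closed_form_median_centering(self):
        m = matrix_from_array([[4.0], [16.0]], log_transformed=False)
        out = log_and_normalize(m, PreprocessConfig())
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_round_trip_without_normalization(self, rng=np.random.default_rng(3)):
        vals = rng.lognormal(3, 1, (15, 6))
        m = matrix_from_array(vals, log_transformed=False)
        out = log_and_normalize(m, PreprocessConfig(normalization="none"))
        np.testing.assert_allclose(np.power(2.0, out.values), vals, rtol=1e-12)

    def test_column_medians_zero_after_centering(self, small_sim):
        cfg = PreprocessConfig()
        out = log_and_normalize(filter_by_presence(small_sim["raw"], cfg), cfg)
        medians = out.data.median(axis=0, skipna=True)
        np.testing.assert_allclose(medians.to_numpy(), 0.0, atol=1e-12)

    def test_nonpositive_value_rejected(self):
        m = matrix_from_array([[0.0, 2.0]], log_transformed=False)
        with pytest.raises(ValidationError):
            log_and_normalize(m, PreprocessConfig())

    def test_missingness_pattern_unchanged(self, small_sim):
        cfg = PreprocessConfig()
        filtered = filter_by_presence(small_sim["raw"], cfg)
        out = log_and_normalize(filtered, cfg)
        assert (out.data.isna() == filtered.data.isna()).all().all()


class TestImputeMissing:
    def test_complete_matrix_returned_unchanged(self):
        m = matrix_from_array([[1.0, 2.0], [3.0, 4.0]])
        out = impute_missing(m, PreprocessConfig())
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_deterministic_under_seed(self, small_sim):
        cfg = PreprocessConfig(seed=42)
        logged = log_and_normalize(filter_by_presence(small_sim["raw"], cfg), cfg)
        a = impute_missing(logged, cfg)
        b = impute_missing(logged, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_present_values_untouched(self, small_sim):
        cfg = PreprocessConfig(seed=1)
        logged = log_and_normalize(filter_by_presence(small_sim["raw"], cfg), cfg)
        out = impute_missing(logged, cfg)
        mask = logged.data.notna()
        pd.testing.assert_frame_equal(out.data[mask], logged.data[mask])

    def test_downshifted_distribution_recovered(self):
        # one large column, 50% missing: imputed mean ~ mean - 1.8 SD
        rng = np.random.default_rng(0)
        present = rng.normal(20.0, 2.0, 4000)
        col = np.concatenate([present, np.full(4000, np.nan)])
        m = matrix_from_array(col[:, None])
        cfg = PreprocessConfig(seed=9, impute_width=0.3, impute_downshift=1.8)
        out = impute_missing(m, cfg)
        imputed = out.values[4000:, 0]
        mu, sd = present.mean(), present.std(ddof=1)
        se = cfg.impute_width * sd / np.sqrt(4000)
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se

    def test_sparse_column_falls_back_to_global(self):
        col0 = [5.0, np.nan, np.nan, np.nan]
        col1 = [5.0, 6.0, 7.0, 8.0]
        m = matrix_from_array(np.column_stack([col0, col1]))
        out = impute_missing(m, PreprocessConfig(seed=0))
        assert out.is_complete()


class TestPcaEmbed:
    def test_identical_samples_have_identical_coordinates(self):
        col = np.arange(10.0)
        m = matrix_from_array(np.column_stack([col, col, col + 5]))
        coords, _ = pca_embed(m, 2)
        np.testing.assert_allclose(
            coords.iloc[0].to_numpy(), coords.iloc[1].to_numpy(), atol=1e-9
        )

    def test_explained_variance_sorted_and_bounded(self, small_sim):
        _, evr = pca_embed(small_sim["matrix"], 5)
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-9

    def test_distances_invariant_to_protein_order(self, small_sim):
        m = small_sim["matrix"]
        coords, _ = pca_embed(m, 2)
        shuffled = AbundanceMatrix(
            m.data.sample(frac=1, random_state=4), log_transformed=True
        )
        coords2, _ = pca_embed(shuffled, 2)
        d1 = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None], axis=2)
        d2 = np.linalg.norm(coords2.to_numpy()[:, None] - coords2.to_numpy()[None], axis=2)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_planted_group_geometry(self, small_sim):
        # IUP was planted to share half its shifts with each tumor class but
        # the PUC-like classes dominate none; check IUP sits between, i.e.
        # IUP<->PUC and IUP<->NU both closer than PUC<->NU on PC1-2
        coords, _ = pca_embed(small_sim["matrix"], 2)
        groups = small_sim["groups"]
        centroid = {g: coords.loc[groups[groups == g].index].mean() for g in ("IUP", "PUC", "NU")}
        d = lambda a, b: np.linalg.norm(centroid[a] - centroid[b])
        assert d("IUP", "PUC") < d("PUC", "NU")
        assert d("IUP", "NU") < d("PUC", "NU")

    def test_missing_values_rejected(self, small_sim):
        cfg = PreprocessConfig()
        filtered = filter_by_presence(small_sim["raw"], cfg)
        with pytest.raises(ValidationError):
            pca_embed(log_and_normalize(filtered, cfg))
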