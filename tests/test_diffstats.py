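"""Permutation t-test / ANOVA statistics and the SAM-style FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invpap import (
    PermutationConfig,
    ValidationError,
    fold_change,
    permutation_anova,
    permutation_ttest,
)

from conftest import matrix_from_array, two_group_matrix


def three_group_matrix(rng, n_proteins, sizes=(4, 4, 4), shift=None):
    samples = (
        [f"I{i}" for i in range(sizes[0])]
        + [f"P{i}" for i in range(sizes[1])]
        + [f"N{i}" for i in range(sizes[2])]
    )
    X = rng.normal(0.0, 1.0, (n_proteins, sum(sizes)))
    if shift is not None:
        X[:, : sizes[0]] += np.asarray(shift)[:, None]
    m = matrix_from_array(X, samples=samples)
    groups = pd.Series(
        ["IUP"] * sizes[0] + ["PUC"] * sizes[1] + ["NU"] * sizes[2], index=samples
    )
    return m, groups


class TestPermutationTtest:
    def test_zero_effect_protein(self, perm_cfg):
        X = np.vstack([np.tile([1.0, 2.0, 3.0], 2)])
        m = matrix_from_array(X, samples=["A1", "A2", "A3", "B1", "B2", "B3"])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=m.sample_ids)
        res = permutation_ttest(m, groups, "A", "B", perm_cfg)
        assert res.loc[0, "statistic"] == 0.0
        assert res.loc[0, "p_raw"] == 1.0
        assert not res.loc[0, "significant"]

    def test_p_floor_at_full_separation(self, perm_cfg):
        rng = np.random.default_rng(1)
        m, groups = two_group_matrix(rng, n_proteins=5, n_a=10, n_b=10,
                                     shift=np.full(5, 50.0))
        res = permutation_ttest(m, groups, "A", "B", perm_cfg)
        floor = 1.0 / (1 + perm_cfg.n_permutations)
        assert (res["p_raw"] == floor).all()

    def test_matches_exhaustive_enumeration_for_tiny_groups(self):
        # full enumeration of the two-sided permutation distribution
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 6)
        vals[:3] += 1.5
        m = matrix_from_array(vals[None, :], samples=[f"S{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=m.sample_ids)

        def welch(a, b):
            return (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)

        obs = abs(welch(vals[:3], vals[3:]))
        perm_stats = []
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            perm_stats.append(abs(welch(vals[list(comb)], vals[rest])))
        exact_p = np.mean([s >= obs - 1e-12 for s in perm_stats])

        cfg = PermutationConfig(n_permutations=20000, seed=0)
        res = permutation_ttest(m, groups, "A", "B", cfg)
        assert res.loc[0, "p_raw"] == pytest.approx(exact_p, abs=0.02)

    def test_deterministic_under_seed(self, perm_cfg):
        rng = np.random.default_rng(3)
        m, groups = two_group_matrix(rng, n_proteins=30, n_a=4, n_b=5)
        a = permutation_ttest(m, groups, "A", "B", perm_cfg)
        b = permutation_ttest(m, groups, "A", "B", perm_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_qvalues_monotone_in_statistic(self, perm_cfg):
        rng = np.random.default_rng(4)
        shift = np.concatenate([np.full(10, 3.0), np.zeros(40)])
        m, groups = two_group_matrix(rng, n_proteins=50, n_a=5, n_b=5, shift=shift)
        res = permutation_ttest(m, groups, "A", "B", perm_cfg)
        ordered = res.reindex(res["statistic"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["q_value"].to_numpy()) >= -1e-12).all()

    def test_qvalues_invariant_to_protein_order(self, perm_cfg):
        rng = np.random.default_rng(5)
        shift = np.concatenate([np.full(5, 3.0), np.zeros(25)])
        m, groups = two_group_matrix(rng, n_proteins=30, n_a=5, n_b=5, shift=shift)
        res = permutation_ttest(m, groups, "A", "B", perm_cfg).set_index("protein")
        from invpap import AbundanceMatrix

        shuffled = AbundanceMatrix(m.data.sample(frac=1, random_state=8), log_transformed=True)
        res2 = permutation_ttest(shuffled, groups, "A", "B", perm_cfg).set_index("protein")
        pd.testing.assert_series_equal(
            res["q_value"], res2["q_value"].reindex(res.index)
        )

    def test_null_pvalues_not_anticonservative(self):
        # under the global null the p-value distribution must not pile up
        # near zero: check the fraction below alpha stays near alpha
        rng = np.random.default_rng(6)
        m, groups = two_group_matrix(rng, n_proteins=400, n_a=6, n_b=6)
        res = permutation_ttest(m, groups, "A", "B", PermutationConfig(seed=7))
        assert (res["p_raw"] <= 0.05).mean() < 0.10

    def test_small_group_rejected(self, perm_cfg):
        rng = np.random.default_rng(7)
        m, groups = two_group_matrix(rng, n_proteins=3, n_a=1, n_b=5)
        with pytest.raises(ValidationError):
            permutation_ttest(m, groups, "A", "B", perm_cfg)


class TestPermutationAnova:
    def test_null_proteins_not_significant(self, perm_cfg):
        rng = np.random.default_rng(8)
        m, groups = three_group_matrix(rng, n_proteins=50)
        res = permutation_anova(m, groups, perm_cfg)
        assert int(res["significant"].sum()) <= 2

    def test_shifted_group_detected(self, perm_cfg):
        rng = np.random.default_rng(9)
        shift = np.concatenate([np.full(5, 6.0), np.zeros(45)])
        m, groups = three_group_matrix(rng, 50, sizes=(5, 5, 5), shift=shift)
        res = permutation_anova(m, groups, perm_cfg)
        assert res.loc[:4, "significant"].all()

    def test_agrees_with_parametric_f_test(self):
        rng = np.random.default_rng(10)
        m, groups = three_group_matrix(rng, 20, sizes=(6, 6, 6))
        cfg = PermutationConfig(n_permutations=10000, seed=11)
        res = permutation_anova(m, groups, cfg)
        X = m.values
        f_p = [
            stats.f_oneway(X[i, :6], X[i, 6:12], X[i, 12:]).pvalue for i in range(20)
        ]
        np.testing.assert_allclose(res["p_raw"], f_p, atol=0.05)

    def test_two_groups_rejected(self, perm_cfg):
        rng = np.random.default_rng(12)
        m, groups = two_group_matrix(rng, n_proteins=5, n_a=3, n_b=3)
        with pytest.raises(ValidationError):
            permutation_anova(m, groups, perm_cfg)


class TestFoldChange:
    def test_mean_difference_and_identity(self):
        m = matrix_from_array(
            [[5.0, 5.0, 3.0, 3.0], [2.0, 2.0, 2.0, 2.0]],
            samples=["A1", "A2", "B1", "B2"],
        )
        groups = pd.Series(["A", "A", "B", "B"], index=m.sample_ids)
        fc = fold_change(m, groups, "A", "B")
        assert fc.iloc[0] == pytest.approx(2.0)
        assert fc.iloc[1] == pytest.approx(0.0)

    def test_antisymmetry(self, small_sim):
        m, groups = small_sim["matrix"], small_sim["groups"]
        ab = fold_change(m, groups, "IUP", "PUC")
        ba = fold_change(m, groups, "PUC", "IUP")
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy(), atol=1e-12)

    def test_group_absent_protein_flagged_nan(self):
        m = matrix_from_array(
            [[np.nan, np.nan, 3.0, 4.0]], samples=["A1", "A2", "B1", "B2"]
        )
        groups = pd.Series(["A", "A", "B", "B"], index=m.sample_ids)
        fc = fold_change(m, groups, "A", "B")
        assert np.isnan(fc.iloc[0])

    def test_requires_log_scale(self):
        m = matrix_from_array([[1.0, 2.0]], log_transformed=False, samples=["A1", "B1"])
        groups = pd.Series(["A", "B"], index=m.sample_ids)
        with pytest.raises(ValidationError):
            fold_change(m, groups, "A", "B")
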