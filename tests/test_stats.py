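"""Normalization, signed-rank inference, comparison, PCA and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonequant import (
    DataError,
    compare_groups,
    hclust_order,
    log2_transform,
    paired_wilcoxon,
    pca_embed,
    proteome_coverage,
    zscore_per_sample,
)

from conftest import make_design, make_matrix

NA = np.nan


class TestLog2:
    def test_elementwise_values_and_missing_preserved(self):
        m = make_matrix([[8.0, 1.0, NA]])
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert np.isnan(out.values.iloc[0, 2])
        assert out.scale == "log2"

    def test_nonpositive_observed_value_rejected(self):
        m = make_matrix([[4.0, 0.0]])
        with pytest.raises(DataError, match="missing at ingest"):
            log2_transform(m)

    def test_requires_raw_scale(self):
        m = make_matrix([[1.0]], scale="log2")
        with pytest.raises(ValueError):
            log2_transform(m)


class TestZscore:
    def test_column_contract(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(20, 3, (10, 4)), scale="log2")
        out = zscore_per_sample(m)
        assert out.scale == "zscored"
        for col in out.values:
            assert abs(out.values[col].mean()) < 1e-12
            assert abs(out.values[col].std(ddof=1) - 1) < 1e-12

    def test_three_point_column(self):
        m = make_matrix([[1.0], [2.0], [3.0]], scale="log2")
        out = zscore_per_sample(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_named_in_error(self):
        m = make_matrix([[1.0, 1.0], [1.0, 2.0]], scale="log2",
                        samples=["flat", "ok"])
        with pytest.raises(DataError, match="flat"):
            zscore_per_sample(m)


def brute_force_wilcoxon_p(d):
    """Full 2^n enumeration oracle with the symmetric-distance definition."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestPairedWilcoxon:
    def test_five_positive_differences(self):
        res = paired_wilcoxon([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.tested
        assert res.p == pytest.approx(0.0625)

    def test_identical_vectors_untested(self):
        res = paired_wilcoxon([1, 2, 3, 4], [1, 2, 3, 4])
        assert not res.tested and res.p is None

    def test_eight_pair_toy_matches_enumeration(self):
        x = np.array([3.0, 1.2, 5.5, 2.2, 4.1, 0.3, 2.9, 3.3])
        y = np.array([2.0, 1.9, 5.0, 2.0, 4.4, 0.1, 2.1, 3.9])
        res = paired_wilcoxon(x, y)
        assert res.p == pytest.approx(brute_force_wilcoxon_p(x - y))

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = np.round(rng.normal(0, 1, n), 2)
        d[d == 0] = 0.5
        res = paired_wilcoxon(d, np.zeros(n))
        assert res.p == pytest.approx(brute_force_wilcoxon_p(d))

    def test_agrees_with_scipy_exact_when_untied(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0, 1, 10)  # continuous: no ties, no zeros
        res = paired_wilcoxon(d, np.zeros(10))
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue)

    def test_normal_branch_close_to_scipy(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.4, 1, 40)
        res = paired_wilcoxon(d, np.zeros(40))
        ref = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=True)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_pairs_removed(self):
        x = [1, 2, NA, 4, 5, 6]
        y = [0, 1, 1, NA, 4, 5]
        res = paired_wilcoxon(x, y)
        assert res.n_used == 4


class TestCompareGroups:
    def _matrices(self, n_donors=6, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        design = make_design(n_donors)
        feats = [f"P{i}" for i in range(4)]
        runs_a = list(design.loc[design["group"] == "arm_a", "run_id"])
        runs_b = list(design.loc[design["group"] == "arm_b", "run_id"])
        base = rng.normal(20, 1, (4, n_donors))
        noise = rng.normal(0, 0.3, (4, n_donors))
        ma = make_matrix(base, scale="log2", features=feats, samples=runs_a)
        mb = make_matrix(base + noise + effect, scale="log2", features=feats,
                         samples=runs_b)
        return ma, mb, design

    def test_identical_arms_give_no_significance(self):
        design = make_design(4)
        runs_a = list(design.loc[design["group"] == "arm_a", "run_id"])
        runs_b = list(design.loc[design["group"] == "arm_b", "run_id"])
        vals = np.arange(12, dtype=float).reshape(3, 4) + 1
        ma = make_matrix(vals, scale="log2", samples=runs_a)
        mb = make_matrix(vals, scale="log2", samples=runs_b)
        rep = compare_groups(ma, mb, design, "arm_a", "arm_b")
        assert rep.summary["n_significant"] == 0
        assert rep.summary["n_tested"] == 0  # all differences are zero

    def test_antisymmetry(self):
        ma, mb, design = self._matrices(effect=0.5, seed=3)
        ab = compare_groups(ma, mb, design, "arm_a", "arm_b")
        ba = compare_groups(mb, ma, design, "arm_b", "arm_a")
        pd.testing.assert_series_equal(ab.per_feature["p"], ba.per_feature["p"])
        # the winning arm keeps its label; the a/b bookkeeping swaps
        assert (ab.per_feature["direction"] == ba.per_feature["direction"]).all()
        assert ab.summary["higher_in_a"] == ba.summary["higher_in_b"]
        assert ab.summary["higher_in_b"] == ba.summary["higher_in_a"]

    def test_counts_compose_from_per_feature_tests(self):
        ma, mb, design = self._matrices(effect=1.0, seed=4)
        rep = compare_groups(ma, mb, design, "arm_a", "arm_b", alpha=0.10)
        manual = 0
        for f in rep.per_feature.index:
            res = paired_wilcoxon(ma.values.loc[f], mb.values.loc[f])
            if res.tested and res.p < 0.10:
                manual += 1
        assert rep.summary["n_significant"] == manual
        assert (rep.summary["higher_in_a"] + rep.summary["higher_in_b"]
                <= rep.summary["n_significant"])

    def test_shared_features_are_intersection(self):
        ma, mb, design = self._matrices()
        mb2 = mb.subset_features(["P0", "P2"])
        rep = compare_groups(ma, mb2, design, "arm_a", "arm_b")
        assert list(rep.per_feature.index) == ["P0", "P2"]

    def test_disjoint_features_error(self):
        ma, mb, design = self._matrices()
        mb2 = mb.copy()
        mb2.values.index = [f"X{i}" for i in range(4)]
        with pytest.raises(ValueError, match="shared"):
            compare_groups(ma, mb2, design, "arm_a", "arm_b")


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 5)
        vals = np.column_stack([col, col, rng.normal(0, 1, 5)])
        m = make_matrix(vals, scale="log2")
        res = pca_embed(m)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[1],
                                   atol=1e-10)

    def test_variance_explained_sums_to_hundred(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(0, 1, (6, 5)), scale="log2")
        total = pca_embed(m).variance_explained_pct.sum()
        assert abs(total - 100.0) < 1e-9

    def test_two_feature_principal_axis(self):
        """Closed-form 2x2 eigenproblem: equal variances with correlation
        rho > 0 put the first axis along (1,1)/sqrt(2)."""
        rng = np.random.default_rng(3)
        shared = rng.normal(0, 1, 200)
        f1 = shared + rng.normal(0, 0.3, 200)
        f2 = shared + rng.normal(0, 0.3, 200)
        m = make_matrix(np.vstack([f1, f2]), scale="log2")
        res = pca_embed(m)
        x = np.vstack([f1 - f1.mean(), f2 - f2.mean()])
        proj = (x[0] + x[1]) / np.sqrt(2)
        r = np.corrcoef(proj, res.scores["PC1"])[0, 1]
        assert abs(r) > 0.999

    def test_missing_cells_rejected(self):
        m = make_matrix([[1, NA, 2], [1, 2, 3]], scale="log2")
        with pytest.raises(ValueError, match="complete"):
            pca_embed(m)


class TestHclustAndCoverage:
    def test_hclust_orders_are_permutations(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(0, 1, (6, 5)), scale="log2")
        f_order, s_order = hclust_order(m)
        assert sorted(f_order) == sorted(m.feature_ids)
        assert sorted(s_order) == sorted(m.sample_ids)
        assert (f_order, s_order) == hclust_order(m)  # deterministic

    def test_coverage_hand_counted(self):
        design = make_design(2)
        runs_a = list(design.loc[design["group"] == "arm_a", "run_id"])
        runs_b = list(design.loc[design["group"] == "arm_b", "run_id"])
        ma = make_matrix([[1, NA], [1, 1], [NA, NA]], samples=runs_a)
        mb = make_matrix([[1, 1], [1, 1], [1, NA]], samples=runs_b)
        cov = proteome_coverage(ma, mb, design, "arm_a", "arm_b")
        assert list(cov["coverage_a"]) == [2, 1]
        assert list(cov["coverage_b"]) == [3, 2]
        assert not cov["tested"]  # only 2 pairs

    def test_identical_groups_not_significant(self):
        design = make_design(5)
        runs_a = list(design.loc[design["group"] == "arm_a", "run_id"])
        runs_b = list(design.loc[design["group"] == "arm_b", "run_id"])
        vals = np.ones((4, 5))
        ma = make_matrix(vals, samples=runs_a)
        mb = make_matrix(vals, samples=runs_b)
        cov = proteome_coverage(ma, mb, design, "arm_a", "arm_b")
        assert not cov["tested"] or cov["p"] > 0.05
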