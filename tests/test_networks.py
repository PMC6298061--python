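"""Correlation stores, binarization and TAN aggregation."""

import numpy as np
import pytest
from scipy import stats

from dcoex import (
    ExpressionDataset,
    aggregation_threshold,
    binarize,
    build_tan,
    correlation_network,
    harmonize_genes,
    mark_expressed,
)
from dcoex.core import pair_index

from conftest import brute_force_pearson


def _dataset(matrix, dataset_id="d1", tissue="t1", genes=None):
    genes = genes or [f"G{i}" for i in range(matrix.shape[0])]
    return ExpressionDataset(dataset_id, tissue, genes, matrix)


class TestHarmonize:
    def test_identical_gene_sets(self):
        rng = np.random.default_rng(0)
        ds = [_dataset(rng.normal(size=(4, 5)), f"d{k}") for k in range(2)]
        universe, restricted = harmonize_genes(ds)
        assert universe == ds[0].gene_ids

    def test_partial_overlap(self):
        rng = np.random.default_rng(0)
        d1 = _dataset(rng.normal(size=(3, 5)), "d1", genes=["A", "B", "C"])
        d2 = _dataset(rng.normal(size=(3, 5)), "d2", genes=["B", "C", "D"])
        universe, restricted = harmonize_genes([d1, d2])
        assert universe == ["B", "C"]
        assert all(ds.gene_ids == ["B", "C"] for ds in restricted)

    def test_disjoint_is_fatal(self):
        rng = np.random.default_rng(0)
        d1 = _dataset(rng.normal(size=(2, 5)), "d1", genes=["A", "B"])
        d2 = _dataset(rng.normal(size=(2, 5)), "d2", genes=["C", "D"])
        with pytest.raises(ValueError, match="intersection"):
            harmonize_genes([d1, d2])


class TestMarkExpressed:
    def test_bimodal_means_recovered_by_mixture(self):
        rng = np.random.default_rng(5)
        n_off, n_on = 150, 150
        means = np.concatenate([rng.normal(4.0, 0.5, n_off), rng.normal(9.0, 0.5, n_on)])
        matrix = means[:, None] + rng.normal(0, 0.05, size=(n_off + n_on, 10))
        ds = _dataset(matrix)
        expressed, info = mark_expressed([ds], method="gmm2")
        on_genes = {f"G{i}" for i in range(n_off, n_off + n_on)}
        assert on_genes <= expressed
        assert 5.5 < info["split"] < 7.5

    def test_fixed_threshold(self):
        matrix = np.array([[4.0] * 3, [5.0] * 3, [9.0] * 3, [10.0] * 3])
        ds = _dataset(matrix)
        expressed, _ = mark_expressed([ds], method="fixed", threshold=6.0)
        assert expressed == {"G2", "G3"}

    def test_unimodal_input_falls_back_with_warning(self):
        rng = np.random.default_rng(6)
        matrix = rng.normal(7.0, 1.0, size=(200, 5))
        ds = _dataset(matrix)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            expressed, info = mark_expressed([ds], method="gmm2")
        assert info["method"] == "fixed"
        assert len(expressed) == pytest.approx(100, abs=10)


class TestCorrelationNetwork:
    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(7)
        ds = _dataset(rng.normal(size=(10, 50)))
        store = correlation_network(ds, set(ds.gene_ids))
        oracle = brute_force_pearson(ds.matrix)
        for (i, j), r in oracle.items():
            assert store.corr(f"G{i}", f"G{j}") == pytest.approx(r, abs=1e-12)

    def test_symmetric_access_and_no_diagonal(self):
        rng = np.random.default_rng(8)
        ds = _dataset(rng.normal(size=(5, 20)))
        store = correlation_network(ds, set(ds.gene_ids))
        assert store.corr("G1", "G3") == store.corr("G3", "G1")
        assert store.n_pairs == 10  # C(5,2): self-pairs excluded
        with pytest.raises(ValueError):
            pair_index(2, 2, 5)

    def test_identical_profiles_correlate_at_one(self):
        base = np.random.default_rng(9).normal(size=20)
        matrix = np.vstack([base, base, np.random.default_rng(10).normal(size=20)])
        store = correlation_network(_dataset(matrix), {"G0", "G1", "G2"})
        assert store.corr("G0", "G1") == pytest.approx(1.0)

    def test_zero_variance_gene_flagged_not_nan(self):
        matrix = np.vstack([np.ones(10), np.random.default_rng(11).normal(size=10)])
        store = correlation_network(_dataset(matrix), {"G0", "G1"})
        assert store.corr("G0", "G1") == 0.0
        assert store.zero_variance.any()
        assert np.isfinite(store.values).all()


class TestBinarize:
    def test_at_most_ten_percent_of_pairs(self):
        rng = np.random.default_rng(12)
        ds = _dataset(rng.normal(size=(15, 40)))  # 105 pairs
        store = correlation_network(ds, set(ds.gene_ids))
        net = binarize(store, 0.90)
        assert len(net.link_indices) <= np.ceil(0.10 * store.n_pairs)

    def test_all_equal_correlations_give_no_links(self):
        # three identical profiles: every pairwise correlation is 1.0
        base = np.random.default_rng(13).normal(size=20)
        store = correlation_network(_dataset(np.vstack([base] * 3)), {"G0", "G1", "G2"})
        assert len(binarize(store, 0.90).link_indices) == 0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(14)
        ds = _dataset(rng.normal(size=(20, 30)))
        store = correlation_network(ds, set(ds.gene_ids))
        net = binarize(store, 0.90)
        cutoff = np.quantile(store.values, 0.90)
        oracle = {k for k, v in enumerate(store.values) if v > cutoff}
        assert set(net.link_indices) == oracle


class TestAggregationThreshold:
    def test_matches_binomial_tail_oracle(self):
        # oracle: smallest n with sum_{k>=n} C(10,k) 0.1^k 0.9^(10-k) <= 1e-4
        def tail(n):
            return sum(stats.binom.pmf(k, 10, 0.1) for k in range(n, 11))

        oracle_n = min(n for n in range(1, 11) if tail(n) <= 1e-4)
        assert aggregation_threshold(10, 0.1, 10000, 1e-4, mode="planning") == oracle_n

    def test_fdr_one_accepts_single_support(self):
        assert aggregation_threshold(10, 0.1, 1000, 0.999999, mode="planning") == 1

    def test_single_dataset_infeasible(self):
        with pytest.raises(ValueError, match="looser"):
            aggregation_threshold(1, 0.1, 1000, 1e-4, mode="planning")

    def test_empirical_mode_never_less_conservative_than_planning(self):
        # observed discoveries <= total pairs, so the empirical criterion can
        # only push n up; with every pair at full support the two coincide
        n_plan = aggregation_threshold(10, 0.1, 100000, 1e-4, mode="planning")
        sparse = np.concatenate([np.full(500, 9), np.zeros(99500)]).astype(int)
        n_sparse = aggregation_threshold(10, 0.1, 100000, 1e-4, support_counts=sparse, mode="empirical")
        assert n_sparse >= n_plan
        full = np.full(100000, 10)
        n_full = aggregation_threshold(10, 0.1, 100000, 1e-4, support_counts=full, mode="empirical")
        assert n_full == n_plan


class TestBuildTan:
    def _nets(self, masks):
        from dcoex.networks import BinaryNetwork

        return [
            BinaryNetwork(f"d{k}", 0.0, np.flatnonzero(m), len(m))
            for k, m in enumerate(masks)
        ]

    def test_support_counting(self):
        n_pairs_total = 4
        masks = [np.zeros(n_pairs_total, bool) for _ in range(7)]
        for m in masks:
            m[0] = True  # link 0 in all 7 networks
        for m in masks[:2]:
            m[1] = True  # link 1 in 2 of 7
        tan = build_tan(self._nets(masks), n=3, tissue="t", gene_ids=["A", "B", "C", "D"])
        assert tan.support[0] == 7 and 0 in tan.link_indices
        assert tan.support[1] == 2 and 1 not in tan.link_indices

    def test_support_equals_brute_force_multiset_count(self):
        rng = np.random.default_rng(15)
        masks = [rng.random(50) < 0.2 for _ in range(9)]
        tan = build_tan(self._nets(masks), n=2, tissue="t", gene_ids=[f"G{i}" for i in range(10)])
        oracle = np.sum(masks, axis=0)
        np.testing.assert_array_equal(tan.support, oracle)
        np.testing.assert_array_equal(tan.link_indices, np.flatnonzero(oracle >= 2))

    def test_invariant_to_dataset_ordering(self):
        rng = np.random.default_rng(16)
        masks = [rng.random(30) < 0.3 for _ in range(6)]
        tan1 = build_tan(self._nets(masks), 2, "t", [f"G{i}" for i in range(8)] + ["X"])
        tan2 = build_tan(self._nets(masks[::-1]), 2, "t", [f"G{i}" for i in range(8)] + ["X"])
        np.testing.assert_array_equal(tan1.link_indices, tan2.link_indices)

    def test_links_as_pairs_round_trip(self):
        masks = [np.array([True, False, True])]
        tan = build_tan(self._nets(masks), 1, "t", ["A", "B", "C"])
        # condensed order over 3 genes: (A,B), (A,C), (B,C)
        assert tan.links_as_pairs() == {("A", "B"), ("B", "C")}
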