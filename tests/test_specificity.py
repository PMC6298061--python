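"""Binned rank transform, TSS, Wilcoxon alternative, pseudo-tissues and FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dcoex import (
    ExpressionDataset,
    correlation_network,
    make_pseudo_tissues,
    sb_all,
    sb_values,
    select_tsn,
    tss,
    tss_fdr_curve,
    tss_from_sb,
    tss_wilcoxon,
)

from conftest import brute_force_sb, brute_force_tss


def _store(values, dataset_id="d1", tissue="t1"):
    """Correlation store with a prescribed condensed value vector."""
    from dcoex.networks import DatasetCorrelations

    n_genes = int((1 + np.sqrt(1 + 8 * len(values))) / 2)
    assert n_genes * (n_genes - 1) // 2 == len(values)
    return DatasetCorrelations(
        dataset_id=dataset_id,
        tissue=tissue,
        gene_ids=[f"G{i}" for i in range(n_genes)],
        values=np.asarray(values, float),
        zero_variance=np.zeros(len(values), bool),
    )


class TestBinTransform:
    def test_matches_brute_force_rank_ceil(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(-1, 1, size=190)  # 20 genes -> 190 pairs
        store = _store(values)
        np.testing.assert_allclose(sb_all(store, n_bins=1000), brute_force_sb(values, 1000))

    def test_negative_correlations_floored_regardless_of_rank(self):
        # mostly-negative dataset: a mildly negative value ranks high, still 0.5
        values = np.concatenate([np.linspace(-0.9, -0.1, 170), np.linspace(0.1, 0.9, 20)])
        store = _store(values)
        sb = sb_values(store, np.array([-0.11, -0.89]))
        assert sb[0] == 0.5 and sb[1] == 0.5

    def test_largest_correlation_maps_to_top_bin(self):
        rng = np.random.default_rng(22)
        values = rng.uniform(-1, 1, size=45)
        store = _store(values)
        assert sb_values(store, np.array([values.max()]))[0] == 1.0

    def test_median_of_symmetric_dataset_near_half(self):
        # half the pairs negative: the median correlation sits at bin ~0.5
        values = np.linspace(-0.99, 0.99, 190)
        store = _store(values)
        med = np.median(values)
        assert sb_values(store, np.array([med]))[0] == pytest.approx(0.5, abs=0.01)

    def test_sb_always_in_floor_to_one(self):
        rng = np.random.default_rng(23)
        values = rng.uniform(-1, 1, size=105)
        sb = sb_all(_store(values), n_bins=1000)
        assert ((sb >= 0.5) & (sb <= 1.0)).all()
        # values land on the 1/n_bins grid
        assert np.allclose(sb * 1000, np.round(sb * 1000))


class TestTss:
    def test_identical_sb_everywhere_scores_zero(self):
        sb = np.full(10, 0.7)
        assert tss(sb, ["a"] * 3 + ["b"] * 7, "a") == 0.0

    def test_maximal_separation_scores_half(self):
        sb = np.array([1.0, 1.0, 0.5, 0.5, 0.5])
        assert tss(sb, ["a", "a", "b", "b", "c"], "a") == pytest.approx(0.5)

    def test_hand_computed_four_dataset_example(self):
        # target {0.9, 0.6}, others {0.5, 0.8}:
        # (0.4 + 0.1 + 0.1 + 0) / 4 = 0.15
        sb = np.array([0.9, 0.6, 0.5, 0.8])
        assert tss(sb, ["a", "a", "b", "b"], "a") == pytest.approx(0.15)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(24)
        sb = rng.uniform(0.5, 1.0, size=(30, 12))
        mask = np.zeros(12, bool)
        mask[:4] = True
        scores = tss_from_sb(sb, mask)
        for row, score in zip(sb, scores):
            assert score == pytest.approx(brute_force_tss(row[mask], row[~mask]), abs=1e-12)

    def test_invariant_under_monotone_transform_of_correlations(self):
        rng = np.random.default_rng(25)
        raw = rng.uniform(0.01, 0.99, size=45)
        store1 = _store(raw)
        store2 = _store(np.tanh(3 * raw))  # strictly monotone
        links = [("G0", "G1"), ("G2", "G5"), ("G3", "G8")]
        sb1 = sb_values(store1, store1.values[store1.pair_indices(links)])
        sb2 = sb_values(store2, store2.values[store2.pair_indices(links)])
        np.testing.assert_allclose(sb1, sb2)

    def test_invariant_to_dataset_ordering(self):
        rng = np.random.default_rng(26)
        sb = rng.uniform(0.5, 1.0, size=(5, 10))
        tissues = ["a"] * 3 + ["b"] * 7
        perm = rng.permutation(10)
        scores1 = tss_from_sb(sb, np.array([t == "a" for t in tissues]))
        scores2 = tss_from_sb(sb[:, perm], np.array([tissues[i] == "a" for i in perm]))
        np.testing.assert_allclose(scores1, scores2)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_by_sb_range(self, seed):
        rng = np.random.default_rng(seed)
        sb = rng.uniform(0.5, 1.0, size=(1, 8))
        score = tss_from_sb(sb, np.array([True, True, False, False, False, False, False, False]))[0]
        assert 0.0 <= score <= np.ptp(sb) + 1e-12
        assert score <= 0.5 + 1e-12


class TestWilcoxon:
    def test_exact_five_versus_five_complete_separation(self):
        sb = np.array([0.9, 0.91, 0.92, 0.93, 0.94, 0.5, 0.51, 0.52, 0.53, 0.54])
        tissues = ["a"] * 5 + ["b"] * 5
        p, ok = tss_wilcoxon(sb, tissues, "a")
        assert ok
        assert p == pytest.approx(1 / 252)  # 1 / C(10,5): exact rank-sum

    def test_all_tied_gives_p_one(self):
        p, ok = tss_wilcoxon(np.full(8, 0.5), ["a"] * 4 + ["b"] * 4, "a")
        assert p == 1.0 and ok

    def test_single_dataset_side_flagged(self):
        p, ok = tss_wilcoxon(np.array([0.9, 0.5, 0.5]), ["a", "b", "b"], "a")
        assert p == 1.0 and not ok

    def test_calibration_under_identical_distributions(self):
        rng = np.random.default_rng(27)
        tissues = ["a"] * 8 + ["b"] * 30
        pvals = []
        for _ in range(400):
            sb = rng.uniform(0.5, 1.0, size=38)
            pvals.append(tss_wilcoxon(sb, tissues, "a")[0])
        # one-sided p under the null is stochastically >= uniform
        assert stats.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01

    def test_rank_correlated_with_tss(self, default_run):
        """The two specificity scores order links nearly identically."""
        _, _, res = default_run
        t = res.tissues[0]
        member = np.flatnonzero(res.tan_membership[t])
        tissues = res.dataset_tissues
        tss_vals = res.tss_by_tissue[t][member]
        wil = [-np.log10(tss_wilcoxon(res.sb[i], tissues, t)[0] + 1e-300) for i in member]
        rho = stats.spearmanr(tss_vals, wil).statistic
        assert rho >= 0.8


class TestPseudoTissues:
    def _tissue_map(self, counts):
        out = {}
        for t, c in counts.items():
            for i in range(c):
                out[f"{t}_d{i}"] = t
        return out

    def test_even_split_when_divisible(self):
        dm = self._tissue_map({f"t{i}": 4 for i in range(5)})
        # mirror a tissue with 10 datasets -> exactly 2 per real tissue
        dm2 = dict(dm)
        for i in range(4, 10):
            dm2[f"t0_d{i}"] = "t0"
        pseudo = make_pseudo_tissues(dm2, "t0", 5, np.random.default_rng(0))
        for pt in pseudo:
            counts = {}
            for d in pt.dataset_ids:
                counts[dm2[d]] = counts.get(dm2[d], 0) + 1
            assert all(v == 2 for v in counts.values())

    def test_floor_ceil_split_for_remainder(self):
        dm = self._tissue_map({f"t{i}": 7 for i in range(5)})
        pseudo = make_pseudo_tissues(dm, "t0", 10, np.random.default_rng(1))
        for pt in pseudo:
            assert len(pt.dataset_ids) == 7
            counts = {}
            for d in pt.dataset_ids:
                counts[dm[d]] = counts.get(dm[d], 0) + 1
            assert sorted(counts.values()) == [1, 1, 1, 2, 2]

    def test_fixed_seed_reproducible(self):
        dm = self._tissue_map({f"t{i}": 6 for i in range(5)})
        a = make_pseudo_tissues(dm, "t1", 30, np.random.default_rng(42))
        b = make_pseudo_tissues(dm, "t1", 30, np.random.default_rng(42))
        assert [p.dataset_ids for p in a] == [p.dataset_ids for p in b]

    def test_quota_relaxation_warns(self):
        dm = self._tissue_map({"t0": 12, "t1": 1, "t2": 1})
        with pytest.warns(RuntimeWarning, match="relaxed"):
            pseudo = make_pseudo_tissues(dm, "t0", 3, np.random.default_rng(2))
        assert all(len(pt.dataset_ids) == 12 for pt in pseudo)


class TestFdrCurve:
    def test_hand_computed_small_fixture(self):
        real = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pseudo = [np.array([0.05, 0.15, 0.25, 0.0, 0.0]), np.array([0.45, 0.0, 0.0, 0.0, 0.0])]
        curve = tss_fdr_curve(real, pseudo)
        # hand computation: mean pseudo exceedances / real exceedances
        #  t=0.1: pseudo (2 + 1)/2 = 1.5, real 4 -> 0.375
        #  t=0.2: (1 + 1)/2 = 1.0, real 3 -> 1/3
        #  t=0.3: (0 + 1)/2 = 0.5, real 2 -> 0.25
        #  t=0.4: (0 + 1)/2 = 0.5, real 1 -> 0.5
        #  t=0.5: real exceedances 0 -> 0.0
        np.testing.assert_allclose(curve.raw_fdr, [0.375, 1 / 3, 0.25, 0.5, 0.0])
        # running minimum from high cuts downward, over defined cuts only
        # (the top cut 0.5 has no real score above it: FDR 0 but not a threshold)
        np.testing.assert_allclose(curve.fdr, [0.25, 0.25, 0.25, 0.5, 0.0])
        assert curve.threshold(0.01) is None
        assert curve.threshold(0.3) == pytest.approx(0.1)

    def test_zero_pseudo_scores_give_zero_fdr(self):
        curve = tss_fdr_curve(np.array([0.1, 0.2]), [np.zeros(2)])
        assert curve.fdr_at(0.05) == 0.0
        assert curve.threshold(0.01) == pytest.approx(0.1)

    def test_same_distribution_gives_fdr_near_one_at_median(self):
        # exchangeable real and pseudo scores: the raw estimator sits at ~1
        # (the smoothed curve is a running min and may dip below on the
        # noisy small-count tail, which is why thresholds use it instead)
        rng = np.random.default_rng(28)
        real = rng.uniform(0, 0.5, 2000)
        pseudo = [rng.uniform(0, 0.5, 2000) for _ in range(10)]
        curve = tss_fdr_curve(real, pseudo)
        i = int(np.searchsorted(curve.grid, float(np.median(real))))
        assert curve.raw_fdr[i] == pytest.approx(1.0, abs=0.15)


class TestSelectTsn:
    def _setup(self):
        links = [("A", "B"), ("C", "D"), ("E", "F")]
        tss_by_tissue = {
            "t1": np.array([0.45, 0.45, 0.05]),
            "t2": np.array([0.45, 0.10, 0.05]),
        }
        membership = {
            "t1": np.array([True, True, True]),
            "t2": np.array([True, True, False]),
        }
        curves = {
            t: tss_fdr_curve(tss_by_tissue[t][membership[t]], [np.zeros(3)])
            for t in ("t1", "t2")
        }
        return links, tss_by_tissue, membership, curves

    def test_cross_tissue_ceiling_excludes_shared_links(self):
        links, tbt, member, curves = self._setup()
        sel = select_tsn(links, tbt, member, curves, fdr_target=0.01, other_max=0.4)
        # (A,B) scores 0.45 in both tissues -> excluded everywhere
        assert ("A", "B") not in sel.selected["t1"]
        assert ("C", "D") in sel.selected["t1"]

    def test_fdr_target_one_keeps_all_tan_links_passing_ceiling(self):
        links, tbt, member, curves = self._setup()
        sel = select_tsn(links, tbt, member, curves, fdr_target=1.0, other_max=0.4)
        assert sel.selected["t1"] == {("C", "D"), ("E", "F")}

    def test_unreachable_fdr_yields_empty_tsn_with_warning(self):
        links, tbt, member, _ = self._setup()
        bad_curve = tss_fdr_curve(np.array([0.1, 0.2]), [np.array([0.3, 0.4])])
        curves = {"t1": bad_curve, "t2": bad_curve}
        with pytest.warns(RuntimeWarning, match="empty TSN"):
            sel = select_tsn(links, tbt, member, curves, fdr_target=0.001, other_max=0.4)
        assert sel.selected["t1"] == set()
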