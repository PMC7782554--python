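"""Modularity DP segmentation: oracle equivalence, γ-sweep, robustness."""

import itertools

import numpy as np
import pytest

from snfold import synthetic
from snfold.maps import SparseContactMap, shuffle_map
from snfold.segmentation import Segmentation, match_boundaries
from snfold.tad_modularity import (
    boundary_support_refine,
    compare_segmentations,
    gamma_sweep,
    randomize_boundaries,
    segment_map,
    segment_score,
    stability_classes,
    subtad_hierarchy_test,
)


def exhaustive_optimum(dense, gamma):
    """Brute-force maximum over all contiguous partitions with null bins.

    Enumerates every cut pattern (2^(N-1)); multi-bin segments score
    their modularity, single bins may opt out at score 0.
    """
    n = dense.shape[0]
    best = -np.inf
    for mask in range(2 ** (n - 1)):
        cuts = [0] + [k + 1 for k in range(n - 1) if mask >> k & 1] + [n]
        total = 0.0
        for a, b in zip(cuts, cuts[1:]):
            s = segment_score(dense, a, b, gamma)
            total += max(s, 0.0) if b - a == 1 else s
        best = max(best, total)
    return best


def dp_total_score(dense, gamma):
    # with min_tad_bins=1, interTAD segments are merged runs of null
    # singletons (each contributing 0); TAD segments contribute their score
    seg = segment_map(dense, gamma, min_tad_bins=1)
    return sum(
        segment_score(dense, a, b, gamma)
        for a, b, lab in seg.segments
        if lab == "TAD"
    )


class TestSegmentScore:
    def test_whole_map_scores_one_at_gamma_zero(self, cell200):
        n = cell200.chrom_bins["chr1"]
        assert segment_score(cell200, 0, n, 0.0) == pytest.approx(1.0)

    def test_empty_single_bin_scores_zero(self):
        dense = np.zeros((5, 5))
        dense[0, 3] = dense[3, 0] = 2
        assert segment_score(dense, 1, 2, 0.0) == 0.0

    def test_four_bin_uniform_hand_computation(self):
        """All off-diagonal entries 1: T=6; W(0,2)=1, M(0,2)=6."""
        dense = np.ones((4, 4)) - np.eye(4)
        g = 2.0
        expect = 1 / 6 - g * (6 / 12) ** 2
        assert segment_score(dense, 0, 2, g) == pytest.approx(expect)

    def test_gamma_monotone_penalty(self, cell200):
        """Raising γ never increases any fixed segment's score."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = int(rng.integers(0, 190))
            b = int(rng.integers(a + 1, 200))
            s1 = segment_score(cell200, a, b, 1.0)
            s2 = segment_score(cell200, a, b, 5.0)
            assert s2 <= s1 + 1e-12


class TestDPOracle:
    @pytest.mark.parametrize("gamma", [0.0, 0.5, 2.0, 10.0])
    def test_dp_equals_exhaustive_small_maps(self, gamma):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            dense = rng.poisson(1.0, (n, n)).astype(float)
            dense = np.triu(dense, 1)
            dense = dense + dense.T
            assert dp_total_score(dense, gamma) == pytest.approx(
                exhaustive_optimum(dense, gamma), abs=1e-9
            )

    def test_two_blocks_split_at_midrange_gamma(self):
        dense = np.zeros((21, 21))
        dense[:10, :10] = 1.0
        dense[11:, 11:] = 1.0
        np.fill_diagonal(dense, 0.0)
        seg = segment_map(dense, 1.0)
        assert seg.n_tads == 2
        assert seg.tads == [(0, 10), (11, 21)]

    def test_large_gamma_all_inter_tad(self, cell200):
        seg = segment_map(cell200, 1e6)
        assert seg.n_tads == 0


class TestGammaSweep:
    def test_gamma_max_attains_maximum(self, cell200):
        sw = gamma_sweep(cell200, np.arange(0, 50.001, 0.5))
        assert sw.n_tads[0] <= sw.n_tads.max()
        k = np.flatnonzero(sw.gammas == sw.gamma_max)[0]
        assert sw.n_tads[k] == sw.n_tads.max()
        # first attained
        assert np.all(sw.n_tads[:k] < sw.n_tads[k])

    def test_median_size_decreasing_trend(self, cell200):
        from scipy.stats import spearmanr

        sw = gamma_sweep(cell200, np.arange(0, 30.001, 0.5))
        sel = sw.n_tads > 0
        rho = spearmanr(sw.gammas[sel], sw.median_size[sel]).statistic
        assert rho < 0

    def test_planted_median_recovered_at_gamma_half(self):
        arch = synthetic.make_architecture(500, seed=1)
        cell = synthetic.sample_cell_contacts(arch, 30_000, seed=2)
        sw = gamma_sweep(cell, np.arange(0, 375.001, 0.5))
        planted = np.median(arch.tad_sizes())
        assert abs(sw.segmentation_half.median_tad_size() - planted) <= 2

    def test_empty_grid_rejected(self, cell200):
        with pytest.raises(ValueError):
            gamma_sweep(cell200, np.array([]))


class TestBoundarySupport:
    def test_full_level_supports_every_boundary(self, cell200):
        sw = gamma_sweep(cell200, np.arange(0, 30.001, 1.0))
        bs = boundary_support_refine(
            cell200, sw.gamma_half, levels=np.array([99.99]), reps=2, seed=1,
            support_levels=(99.99,),
        )
        assert np.all(bs.support[0][bs.full_edges] == 1.0)
        assert set(bs.refined_edges) == set(bs.full_edges)

    def test_bad_levels_rejected(self, cell200):
        with pytest.raises(ValueError):
            boundary_support_refine(cell200, 1.0, levels=np.array([0.0]))

    def test_strong_boundaries_survive_subsampling(self):
        arch = synthetic.make_architecture(300, seed=3)
        cell = synthetic.sample_cell_contacts(arch, 20_000, seed=4)
        sw = gamma_sweep(cell, np.arange(0, 50.001, 1.0))
        bs = boundary_support_refine(
            cell, sw.gamma_half, levels=np.array([90.0]), reps=5, seed=5,
            support_levels=(90.0,),
        )
        mean_support = bs.support[0][bs.full_edges].mean()
        assert mean_support > 0.8
        assert not np.isnan(bs.roc_auc[0])
        assert bs.roc_auc[0] > 0.85


class TestCompare:
    def _seg(self, edges, n=30):
        segs = []
        pos = 0
        for e in list(edges) + [n]:
            if e > pos:
                segs.append((pos, e, "TAD"))
            pos = e
        return Segmentation(segs, n)

    def test_identity(self):
        a = self._seg([10, 20])
        out = compare_segmentations(a, a)
        assert out == {"shared_boundary_pct": 100.0, "jaccard_tad_bins": 1.0}

    def test_one_bin_shift_matches_with_offset(self):
        a = self._seg([10, 20])
        b = self._seg([11, 21])
        assert compare_segmentations(a, b, offset=1)["shared_boundary_pct"] == 100.0
        assert compare_segmentations(a, b, offset=0)["shared_boundary_pct"] < 100.0

    def test_disjoint(self):
        a = Segmentation([(0, 10, "TAD"), (10, 30, "interTAD")], 30)
        b = Segmentation([(0, 14, "interTAD"), (14, 30, "TAD")], 30)
        out = compare_segmentations(a, b)
        assert out["shared_boundary_pct"] == 0.0
        assert out["jaccard_tad_bins"] == 0.0

    def test_asymmetric_shared_symmetric_jaccard(self):
        a = self._seg([10, 20])
        b = self._seg([10])
        ab = compare_segmentations(a, b)
        ba = compare_segmentations(b, a)
        assert ab["shared_boundary_pct"] != ba["shared_boundary_pct"]
        assert ab["jaccard_tad_bins"] == ba["jaccard_tad_bins"]


class TestRandomizeBoundaries:
    def test_size_multiset_conserved(self):
        seg = Segmentation(
            [(0, 9, "TAD"), (9, 12, "interTAD"), (12, 30, "TAD")], 30
        )
        out = randomize_boundaries(seg, reps=50, seed=1)
        assert len(out["null_scores"]) == 50

    def test_single_segment_identity(self):
        seg = Segmentation([(0, 10, "TAD")], 10)
        out = randomize_boundaries(seg, reps=10, seed=2)
        assert np.all(out["null_scores"] == out["observed"])

    def test_self_comparison_significant(self, cell200):
        sw = gamma_sweep(cell200, np.arange(0, 30.001, 1.0))
        seg = sw.segmentation_half
        out = randomize_boundaries(seg, reps=200, seed=3)
        assert out["p_value"] < 0.05
        assert out["observed"] == 100.0


class TestStabilityClasses:
    def test_threshold_edges(self):
        sets = [np.array([10, 20])] * 10 + [np.array([10, 40])] * 10
        out = stability_classes(sets, n_bins=50)
        assert 10 in out["stable"]  # in all cells
        assert 20 in out["stable"]  # exactly 50% of cells
        assert 40 in out["stable"]
        single = [np.array([10])] * 19 + [np.array([10, 30])]
        out2 = stability_classes(single, n_bins=50)
        assert 30 in out2["cell_specific"]

    def test_unstable_between(self):
        sets = [np.array([5])] * 6 + [np.array([25])] * 2 + [np.array([45])] * 12
        out = stability_classes(sets, n_bins=50)
        assert 5 in out["unstable"]  # 6/20 cells: >1, <50%
        assert 45 in out["stable"]

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            stability_classes([np.array([1])], n_bins=10)


class TestSubtadHierarchy:
    def _setup(self):
        tads = Segmentation([(0, 20, "TAD"), (20, 40, "TAD")], 40)
        subtads = Segmentation(
            [(0, 8, "TAD"), (8, 16, "TAD"), (16, 22, "interTAD"),
             (22, 30, "TAD"), (30, 40, "TAD")],
            40,
        )
        return tads, subtads

    def test_identical_maps_identical_distributions(self, cell200):
        tads, subtads = self._setup()
        sub = SparseContactMap(
            cell200.binsize, {"chr1": 40},
            {"chr1": tuple(a[:50] % 40 for a in cell200.triplets("chr1"))},
        )
        out = subtad_hierarchy_test(sub, tads, subtads, sub)
        assert np.array_equal(out["real"], out["control"])

    def test_planted_hierarchy_dominates_control(self):
        rng = np.random.default_rng(9)
        n = 40
        base = rng.poisson(0.3, (n, n)).astype(float)
        base = np.triu(base, 1) + np.triu(base, 1).T
        enriched = base.copy()
        enriched[0:8, 8:16] += 3  # sibling sub-TADs linked
        enriched[22:30, 30:40] += 3
        tads, subtads = self._setup()
        real = SparseContactMap.from_dense(enriched, 10_000)
        ctrl = SparseContactMap.from_dense(base, 10_000)
        out = subtad_hierarchy_test(real, tads, subtads, ctrl)
        assert np.all(out["real"] >= out["control"])
        assert out["real"].sum() > out["control"].sum()

    def test_no_nested_pairs_empty(self):
        tads = Segmentation([(0, 40, "interTAD")], 40)
        subtads = Segmentation([(0, 40, "interTAD")], 40)
        m = SparseContactMap(10_000, {"chr1": 40})
        out = subtad_hierarchy_test(m, tads, subtads, m)
        assert len(out["real"]) == 0


class TestRecoveryEndToEnd:
    def test_planted_boundaries_recovered(self):
        """Strong planted TADs: γ_max/2 calling recovers >= 90% of planted
        boundaries at one-bin offset; shuffled maps fall to chance."""
        arch = synthetic.make_architecture(500, seed=11)
        cell = synthetic.sample_cell_contacts(arch, 30_000, seed=12)
        sw = gamma_sweep(cell, np.arange(0, 375.001, 0.5))
        rec = match_boundaries(
            arch.tad_edges, sw.segmentation_half.boundary_edges(), 1
        ).mean()
        assert rec >= 0.9

    def test_shuffled_maps_fall_to_chance(self):
        arch = synthetic.make_architecture(500, seed=11)
        cell = synthetic.sample_cell_contacts(arch, 30_000, seed=12)
        sh = shuffle_map(cell, "per_distance", seed=13)
        sw = gamma_sweep(sh, np.arange(0, 375.001, 0.5))
        seg = sw.segmentation_half
        rec = match_boundaries(arch.tad_edges, seg.boundary_edges(), 1).mean()
        # chance level: same segmentation with randomized boundary placement
        null = randomize_boundaries(seg, reps=100, seed=14)
        chance_scores = []
        rng = np.random.default_rng(15)
        pieces = [(e - s, lab) for s, e, lab in seg.segments]
        for _ in range(100):
            order = rng.permutation(len(pieces))
            segs, pos = [], 0
            for k in order:
                size, lab = pieces[k]
                segs.append((pos, pos + size, lab))
                pos += size
            rand = Segmentation(segs, seg.n_bins)
            chance_scores.append(
                match_boundaries(arch.tad_edges, rand.boundary_edges(), 1).mean()
            )
        chance = float(np.mean(chance_scores))
        assert rec <= chance + 0.05
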