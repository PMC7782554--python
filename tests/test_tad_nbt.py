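"""Non-backtracking spectral caller: operator, spectrum, clustering."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from snfold import synthetic
from snfold.maps import SparseContactMap
from snfold.tad_nbt import (
    ContactGraph,
    build_nbt_operator,
    call_tads_nbt,
    cluster_embedding,
    embed_nodes,
    finalize_segmentation,
    nbt_spectrum,
    preprocess_for_nbt,
    spectral_edge_closed_form,
)


def graph_from_edges(n, edges):
    e = np.sort(np.asarray(edges), axis=1)
    return ContactGraph(n, np.unique(e, axis=0))


def complete_graph(n):
    return graph_from_edges(n, list(itertools.combinations(range(n), 2)))


def cycle_graph(n):
    return graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def hungarian_agreement(labels, truth):
    m = np.zeros((labels.max() + 1, truth.max() + 1))
    for a, b in zip(labels, truth):
        m[a, b] += 1
    r, c = linear_sum_assignment(-m)
    return m[r, c].sum() / len(labels)


class TestPreprocess:
    def _map(self, pairs, n=200):
        pairs = np.asarray(pairs).reshape(-1, 2)
        return SparseContactMap(
            10_000, {"chr1": n},
            {"chr1": (pairs[:, 0], pairs[:, 1], np.full(len(pairs), 7))},
        )

    def test_distance_cap(self):
        g = preprocess_for_nbt(self._map([(0, 150), (0, 50)]), max_distance_bins=100)
        pairs = set(map(tuple, g.edges))
        assert (0, 150) not in pairs
        assert (0, 50) in pairs

    def test_empty_map_gives_backbone_path(self):
        g = preprocess_for_nbt(self._map(np.zeros((0, 2)), n=5))
        assert g.n_edges == 4
        assert np.array_equal(g.edges, [[0, 1], [1, 2], [2, 3], [3, 4]])

    def test_counts_binarized(self):
        g = preprocess_for_nbt(self._map([(0, 3)], n=5))
        adj = g.adjacency().toarray()
        assert adj[0, 3] == 1  # count 7 collapsed to one edge


class TestSpectrum:
    def test_k4_leading_eigenvalue_two(self):
        """d-regular graph: leading NBT eigenvalue = d − 1."""
        spec = nbt_spectrum(complete_graph(4))
        lead = spec.eigenvalues[np.argmax(np.abs(spec.eigenvalues))]
        assert lead == pytest.approx(2.0, abs=1e-8)

    def test_closed_form_three_regular(self):
        # printed formula on d = 3: sqrt((1/3)·(3/2))
        rc = spectral_edge_closed_form(np.full(10, 3))
        assert rc == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_cycle_spectrum_on_unit_circle(self):
        spec = nbt_spectrum(cycle_graph(8))
        assert np.allclose(np.abs(spec.eigenvalues), 1.0, atol=1e-8)

    def test_operator_row_structure(self):
        """B has one row per directed edge; row sums equal the out-degree
        of the head minus the backtracking exclusion."""
        g = complete_graph(4)
        b = build_nbt_operator(g).toarray()
        assert b.shape == (12, 12)
        assert np.all(b.sum(axis=1) == 2)  # d−1 continuations

    def test_sparse_matches_dense(self):
        """ARPACK eigenvalues match the dense decomposition on a graph
        pushed over the sparse-path threshold."""
        rng = np.random.default_rng(1)
        n = 60
        extra = rng.integers(0, n, size=(400, 2))
        extra = extra[extra[:, 0] != extra[:, 1]]
        edges = np.concatenate(
            [np.stack([np.arange(n - 1), np.arange(1, n)], 1), np.sort(extra, 1)]
        )
        g = ContactGraph(n, np.unique(np.sort(edges, 1), axis=0))
        assert 2 * g.n_edges > 600
        b = build_nbt_operator(g)
        dense_vals = np.linalg.eigvals(b.toarray())
        dense_top = np.sort(np.abs(dense_vals))[::-1][:10]
        spec = nbt_spectrum(g, n_eigs=10)
        sparse_top = np.sort(np.abs(spec.eigenvalues[:10]))[::-1]
        assert np.allclose(sparse_top, dense_top, atol=1e-6)

    def test_ihara_bass_oracle(self):
        """Non-trivial NBT eigenvalues coincide with the spectrum of the
        2N×2N block matrix [[A, I−D], [I, 0]]."""
        g = complete_graph(5)
        a = g.adjacency().toarray()
        d = np.diag(g.degrees().astype(float))
        n = 5
        block = np.block(
            [[a, np.eye(n) - d], [np.eye(n), np.zeros((n, n))]]
        )
        ib_vals = np.sort_complex(np.linalg.eigvals(block))
        b_vals = np.linalg.eigvals(build_nbt_operator(g).toarray())
        # every Ihara-Bass eigenvalue appears in the full edge spectrum
        for v in ib_vals:
            assert np.min(np.abs(b_vals - v)) < 1e-8

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            nbt_spectrum(graph_from_edges(3, [(0, 1), (1, 2)]))


class TestEmbedding:
    def test_two_cliques_separate(self):
        """Two cliques joined by one edge embed into two tight clusters."""
        from sklearn.metrics import silhouette_score

        edges = (
            list(itertools.combinations(range(6), 2))
            + [(u + 6, v + 6) for u, v in itertools.combinations(range(6), 2)]
            + [(5, 6)]
        )
        g = graph_from_edges(12, edges)
        spec = nbt_spectrum(g)
        emb = embed_nodes(spec, g)
        truth = np.array([0] * 6 + [1] * 6)
        assert silhouette_score(emb / np.linalg.norm(emb, axis=1, keepdims=True), truth) > 0.5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4), (0, 4)]
        g = graph_from_edges(5, edges)
        spec = nbt_spectrum(g)
        emb = embed_nodes(spec, g)
        perm = rng.permutation(5)
        p_edges = [(perm[u], perm[v]) for u, v in edges]
        g2 = graph_from_edges(5, p_edges)
        spec2 = nbt_spectrum(g2)
        emb2 = embed_nodes(spec2, g2)
        # same isolated-eigenvalue set regardless of labeling
        assert np.allclose(
            np.sort(spec.eigenvalues[spec.isolated].real),
            np.sort(spec2.eigenvalues[spec2.isolated].real),
            atol=1e-8,
        )


class TestClustering:
    def test_antipodal_clouds_perfect_split(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([
            rng.normal([5, 0], 0.1, (20, 2)), rng.normal([-5, 0], 0.1, (20, 2))
        ])
        labels = cluster_embedding(x, 2, seed=1)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicate_rows_same_label(self):
        x = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        labels = cluster_embedding(x, 2, seed=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_more_clusters_than_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_embedding(np.eye(3), 5, seed=1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        a = cluster_embedding(x, 4, seed=9)
        b = cluster_embedding(x, 4, seed=9)
        assert np.array_equal(a, b)

    def test_planted_blocks_recovered(self, block_arch):
        """Ten equal planted blocks: spherical k-means on the NBT
        embedding matches the planting at >= 80% (Hungarian)."""
        truth = block_arch.tad_index()
        accs = []
        for s in range(3):
            cell = synthetic.sample_cell_contacts(block_arch, 1200, seed=40 + s)
            g = preprocess_for_nbt(cell)
            spec = nbt_spectrum(g)
            emb = embed_nodes(spec, g)
            labels = cluster_embedding(emb, 10, seed=s)
            accs.append(hungarian_agreement(labels, truth))
        assert np.mean(accs) >= 0.8


class TestFinalize:
    def _graph_with_block(self, n=20, block=(5, 12)):
        edges = [(i, i + 1) for i in range(n - 1)]
        s, e = block
        edges += [(i, j) for i in range(s, e) for j in range(i + 2, e)]
        return graph_from_edges(n, edges)

    def test_small_cluster_becomes_inter_tad(self):
        g = self._graph_with_block()
        labels = np.zeros(20, dtype=int)
        labels[3:5] = 1  # 2-bin run
        labels[5:12] = 2
        labels[12:] = 3
        seg = finalize_segmentation(labels, g)
        kinds = {(s, e): lab for s, e, lab in seg.segments}
        assert all(lab == "interTAD" for (s, e), lab in kinds.items() if e - s < 3)

    def test_backbone_only_cluster_is_inter_tad(self):
        g = self._graph_with_block(block=(5, 12))
        labels = np.zeros(20, dtype=int)
        labels[0:5] = 0  # 5 bins, only backbone links: l-1 = 4 internal
        labels[5:12] = 1  # dense block
        labels[12:] = 2
        seg = finalize_segmentation(labels, g)
        lab_by_start = {s: lab for s, e, lab in seg.segments}
        assert lab_by_start[0] == "interTAD"
        assert lab_by_start[5] == "TAD"

    def test_dense_cluster_is_tad(self):
        g = self._graph_with_block(block=(2, 12))
        labels = np.zeros(20, dtype=int)
        labels[2:12] = 1
        labels[12:] = 2
        seg = finalize_segmentation(labels, g)
        assert (2, 12) in seg.tads


class TestEndToEnd:
    def test_nbt_and_modularity_agree_on_planted_cells(self, block_arch):
        from snfold.tad_modularity import compare_segmentations, gamma_sweep

        shared = []
        for s in range(3):
            cell = synthetic.sample_cell_contacts(block_arch, 1200, seed=60 + s)
            seg_nbt = call_tads_nbt(cell, seed=70 + s, cluster_factor=1.0)
            seg_mod = gamma_sweep(cell, np.arange(0, 375.001, 1.0)).segmentation_half
            shared.append(
                compare_segmentations(seg_nbt, seg_mod)["shared_boundary_pct"]
            )
        assert np.mean(shared) >= 60.0

    def test_shuffled_maps_share_fewer_boundaries_across_cells(self, block_arch):
        from snfold.maps import shuffle_map
        from snfold.tad_modularity import compare_segmentations

        real_segs, shuf_segs = [], []
        for s in range(3):
            cell = synthetic.sample_cell_contacts(block_arch, 1200, seed=80 + s)
            real_segs.append(call_tads_nbt(cell, seed=90 + s, cluster_factor=1.0))
            shuf = shuffle_map(cell, "per_distance", seed=95 + s)
            shuf_segs.append(call_tads_nbt(shuf, seed=97 + s, cluster_factor=1.0))
        def mean_shared(segs):
            vals = [
                compare_segmentations(a, b)["shared_boundary_pct"]
                for i, a in enumerate(segs)
                for j, b in enumerate(segs)
                if i != j
            ]
            return np.mean(vals)
        assert mean_shared(real_segs) > mean_shared(shuf_segs)
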