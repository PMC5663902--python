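"""Signed Louvain: Q* formula oracle, optimizer behaviour, protocol."""

import numpy as np
import pytest
from sympy.utilities.iterables import multiset_partitions

from modparc import modularity as mo
from modparc.core import Partition, SignedGraph

from conftest import random_signed_graph


def signed_q_oracle(w, labels):
    """Direct evaluation of the asymmetric signed modularity formula,
    independent of the package implementation."""
    w = np.asarray(w, dtype=float)
    wp = np.maximum(w, 0.0)
    wn = np.maximum(-w, 0.0)
    sp, sn = wp.sum(1), wn.sum(1)
    vp, vn = sp.sum(), sn.sum()
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            q += (wp[i, j] - sp[i] * sp[j] / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - sn[i] * sn[j] / vn) / (vp + vn)
    return q


def exhaustive_max_q(graph):
    """Maximum Q* over every set partition of the nodes (brute force)."""
    n = graph.n_nodes
    b = mo.modularity_matrix(graph)
    best = -np.inf
    for part in multiset_partitions(list(range(n))):
        lab = np.empty(n, dtype=int)
        for c, blockvals in enumerate(part):
            lab[list(blockvals)] = c
        same = lab[:, None] == lab[None, :]
        best = max(best, b[same].sum())
    return best


class TestSignedQ:
    def test_single_community_positive_graph_is_zero(self, rng):
        w = np.abs(rng.normal(1, 0.3, (6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        assert mo.signed_q(g, np.ones(6, int)) == pytest.approx(0.0, abs=1e-12)

    def test_four_node_paired_graph_matches_formula_oracle(self):
        # +1 inside pairs {0,1} and {2,3}, -1 between pairs
        w = np.array(
            [
                [0, 1, -1, -1],
                [1, 0, -1, -1],
                [-1, -1, 0, 1],
                [-1, -1, 1, 0],
            ],
            dtype=float,
        )
        g = SignedGraph(w)
        labels = [1, 1, 2, 2]
        assert mo.signed_q(g, labels) == pytest.approx(
            signed_q_oracle(w, labels), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_oracle_on_random_signed_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        g = random_signed_graph(rng, rng.integers(3, 9))
        labels = rng.integers(1, 4, g.n_nodes)
        assert mo.signed_q(g, labels) == pytest.approx(
            signed_q_oracle(g.weights, labels), abs=1e-10
        )

    def test_label_permutation_invariance(self, rng):
        g = random_signed_graph(rng, 12)
        labels = rng.integers(0, 4, 12)
        perm = {v: i for i, v in enumerate(rng.permutation(5))}
        relabeled = np.array([perm[v] for v in labels])
        assert mo.signed_q(g, labels + 1) == pytest.approx(
            mo.signed_q(g, relabeled + 1), abs=1e-12
        )

    def test_all_positive_reduces_to_newman_girvan(self, rng):
        import networkx as nx

        w = np.abs(rng.normal(0.5, 0.2, (15, 15)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        labels = rng.integers(0, 3, 15)
        gx = nx.from_numpy_array(w)
        communities = [set(np.flatnonzero(labels == c)) for c in range(3)]
        communities = [c for c in communities if c]
        expected = nx.algorithms.community.modularity(gx, communities, weight="weight")
        assert mo.signed_q(g, labels + 1) == pytest.approx(expected, abs=1e-10)

    def test_all_negative_rejected(self):
        w = -np.ones((3, 3))
        np.fill_diagonal(w, 0)
        with pytest.raises(ValueError, match="positive"):
            mo.signed_q(SignedGraph(w), [1, 1, 1])


class TestLocalMoving:
    def test_merges_disconnected_positive_cliques(self, rng):
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        labels, improved = mo.local_moving_pass(g, np.arange(1, 9), rng)
        assert improved
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:4])) == 1 and len(np.unique(labels[4:])) == 1

    def test_no_move_from_optimum(self, rng):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        w[w == 0] = -0.5
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        opt = np.array([1, 1, 1, 2, 2, 2])
        labels, improved = mo.local_moving_pass(g, opt, rng)
        assert not improved
        assert len(np.unique(labels)) == 2

    def test_single_node_graph(self, rng):
        g = SignedGraph(np.zeros((1, 1)), pos=np.ones((1, 1)), neg=np.zeros((1, 1)))
        labels, improved = mo.local_moving_pass(g, [1], rng)
        assert not improved and labels.tolist() == [1]

    def test_incremental_gain_matches_full_recomputation(self, rng):
        # bookkeeping Delta-Q for a single move vs. before/after signed_q
        g = random_signed_graph(rng, 10)
        b = mo.modularity_matrix(g)
        labels = rng.integers(0, 3, 10)
        for i in range(10):
            for c in range(3):
                a = labels[i]
                if c == a:
                    continue
                sic = b[i, labels == c].sum()
                sia = b[i, labels == a].sum() - b[i, i]
                delta = 2 * (sic - sia)
                moved = labels.copy()
                moved[i] = c
                full = mo.signed_q(g, moved + 1) - mo.signed_q(g, labels + 1)
                assert delta == pytest.approx(full, abs=1e-10)


class TestAggregation:
    def test_singleton_aggregation_is_identity(self, rng):
        g = random_signed_graph(rng, 7)
        agg = mo.aggregate_graph(g, np.arange(1, 8))
        assert np.allclose(agg.weights, g.weights)

    def test_q_invariant_under_aggregation(self, rng):
        for _ in range(5):
            g = random_signed_graph(rng, 12)
            labels = rng.integers(1, 5, 12)
            agg = mo.aggregate_graph(g, labels)
            q_orig = mo.signed_q(g, labels)
            q_agg = mo.signed_q(agg, np.arange(1, agg.n_nodes + 1))
            assert q_agg == pytest.approx(q_orig, abs=1e-12)

    def test_single_community_gives_total_self_loop(self, rng):
        g = random_signed_graph(rng, 5)
        agg = mo.aggregate_graph(g, np.ones(5, int))
        assert agg.n_nodes == 1
        assert agg.weights[0, 0] == pytest.approx(g.weights.sum())


class TestLouvainRun:
    def test_two_node_positive_edge_merges(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = SignedGraph(w)
        part = mo.louvain_run(g, np.random.default_rng(0))
        assert part.n_modules == 1
        # compare Q of both candidate partitions directly
        assert mo.signed_q(g, [1, 1]) > mo.signed_q(g, [1, 2])

    def test_zero_weight_graph_rejected(self):
        g = SignedGraph(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="positive"):
            mo.louvain_run(g, np.random.default_rng(0))

    def test_planted_three_blocks_recovered(self):
        rng = np.random.default_rng(5)
        sizes = [60, 70, 70]
        labels_true = np.repeat([0, 1, 2], sizes)
        n = len(labels_true)
        same = labels_true[:, None] == labels_true[None, :]
        w = np.where(same, 0.6, 0.1) + 0.05 * rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        hits = 0
        for s in range(20):
            part = mo.louvain_run(g, np.random.default_rng(s))
            if part.n_modules == 3:
                from sklearn.metrics import adjusted_rand_score

                if adjusted_rand_score(labels_true, part.labels) == 1.0:
                    hits += 1
        assert hits >= 19


class TestMaxQProtocol:
    def test_planted_graph_terminates_in_two_blocks(self):
        rng = np.random.default_rng(8)
        labels_true = np.repeat([0, 1, 2], [20, 25, 25])
        n = len(labels_true)
        same = labels_true[:, None] == labels_true[None, :]
        w = np.where(same, 0.6, 0.1) + 0.05 * rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        part, trace = mo.max_q_protocol(SignedGraph(w), seed=1)
        assert trace.n_blocks == 2
        assert round(trace.block_best_q[0], 4) == round(trace.block_best_q[1], 4)
        assert len(set(trace.module_count_per_block)) == 1

    def test_block_size_one_on_deterministic_graph(self):
        g = SignedGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        part, trace = mo.max_q_protocol(g, block_size=1, seed=0)
        assert trace.n_blocks == 2
        assert part.n_modules == 1

    def test_protocol_deterministic_given_seed(self, rng):
        g = random_signed_graph(rng, 30)
        p1, t1 = mo.max_q_protocol(g, block_size=20, seed=33)
        p2, t2 = mo.max_q_protocol(g, block_size=20, seed=33)
        assert np.array_equal(p1.labels, p2.labels)
        assert t1.block_best_q == t2.block_best_q


class TestFineTune:
    def test_optimal_partition_unchanged(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        w[w == 0] = -0.5
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        part = Partition(np.array([1, 1, 1, 2, 2, 2]), mo.signed_q(g, [1, 1, 1, 2, 2, 2]), 2)
        out = mo.fine_tune(g, part, seed=0, block_size=10)
        assert np.array_equal(out.labels, part.labels)
        assert out.q == pytest.approx(part.q)

    def test_restores_mislabeled_border_nodes(self):
        rng = np.random.default_rng(17)
        labels_true = np.repeat([1, 2, 3], [30, 35, 35])
        n = len(labels_true)
        same = labels_true[:, None] == labels_true[None, :]
        w = np.where(same, 0.6, 0.1) + 0.05 * rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = SignedGraph(w)
        corrupted = labels_true.copy()
        flip = rng.choice(n, 5, replace=False)
        corrupted[flip] = corrupted[flip] % 3 + 1
        part = Partition(
            np.unique(corrupted, return_inverse=True)[1] + 1,
            mo.signed_q(g, corrupted),
            len(np.unique(corrupted)),
        )
        out = mo.fine_tune(g, part, seed=2, block_size=20)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels_true, out.labels) == 1.0

    @pytest.mark.parametrize("trial", range(20))
    def test_monotone_q_on_random_graphs(self, trial):
        rng = np.random.default_rng(300 + trial)
        g = random_signed_graph(rng, 15)
        labels = rng.integers(1, 4, 15)
        _, lab = np.unique(labels, return_inverse=True)
        part = Partition(lab + 1, mo.signed_q(g, lab + 1), int(lab.max()) + 1)
        out = mo.fine_tune(g, part, seed=trial, block_size=5)
        assert out.q >= part.q - 1e-12
        # never creates new communities
        assert out.n_modules <= part.n_modules


class TestExhaustiveOracle:
    @pytest.mark.parametrize("trial", range(10))
    def test_protocol_reaches_global_optimum_small_graphs(self, trial):
        rng = np.random.default_rng(40 + trial)
        g = random_signed_graph(rng, int(rng.integers(4, 8)))
        part, _ = mo.max_q_protocol(g, block_size=50, seed=trial)
        best = exhaustive_max_q(g)
        assert part.q <= best + 1e-10  # never exceeds the true optimum
        assert part.q == pytest.approx(best, abs=1e-9)


class TestParcellation:
    def test_module_volume_arithmetic(self):
        coords = np.argwhere(np.ones((10, 10, 2), bool))[:97]
        labels = np.array([1] * 87 + [2] * 10)
        vol, table = mo.parcellate_roi(labels, coords, 8.0, (10, 10, 2))
        assert table.iloc[0]["volume_mm3"] == 696.0  # 87 voxels at 2 mm iso
        assert table.iloc[1]["volume_mm3"] == 80.0

    def test_single_voxel_module(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        vol, table = mo.parcellate_roi([1, 1, 2], coords, 8.0, (3, 1, 1))
        assert table["volume_mm3"].min() == 8.0

    def test_volumes_conserve_roi_and_order_by_size(self, rng):
        coords = np.argwhere(np.ones((6, 6, 6), bool))[:100]
        labels = rng.integers(1, 4, 100)
        vol, table = mo.parcellate_roi(labels, coords, 8.0, (6, 6, 6))
        assert table["volume_mm3"].sum() == 800.0
        assert (np.diff(table["n_voxels"]) <= 0).all()
        assert (vol > 0).sum() == 100
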