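import numpy as np
import pytest

from helpers import brute_modularity, random_partition, random_weighted_graph
from netconsensus import (
    ConnectivityMatrix,
    SubjectEnsemble,
    ThresholdedGraph,
    best_of_n,
    detect_ga,
    detect_is,
    detect_vts,
    louvain,
    modularity,
    nmi,
    recalc_modularity,
    threshold_by_density,
)


def _graph(adj):
    n = adj.shape[0]
    return ThresholdedGraph(adj, density=max(np.count_nonzero(adj) / (n * (n - 1)), 1e-6))


class TestModularity:
    def test_single_community_is_zero(self, two_triangles):
        assert modularity(two_triangles, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_two_triangles_hand_value(self, two_triangles):
        # 2 * (3/6 - (6/12)^2) = 0.5
        assert modularity(two_triangles, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            adj = random_weighted_graph(rng, n)
            p = random_partition(rng, n, 4)
            assert modularity(_graph(adj), p) == pytest.approx(
                brute_modularity(adj, p), abs=1e-12
            )

    def test_relabel_invariance(self):
        rng = np.random.default_rng(1)
        adj = random_weighted_graph(rng, 8)
        p = random_partition(rng, 8, 3)
        shifted = p + 17
        assert modularity(_graph(adj), p) == pytest.approx(
            modularity(_graph(adj), shifted), abs=1e-14
        )

    def test_networkx_cross_check(self, two_cliques):
        import networkx as nx

        g = nx.from_numpy_array(two_cliques.adjacency)
        p = np.repeat([0, 1], 5)
        expected = nx.community.modularity(g, [set(range(5)), set(range(5, 10))])
        assert modularity(two_cliques, p) == pytest.approx(expected, abs=1e-12)

    def test_partition_size_mismatch(self, two_triangles):
        with pytest.raises(ValueError):
            modularity(two_triangles, [0, 0, 1])


class TestLouvain:
    def test_recovers_two_cliques_any_seed(self, two_cliques):
        for seed in range(10):
            p, q = louvain(two_cliques, seed=seed)
            assert nmi(p, np.repeat([0, 1], 5)) == 1.0
            assert q == pytest.approx(modularity(two_cliques, p))

    def test_planted_partition_recovery(self, small_planted):
        ensemble, truth = small_planted
        g = threshold_by_density(ensemble.matrices[0], 0.2)
        p, _ = louvain(g, seed=0)
        assert nmi(p, truth) == 1.0

    def test_determinism(self, two_cliques):
        p1, q1 = louvain(two_cliques, seed=5)
        p2, q2 = louvain(two_cliques, seed=5)
        assert np.array_equal(p1, p2)
        assert q1 == q2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            louvain(ThresholdedGraph(np.zeros((4, 4)), density=0.5), seed=0)

    def test_comparable_to_networkx_louvain(self, small_planted):
        import networkx as nx

        ensemble, _ = small_planted
        graph = threshold_by_density(ensemble.matrices[1], 0.15)
        g = nx.from_numpy_array(graph.adjacency)
        nx_comms = nx.community.louvain_communities(g, seed=1, weight="weight")
        nx_q = nx.community.modularity(g, nx_comms, weight="weight")
        _, q = best_of_n(graph, n_runs=10, seed=1)
        assert q >= nx_q - 0.02


class TestBestOfN:
    def test_n_one_equals_single_run(self, two_cliques):
        p1, q1 = best_of_n(two_cliques, n_runs=1, seed=9)
        assert q1 == pytest.approx(modularity(two_cliques, p1))

    def test_max_dominates_single_run(self, small_planted):
        ensemble, _ = small_planted
        g = threshold_by_density(ensemble.matrices[2], 0.1)
        _, q_best = best_of_n(g, n_runs=20, seed=3)
        for seed in range(5):
            _, q_single = louvain(g, seed=seed)
            assert q_best >= q_single - 1e-12

    def test_trivial_topology_all_runs_identical(self, two_triangles):
        parts = [louvain(two_triangles, seed=s)[0] for s in range(100)]
        assert all(nmi(parts[0], p) == 1.0 for p in parts)
        p, _ = best_of_n(two_triangles, n_runs=100, seed=0)
        assert nmi(p, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_invalid_n_runs(self, two_triangles):
        with pytest.raises(ValueError):
            best_of_n(two_triangles, n_runs=0)


class TestDetectVTS:
    def test_identical_subjects_reduce_to_single_matrix(self, identical_ensemble):
        ref, _ = best_of_n(
            threshold_by_density(identical_ensemble.matrices[0], 0.2),
            n_runs=10,
            seed=4,
        )
        p = detect_vts(identical_ensemble, 0.2, n_runs=10, seed=4)
        assert nmi(p, ref) == 1.0

    def test_recovers_planted_partition(self, small_planted):
        ensemble, truth = small_planted
        p = detect_vts(ensemble, 0.15, n_runs=10, seed=0)
        assert nmi(p, truth) == 1.0

    def test_constant_mean_matrix_handled(self):
        # noise cancels to a constant mean: degenerate but must not crash
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 0.4, size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        c = np.full_like(w, 0.5)
        np.fill_diagonal(c, 0)
        ens = SubjectEnsemble(
            (ConnectivityMatrix(w), ConnectivityMatrix(c - w + np.diag(np.diag(w))))
        )
        p = detect_vts(ens, 0.5, n_runs=3, seed=0)
        assert p.shape == (10,)

    def test_subject_order_invariance(self, small_planted):
        ensemble, _ = small_planted
        reordered = SubjectEnsemble(tuple(reversed(ensemble.matrices)))
        p1 = detect_vts(ensemble, 0.2, n_runs=5, seed=1)
        p2 = detect_vts(reordered, 0.2, n_runs=5, seed=1)
        assert nmi(p1, p2) == 1.0


class TestDetectIS:
    def test_identical_subjects_tie_goes_to_first(self, identical_ensemble):
        res = detect_is(identical_ensemble, 0.2, n_runs=5, seed=0)
        assert res.representative_index == 0
        ref, _ = best_of_n(
            threshold_by_density(identical_ensemble.matrices[0], 0.2), n_runs=5, seed=0
        )
        assert nmi(res.partition, ref) == 1.0

    def test_two_subjects_forced_tie(self, small_planted):
        ensemble, _ = small_planted
        pair = SubjectEnsemble(ensemble.matrices[:2])
        res = detect_is(pair, 0.2, n_runs=5, seed=0)
        assert res.representative_index == 0

    def test_outlier_subject_never_representative(self, small_planted):
        ensemble, truth = small_planted
        rng = np.random.default_rng(99)
        # adversary: same weights, randomly relabeled nodes
        perm = rng.permutation(60)
        noise = ensemble.matrices[0].weights[np.ix_(perm, perm)]
        ens = SubjectEnsemble(tuple(ensemble.matrices) + (ConnectivityMatrix(noise),))
        res = detect_is(ens, 0.2, n_runs=5, seed=1)
        assert res.representative_index != ens.n_subjects - 1
        assert nmi(res.partition, truth) == 1.0

    def test_requires_two_subjects(self, small_planted):
        ensemble, _ = small_planted
        solo = SubjectEnsemble(ensemble.matrices[:1])
        with pytest.raises(ValueError):
            detect_is(solo, 0.2)


class TestDetectGA:
    def test_identical_subjects_reduce_to_plain_louvain(self, identical_ensemble):
        ref, _ = best_of_n(
            threshold_by_density(identical_ensemble.matrices[0], 0.2), n_runs=5, seed=2
        )
        p = detect_ga(identical_ensemble, 0.2, n_runs=5, seed=2)
        assert nmi(p, ref) == 1.0

    def test_recovers_planted_partition(self, small_planted):
        ensemble, truth = small_planted
        p = detect_ga(ensemble, 0.15, n_runs=5, seed=0)
        assert nmi(p, truth) == 1.0

    def test_outlier_subject_trimmed(self, small_planted):
        ensemble, truth = small_planted
        rng = np.random.default_rng(7)
        w = rng.uniform(0, 0.8, size=(60, 60))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ens = SubjectEnsemble(tuple(ensemble.matrices) + (ConnectivityMatrix(w),))
        p = detect_ga(ens, 0.15, n_runs=5, seed=0)
        assert nmi(p, truth) == 1.0

    def test_degenerate_band_falls_back_with_warning(self, small_planted):
        ensemble, truth = small_planted
        with pytest.warns(UserWarning, match="percentile band"):
            p = detect_ga(
                ensemble, 0.15, outlier_band=(60.0, 40.0), n_runs=2, seed=0
            )
        assert nmi(p, truth) == 1.0


class TestRecalcModularity:
    def test_consistent_with_own_partition(self, small_planted):
        ensemble, _ = small_planted
        g = threshold_by_density(ensemble.matrices[0], 0.2)
        p, q = best_of_n(g, n_runs=5, seed=0)
        qs = recalc_modularity(p, ensemble, 0.2)
        assert qs[0] == pytest.approx(q)

    def test_single_community_all_zero(self, small_planted):
        ensemble, _ = small_planted
        qs = recalc_modularity(np.zeros(60, dtype=int), ensemble, 0.2)
        assert np.allclose(qs, 0.0)

    def test_planted_beats_random_partition(self, small_planted):
        ensemble, truth = small_planted
        rng = np.random.default_rng(5)
        random_p = rng.permutation(truth)
        q_true = recalc_modularity(truth, ensemble, 0.2)
        q_rand = recalc_modularity(random_p, ensemble, 0.2)
        assert np.all(q_true > q_rand)


def test_modularity_decreases_with_density(small_planted):
    """Recalculated group Q falls (non-strictly) as networks densify."""
    ensemble, truth = small_planted
    qs = [recalc_modularity(truth, ensemble, d).mean() for d in (0.1, 0.2, 0.3, 0.4, 0.5)]
    assert all(a >= b - 1e-9 for a, b in zip(qs, qs[1:]))
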