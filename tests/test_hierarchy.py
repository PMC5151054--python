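import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from constrainet import (Network, Partition, UNASSIGNED, consensus_partition,
                         default_gamma_grid, gamma_sweep, hierarchy_accuracy,
                         local_maxima_partitions, modularity, nmi,
                         generate, SynthSpec)
from conftest import two_cliques


def brute_force_modularity(W, labels, gamma):
    """Independent term-by-term evaluation of the directed modularity."""
    v = W.sum()
    sout = W.sum(axis=1)
    sin = W.sum(axis=0)
    q = 0.0
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * sout[i] * sin[j] / v
    return q / v


def set_partitions(n):
    """All partitions of range(n) as restricted-growth label lists."""
    def rec(i, labels, k):
        if i == n:
            yield list(labels)
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, labels, max(k, c + 1))
    yield from rec(0, [0] * n, 0)


class TestModularity:
    def test_matches_brute_force(self):
        net = two_cliques(2, w=2.0)
        part = Partition([0, 0, 1, 1])
        got = modularity(net, part, gamma=1.0)
        want = brute_force_modularity(net.weights, part.modules, 1.0)
        assert got == pytest.approx(want)

    def test_single_module_closed_form(self):
        # delta == 1 collapses the sum: Q = 1 - (Σ_i s_i^out)(Σ_j s_j^in)/v² = 0
        rng = np.random.default_rng(0)
        W = rng.random((5, 5))
        np.fill_diagonal(W, 0.0)
        net = Network(weights=W)
        v = W.sum()
        want = 1.0 - (W.sum(1).sum() * W.sum(0).sum()) / v**2
        assert want == 0.0
        assert modularity(net, Partition([0] * 5), 1.0) == pytest.approx(want, abs=1e-12)

    def test_monotone_decreasing_in_gamma(self):
        net = two_cliques(3)
        part = Partition([0, 0, 0, 1, 1, 1])
        qs = [modularity(net, part, g) for g in (0.5, 1.0, 1.5, 2.0)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_unassigned_scored_as_singletons(self):
        net = two_cliques(2)
        a = modularity(net, Partition([0, 0, 1, UNASSIGNED]), 1.0)
        b = modularity(net, Partition([0, 0, 1, 2]), 1.0)
        assert a == pytest.approx(b)

    def test_zero_weight_rejected(self):
        net = Network(weights=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            modularity(net, Partition([0, 0, 0]), 1.0)


class TestLocalMaxima:
    def test_two_cliques_global_optimum_found(self, rng):
        """Optimizer matches exhaustive enumeration on the 8-node toy."""
        net = two_cliques(4)
        want_labels = [0, 0, 0, 0, 1, 1, 1, 1]
        best_q, best_labels = -np.inf, None
        for labels in set_partitions(8):
            q = brute_force_modularity(net.weights, labels, 1.0)
            if q > best_q:
                best_q, best_labels = q, labels
        assert Partition(best_labels).same_up_to_labels(Partition(want_labels))
        parts = local_maxima_partitions(net, 1.0, 50, rng)
        qs = [modularity(net, p, 1.0) for p in parts]
        assert max(qs) == pytest.approx(best_q)
        assert parts[int(np.argmax(qs))].same_up_to_labels(Partition(want_labels))

    def test_every_restart_finds_clique_split(self, rng):
        net = two_cliques(4)
        for p in local_maxima_partitions(net, 1.0, 30, rng):
            assert p.same_up_to_labels(Partition([0, 0, 0, 0, 1, 1, 1, 1]))

    def test_fixed_seed_deterministic(self):
        net = two_cliques(3)
        a = local_maxima_partitions(net, 1.0, 1, np.random.default_rng(9))[0]
        b = local_maxima_partitions(net, 1.0, 1, np.random.default_rng(9))[0]
        assert np.array_equal(a.modules, b.modules)

    def test_large_gamma_gives_singletons(self, rng):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = W[2, 0] = 1.0  # 3-ring
        net = Network(weights=W)
        p = local_maxima_partitions(net, 50.0, 5, rng)[0]
        assert p.n_modules == 3


class TestConsensus:
    def test_identical_inputs_fixed_point(self, rng):
        p = Partition([0, 0, 1, 1, 2, 2])
        out = consensus_partition([p] * 7, rng)
        assert out.same_up_to_labels(p)

    def test_label_permuted_copies(self, rng):
        a = Partition([0, 0, 1, 1])
        b = Partition([5, 5, 2, 2])
        out = consensus_partition([a, b], rng)
        assert out.same_up_to_labels(a)

    def test_majority_wins(self, rng):
        a = Partition([0, 0, 0, 0, 1, 1, 1, 1])
        b = Partition([0, 1, 0, 1, 0, 1, 0, 1])
        out = consensus_partition([a] * 90 + [b] * 10, rng)
        assert out.same_up_to_labels(a)

    def test_mismatched_node_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="different node sets"):
            consensus_partition([Partition([0, 1]), Partition([0, 1, 1])], rng)


class TestNMI:
    def test_identical_is_one(self):
        p = Partition([1, 1, 2, 2])
        assert nmi(p, p) == 1.0

    def test_maximally_different_is_zero(self):
        assert nmi(Partition([1, 1, 2, 2]), Partition([1, 2, 1, 2])) == 0.0

    def test_relabeling_is_one(self):
        assert nmi(Partition([0, 0, 1, 2]), Partition([7, 7, 3, 5])) == 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import normalized_mutual_info_score
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=12)
            b = rng.integers(0, 3, size=12)
            want = normalized_mutual_info_score(a, b, average_method="arithmetic")
            got = nmi(Partition(a), Partition(b))
            assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = Partition(rng.integers(0, 4, size=10))
        b = Partition(rng.integers(0, 4, size=10))
        ab, ba = nmi(a, b), nmi(b, a)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            nmi(Partition([0, 1]), Partition([0, 1, 1]))


class TestGammaSweep:
    def test_planted_two_level_structure_found(self, synth_small, rng):
        net, truth = synth_small
        sweep = gamma_sweep(net, default_gamma_grid(0.5, 2.5, 0.1),
                            n_restarts=16, rng=rng)
        assert len(sweep.stable_ranges) >= 2
        best_high = max(nmi(r.partition, truth.high) for r in sweep.stable_ranges)
        best_low = max(nmi(r.partition, truth.low) for r in sweep.stable_ranges)
        assert best_high >= 0.9
        assert best_low >= 0.8

    def test_structureless_network_unstable(self, rng):
        W = np.random.default_rng(0).random((20, 20))
        np.fill_diagonal(W, 0.0)
        net = Network(weights=W)
        sweep = gamma_sweep(net, default_gamma_grid(1.0, 2.0, 0.1),
                            n_restarts=12, rng=rng)
        # at fine resolutions an unstructured matrix yields no long plateaus
        assert all(r.length < 0.4 for r in sweep.stable_ranges)

    def test_single_point_grid_has_no_stable_range(self, synth_small, rng):
        net, _ = synth_small
        sweep = gamma_sweep(net, np.array([1.0]), n_restarts=8, rng=rng)
        assert sweep.stable_ranges == []

    def test_module_count_grows_with_gamma(self, synth_small, rng):
        net, _ = synth_small
        sweep = gamma_sweep(net, np.array([0.5, 2.5]), n_restarts=16, rng=rng)
        assert (sweep.partitions[1].n_modules >= sweep.partitions[0].n_modules)


class TestHierarchyAccuracy:
    def test_model_equals_connectome_scores_one(self, synth_small, rng):
        net, truth = synth_small
        sweep = gamma_sweep(net, default_gamma_grid(0.5, 2.5, 0.1),
                            n_restarts=16, rng=rng)
        levels = {"high": (2.0, truth.high), "low": (0.8, truth.low)}
        # scoring the connectome's own sweep against planted levels
        acc = hierarchy_accuracy(sweep, levels)
        assert acc["high"] >= 0.9

    def test_no_stable_partitions_scores_zero(self, synth_small):
        from constrainet.hierarchy import SweepResult
        _, truth = synth_small
        empty = SweepResult(gammas=np.array([1.0]), partitions=[], stable_ranges=[])
        acc = hierarchy_accuracy(empty, {"high": (2.0, truth.high),
                                         "low": (0.8, truth.low)})
        assert acc == {"high": 0.0, "low": 0.0}
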