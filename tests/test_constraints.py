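import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from constrainet import (ConstraintEntry, ConstraintSpec, Feature, Network,
                         Partition, UNASSIGNED, Variant, build_preset,
                         constraint_error, evaluate, module_weight,
                         module_weight_matrix, node_strength, node_wiring_cost)


class TestNodeStrength:
    def test_out_and_in(self, net22):
        assert np.array_equal(node_strength(net22, "out"), [2.0, 3.0])
        assert np.array_equal(node_strength(net22, "in"), [3.0, 2.0])

    def test_zero_matrix(self):
        net = Network(weights=np.zeros((3, 3)))
        assert np.array_equal(node_strength(net, "out"), np.zeros(3))

    def test_conservation(self, synth_default):
        net, _ = synth_default
        assert node_strength(net, "out").sum() == pytest.approx(
            node_strength(net, "in").sum())
        assert node_strength(net, "out").sum() == pytest.approx(net.total_weight)


class TestWiringCost:
    def make(self):
        return Network(weights=[[0.0, 2.0], [3.0, 0.0]],
                       distances=[[0.0, 1.0], [2.0, 0.0]],
                       bandwidths=[[0.0, 4.0], [5.0, 0.0]])

    def test_weighted(self):
        net = self.make()
        assert np.array_equal(node_wiring_cost(net, "out"), [4.0, 10.0])
        assert np.array_equal(node_wiring_cost(net, "in"), [10.0, 4.0])

    def test_binary_substitutes_adjacency(self):
        net = self.make()
        assert np.array_equal(node_wiring_cost(net, "out", binary=True), [1.0, 2.0])

    def test_zero_bandwidth(self):
        net = Network(weights=[[0.0, 2.0], [3.0, 0.0]],
                      distances=[[0.0, 1.0], [2.0, 0.0]],
                      bandwidths=np.zeros((2, 2)))
        assert np.array_equal(node_wiring_cost(net, "out"), [0.0, 0.0])

    def test_missing_matrices_named(self, net22):
        with pytest.raises(ValueError, match="distances"):
            node_wiring_cost(net22, "out")
        net = Network(weights=[[0.0, 1.0], [1.0, 0.0]],
                      distances=[[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="bandwidths"):
            node_wiring_cost(net, "out")


class TestModuleWeight:
    def test_construction_example(self):
        W = np.zeros((4, 4))
        W[0, 1] = 1.0
        W[2, 3] = 1.0
        net = Network(weights=W)
        part = Partition([0, 0, 1, 1])
        assert module_weight(net, part, 0, 0) == 1.0
        assert module_weight(net, part, 1, 1) == 1.0
        assert module_weight(net, part, 0, 1) == 0.0

    def test_all_ones_exhaustive_count(self):
        # oracle: count ordered intra/inter pairs by brute force
        W = np.ones((4, 4)) - np.eye(4)
        net = Network(weights=W)
        part = Partition([0, 0, 1, 1])
        mods = part.modules
        intra = sum(1 for i in range(4) for j in range(4)
                    if i != j and mods[i] == 0 and mods[j] == 0)
        inter = sum(1 for i in range(4) for j in range(4)
                    if i != j and mods[i] == 0 and mods[j] == 1)
        assert module_weight(net, part, 0, 0) == intra == 2
        assert module_weight(net, part, 0, 1) == inter == 4

    def test_unassigned_contribute_nothing(self):
        W = np.ones((3, 3)) - np.eye(3)
        net = Network(weights=W)
        part = Partition([0, 0, UNASSIGNED])
        lm = module_weight_matrix(net, part)
        assert lm.sum() == 2.0  # only the 0<->1 reciprocal pair

    def test_module_sum_conservation(self, synth_default):
        net, truth = synth_default
        # treat UNASSIGNED as its own bucket: totals must add to total weight
        mods = truth.high.modules.copy()
        mods[mods == UNASSIGNED] = truth.high.n_modules
        full = module_weight_matrix(net, Partition(mods))
        assert full.sum() == pytest.approx(net.total_weight)

    def test_unknown_module_rejected(self, net22):
        part = Partition([0, 1])
        with pytest.raises(KeyError):
            module_weight(net22, part, 0, 5)


class TestEvaluate:
    def test_weighted_and_binary(self, net22):
        spec = ConstraintSpec([ConstraintEntry(Feature.OUT_STRENGTH),
                               ConstraintEntry(Feature.OUT_STRENGTH, Variant.BINARY)])
        vals = evaluate(net22, spec)
        assert np.array_equal(vals[0], [2.0, 3.0])
        assert np.array_equal(vals[1], [1.0, 1.0])

    def test_empty_spec(self, net22):
        assert evaluate(net22, ConstraintSpec()) == []


class TestConstraintError:
    def test_zero_iff_exact(self, synth_default):
        net, truth = synth_default
        spec = build_preset("basic_hallmark", high=truth.high)
        vals = evaluate(net, spec)
        for q in (1.0, 2.0, np.inf):
            assert constraint_error(vals, vals, q=q) == 0.0

    def test_hand_evaluated_single_type(self):
        # e = mean|c - t| / mean|t| = ((1+1)/2)/2 = 0.5
        e = constraint_error([np.array([1.0, 3.0])], [np.array([2.0, 2.0])], q=2)
        assert e == pytest.approx(0.5)

    def test_hand_evaluated_two_types(self):
        vals = [np.array([1.0]), np.array([0.7])]
        tgts = [np.array([1.0]), np.array([0.5])]
        # e1 = 0, e2 = 0.4 -> E = sqrt((0 + 0.16)/2)
        assert constraint_error(vals, tgts, q=2) == pytest.approx(
            np.sqrt(0.08), abs=1e-12)

    def test_all_zero_targets_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            constraint_error([np.array([1.0])], [np.array([0.0])])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_scale_and_permutation_invariance(self, seed, alpha):
        rng = np.random.default_rng(seed)
        t = rng.random(6) + 0.1
        c = t + rng.normal(0, 0.3, 6)
        e0 = constraint_error([c], [t], q=2)
        perm = rng.permutation(6)
        assert constraint_error([c[perm]], [t[perm]], q=2) == pytest.approx(e0)
        assert constraint_error([alpha * c], [alpha * t], q=2) == pytest.approx(e0)

    def test_q_infinity_is_max(self):
        vals = [np.array([1.0]), np.array([0.7])]
        tgts = [np.array([1.0]), np.array([0.5])]
        assert constraint_error(vals, tgts, q=np.inf) == pytest.approx(0.4)


class TestPresets:
    def test_basic_hallmark_composition(self, synth_default):
        _, truth = synth_default
        spec = build_preset("basic_hallmark", high=truth.high)
        feats = {(e.feature, e.variant) for e in spec.entries}
        assert feats == {
            (Feature.INTRA_MODULE_WEIGHT, Variant.WEIGHTED),
            (Feature.INTRA_MODULE_WEIGHT, Variant.BINARY),
            (Feature.OUT_STRENGTH, Variant.WEIGHTED),
            (Feature.OUT_STRENGTH, Variant.BINARY),
            (Feature.IN_STRENGTH, Variant.WEIGHTED),
            (Feature.IN_STRENGTH, Variant.BINARY),
        }

    def test_benchmark_adds_inter_and_low(self, synth_default):
        _, truth = synth_default
        spec = build_preset("benchmark", high=truth.high, low=truth.low)
        feats = [e.feature for e in spec.entries]
        assert Feature.INTER_MODULE_WEIGHT in feats
        names = {e.partition_name for e in spec.entries if e.partition is not None}
        assert names == {"high", "low"}

    def test_weighted_only_variant(self, synth_default):
        _, truth = synth_default
        spec = build_preset("basic_hallmark", high=truth.high,
                            binary_variants=False)
        assert all(e.variant is Variant.WEIGHTED for e in spec.entries)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            build_preset("nonsense")

    def test_missing_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            build_preset("basic_hallmark")
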