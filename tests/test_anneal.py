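import numpy as np
import pytest

from constrainet import (AnnealingSchedule, ConstraintSpec, Network, accept,
                         anneal, build_preset, constraint_error, evaluate,
                         generate, propose_move, sample_ensemble, SynthSpec)
from constrainet import test_schedule as scaled_schedule


@pytest.fixture(scope="module")
def reference():
    net, truth = generate(SynthSpec(n_areas_per_hemisphere=8, n_hubs=1, seed=2))
    return net, truth


class TestProposeMove:
    def test_exchange_moves_weight_into_empty_slot(self, rng):
        W = np.zeros((4, 4))
        W[0, 1] = 5.0
        net = Network(weights=W)
        moved = False
        for _ in range(50):
            cand, move = propose_move(net, rng)
            if not np.array_equal(cand.adjacency, net.adjacency):
                moved = True
                break
        assert moved  # topology can change via empty-slot exchange
        assert np.array_equal(np.sort(cand.weights.ravel()),
                              np.sort(net.weights.ravel()))

    def test_same_move_twice_restores(self, reference, rng):
        net, _ = reference
        cand, move = propose_move(net, rng)
        back, _ = propose_move(cand, rng, move=move)
        assert np.array_equal(back.weights, net.weights)
        assert np.array_equal(back.bandwidths, net.bandwidths)

    def test_mirrored_slots_swapped_together(self, rng):
        net, _ = generate(SynthSpec(n_areas_per_hemisphere=8, n_hubs=1,
                                    mirror_noise=0.0, seed=1))
        m = net.mirror
        for _ in range(200):
            cand, move = propose_move(net, rng)
            # exact mirror symmetry of the reference must be conserved
            assert np.array_equal(cand.weights[np.ix_(m, m)], cand.weights)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="n < 3"):
            propose_move(Network(weights=np.zeros((2, 2))), rng)


class TestAccept:
    def test_downhill_always(self, rng):
        assert all(accept(-0.1, t, rng) for t in (1e-9, 1.0, 100.0))

    def test_uphill_frequency_matches_exponential(self, rng):
        hits = sum(accept(0.1, 1.0, rng) for _ in range(20000))
        assert hits / 20000 == pytest.approx(np.exp(-0.1), abs=0.01)

    def test_uphill_never_at_cold(self, rng):
        assert not any(accept(0.1, 1e-12, rng) for _ in range(100))

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            accept(0.1, 0.0, rng)


class TestAnneal:
    def test_empty_spec_shuffles_with_zero_error(self, reference):
        net, _ = reference
        res = anneal(net, ConstraintSpec(), scaled_schedule(net.n_nodes, seed=3))
        assert res.success and res.error == 0.0
        assert not np.array_equal(res.network.weights, net.weights)
        assert np.array_equal(np.sort(res.network.weights.ravel()),
                              np.sort(net.weights.ravel()))

    def test_basic_hallmark_reaches_tolerance(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        res = anneal(net, spec, scaled_schedule(net.n_nodes, seed=5))
        assert res.success
        assert res.error < 0.005
        assert not np.array_equal(res.network.weights, net.weights)
        # independent full evaluation agrees with the reported error
        e_full = constraint_error(evaluate(res.network, spec),
                                  evaluate(net, spec), q=2)
        assert e_full == pytest.approx(res.error, abs=1e-10)

    def test_weight_multiset_bit_exact(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        res = anneal(net, spec, scaled_schedule(net.n_nodes, seed=6))
        assert np.array_equal(np.sort(res.network.weights.ravel()),
                              np.sort(net.weights.ravel()))

    def test_symmetry_conserved_for_mirror_symmetric_reference(self):
        net, truth = generate(SynthSpec(n_areas_per_hemisphere=8, n_hubs=1,
                                        mirror_noise=0.0, seed=7))
        spec = build_preset("basic_hallmark", high=truth.high)
        res = anneal(net, spec, scaled_schedule(net.n_nodes, seed=1))
        m = net.mirror
        out = res.network.weights
        assert np.array_equal(out[np.ix_(m, m)], out)

    def test_best_error_envelope(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        res = anneal(net, spec, scaled_schedule(net.n_nodes, seed=8))
        assert res.best_error <= res.trace["E"].min() + 1e-12
        assert res.best_error <= res.error + 1e-12

    def test_different_seeds_differ(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        a = anneal(net, spec, scaled_schedule(net.n_nodes, seed=1))
        b = anneal(net, spec, scaled_schedule(net.n_nodes, seed=2))
        assert not np.array_equal(a.network.weights, b.network.weights)
        assert np.array_equal(np.sort(a.network.weights.ravel()),
                              np.sort(b.network.weights.ravel()))

    def test_failure_carries_best_error(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        sched = AnnealingSchedule(stage_length=1000, max_iters=3000,
                                  tolerance=1e-9, seed=0)
        res = anneal(net, spec, sched)
        assert not res.success
        assert res.best_error > 0

    def test_ergodicity_smoke(self):
        W = np.zeros((4, 4))
        W[0, 1], W[1, 2], W[2, 3] = 1.0, 2.0, 3.0
        net = Network(weights=W)
        seen = set()
        for seed in range(10):
            res = anneal(net, ConstraintSpec(), scaled_schedule(4, seed=seed))
            seen.add(tuple(res.network.weights.ravel()))
        assert len(seen) > 3  # multiple distinct placements visited


class TestEnsemble:
    def test_ensemble_of_three(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        results = sample_ensemble(net, spec, scaled_schedule(net.n_nodes, seed=0), 3)
        assert len(results) == 3
        assert all(r.error < 0.005 for r in results)
        assert len({r.seed for r in results}) == 3

    def test_zero_samples_rejected(self, reference):
        net, truth = reference
        spec = build_preset("basic_hallmark", high=truth.high)
        with pytest.raises(ValueError):
            sample_ensemble(net, spec, scaled_schedule(net.n_nodes), 0)


class TestSchedule:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(cool_factor=1.5)
        with pytest.raises(ValueError):
            AnnealingSchedule(stage_length=0)
        with pytest.raises(ValueError):
            AnnealingSchedule(tolerance=0.0)
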