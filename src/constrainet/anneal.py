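"""Primary sampling method: hard-constraint randomization by simulated
annealing.

Each sample starts from an unconstrained shuffle of the reference network
(with preserved bilateral weight relationships) and then minimizes the
normalized constraint error E by Metropolis-accepted slot exchanges: a move
swaps the weights of two off-diagonal slots — empty slots included, so the
binary topology can change — together with their bilaterally mirrored
slots.  Moves that lower E are always accepted; moves that raise it are
accepted with probability exp(−ΔE/T) under a geometric cooling schedule.
The empirical weight multiset is preserved exactly by construction, and
bandwidths travel with their weights while distances stay attached to the
node pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .constraints import (ConstraintSpec, Feature, Variant, evaluate,
                          constraint_error)
from .network import Network, UNASSIGNED

_NODE_CODES = {
    (Feature.OUT_STRENGTH, Variant.WEIGHTED): 0,
    (Feature.IN_STRENGTH, Variant.WEIGHTED): 1,
    (Feature.OUT_STRENGTH, Variant.BINARY): 2,
    (Feature.IN_STRENGTH, Variant.BINARY): 3,
    (Feature.OUT_WIRING_COST, Variant.WEIGHTED): 4,
    (Feature.IN_WIRING_COST, Variant.WEIGHTED): 5,
    (Feature.OUT_WIRING_COST, Variant.BINARY): 6,
    (Feature.IN_WIRING_COST, Variant.BINARY): 7,
}


@dataclass
class AnnealingSchedule:
    """Cooling schedule and stopping rule.

    The full-scale run uses T0=1, a 0.999 cooling factor every 10^4
    iterations, 10^9 iterations in total and tolerance E < 0.005
    (:func:`full_schedule`); :func:`test_schedule` shrinks the stage length
    and iteration budget proportionally for desk-scale networks.
    """

    T0: float = 1.0
    cool_factor: float = 0.999
    stage_length: int = 10_000
    max_iters: int = 1_000_000_000
    tolerance: float = 0.005
    seed: int = 0
    q: float = 2.0
    n_shuffle: int | None = None  # default: 10 n^2 accepted moves

    def __post_init__(self):
        if not (0.0 < self.cool_factor < 1.0):
            raise ValueError("cool_factor must lie in (0, 1)")
        if self.stage_length < 1:
            raise ValueError("stage_length must be >= 1")
        if not (self.tolerance > 0):
            raise ValueError("tolerance must be positive")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")


def full_schedule(seed: int = 0, tolerance: float = 0.005) -> AnnealingSchedule:
    """The full-scale schedule (10^9 iterations).""" 
    return AnnealingSchedule(T0=1.0, cool_factor=0.999, stage_length=10_000,
                             max_iters=1_000_000_000, tolerance=tolerance, seed=seed)


def test_schedule(n_nodes: int, seed: int = 0,
                  tolerance: float = 0.005) -> AnnealingSchedule:
    """Proportionally scaled schedule for small (≤ ~60 node) networks."""
    stage = max(1000, 4 * n_nodes * n_nodes)
    return AnnealingSchedule(T0=1.0, cool_factor=0.995, stage_length=stage,
                             max_iters=12_000 * stage, tolerance=tolerance,
                             seed=seed)


@dataclass
class AnnealResult:
    network: Network
    error: float            # E of the returned network (full recomputation)
    best_error: float       # lowest E seen during the search
    n_iters: int
    success: bool
    seed: int
    trace: dict = field(default_factory=dict)  # iteration / T / E per stage


def _mirror_or_identity(net: Network) -> np.ndarray:
    if net.mirror is not None:
        return net.mirror
    return np.arange(net.n_nodes, dtype=np.int64)


def _compile_spec(net: Network, spec: ConstraintSpec):
    """Translate a ConstraintSpec into the kernel's flat arrays."""
    n = net.n_nodes
    part_slots: list = []
    codes, parts, lens, vecs = [], [], [], []
    targets = evaluate(net, spec)
    for e, tvec in zip(spec.entries, targets):
        key = (e.feature, e.variant)
        if key in _NODE_CODES:
            codes.append(_NODE_CODES[key])
            parts.append(0)
        else:
            pid = None
            for s, p in enumerate(part_slots):
                if p is e.partition:
                    pid = s
            if pid is None:
                if len(part_slots) >= 2:
                    raise ValueError("at most two distinct partitions are supported")
                part_slots.append(e.partition)
                pid = len(part_slots) - 1
            base = 8 if e.feature is Feature.INTRA_MODULE_WEIGHT else 10
            codes.append(base + (1 if e.variant is Variant.BINARY else 0))
            parts.append(pid)
        lens.append(len(tvec))
        vecs.append(np.asarray(tvec, dtype=float))

    k = len(codes)
    maxlen = max(lens) if lens else 1
    tgt = np.zeros((k, maxlen))
    denom = np.ones(k)
    for t, v in enumerate(vecs):
        tgt[t, : len(v)] = v
        d = np.abs(v).sum()
        if d == 0:
            raise ValueError("constraint type with all-zero targets: "
                             "normalization undefined")
        denom[t] = d

    mod1 = np.full(n, UNASSIGNED, dtype=np.int64)
    mod2 = np.full(n, UNASSIGNED, dtype=np.int64)
    M1 = M2 = 1
    if len(part_slots) >= 1:
        mod1 = part_slots[0].modules.astype(np.int64)
        M1 = max(part_slots[0].n_modules, 1)
    if len(part_slots) >= 2:
        mod2 = part_slots[1].modules.astype(np.int64)
        M2 = max(part_slots[1].n_modules, 1)

    return (np.array(codes, dtype=np.int64), np.array(parts, dtype=np.int64),
            tgt, denom, np.array(lens, dtype=np.int64), mod1, mod2, M1, M2)


def anneal(reference: Network, spec: ConstraintSpec,
           schedule: AnnealingSchedule) -> AnnealResult:
    """Sample one constrained random network from the reference.

    The returned network carries the reference's exact weight multiset and
    its bilateral weight relationships; on success its full (non-incremental)
    constraint error against the reference's features is ≤
    ``schedule.tolerance``.
    """
    n = reference.n_nodes
    if n < 3:
        raise ValueError("annealing requires at least 3 nodes")
    spec.validate(reference)
    codes, parts, tgt, denom, lens, mod1, mod2, M1, M2 = _compile_spec(reference, spec)

    W = reference.weights.copy()
    B = (reference.bandwidths.copy() if reference.bandwidths is not None
         else np.zeros_like(W))
    D = (reference.distances if reference.distances is not None
         else np.zeros_like(W))
    mirror = _mirror_or_identity(reference)
    n_shuffle = schedule.n_shuffle if schedule.n_shuffle is not None else 10 * n * n

    status, iters, E_kernel, best_E, n_stages, it_tr, T_tr, E_tr = _kernel.run_anneal(
        W, B, D, mirror, mod1, mod2, M1, M2, codes, parts, tgt, denom, lens,
        float(schedule.q), float(schedule.T0), float(schedule.cool_factor),
        int(schedule.stage_length), int(schedule.max_iters),
        float(schedule.tolerance), int(schedule.seed) % (2**31),
        int(n_shuffle),
    )

    out = reference.with_weights(W, bandwidths=B if reference.bandwidths is not None else None)

    # independent verification: full evaluation through the constraints module
    E_full = constraint_error(evaluate(out, spec), evaluate(reference, spec),
                              q=schedule.q) if len(spec) else 0.0
    if abs(E_full - E_kernel) > 1e-8 * max(1.0, E_full):
        raise RuntimeError(
            f"incremental error {E_kernel} disagrees with full evaluation {E_full}")

    return AnnealResult(
        network=out,
        error=E_full,
        best_error=float(best_E),
        n_iters=int(iters),
        success=(status == _kernel.STATUS_OK),
        seed=int(schedule.seed),
        trace={"iteration": it_tr[:n_stages].copy(),
               "T": T_tr[:n_stages].copy(),
               "E": E_tr[:n_stages].copy()},
    )


def sample_ensemble(reference: Network, spec: ConstraintSpec,
                    schedule: AnnealingSchedule, n_samples: int) -> list[AnnealResult]:
    """Draw ``n_samples`` independent samples (one derived seed each)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seeds = np.random.SeedSequence(schedule.seed).generate_state(n_samples) % (2**31)
    out = []
    for s in seeds:
        sched = AnnealingSchedule(
            T0=schedule.T0, cool_factor=schedule.cool_factor,
            stage_length=schedule.stage_length, max_iters=schedule.max_iters,
            tolerance=schedule.tolerance, seed=int(s), q=schedule.q,
            n_shuffle=schedule.n_shuffle)
        out.append(anneal(reference, spec, sched))
    return out


# ----------------------------------------------------- move primitives

def accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept ΔE ≤ 0, else accept with
    probability exp(−ΔE/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_E <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_E / T))


def propose_move(net: Network, rng: np.random.Generator,
                 move: tuple | None = None):
    """Propose (or re-apply) one mirrored slot exchange.

    Returns ``(candidate, move)`` where ``move = (i, j, k, l, mode)`` with
    mode 1 (the mirrored exchange coincides with the drawn one; applied
    once) or 2 (both applied).  Passing ``move`` back re-applies the same
    exchange, restoring the original network (reversibility).  Proposals
    whose mirrored slots partially collide with the drawn slots are
    discarded and redrawn.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("no nontrivial move space for n < 3")
    mirror = _mirror_or_identity(net)
    if move is None:
        while True:
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            k, l = rng.integers(n), rng.integers(n)
            if k == l or (k == i and l == j):
                continue
            mi, mj, mk, ml = mirror[i], mirror[j], mirror[k], mirror[l]
            s3_is_s1 = (mi == i and mj == j)
            s3_is_s2 = (mi == k and mj == l)
            s4_is_s1 = (mk == i and ml == j)
            s4_is_s2 = (mk == k and ml == l)
            if (s3_is_s1 and s4_is_s2) or (s3_is_s2 and s4_is_s1):
                move = (int(i), int(j), int(k), int(l), 1)
                break
            if s3_is_s1 or s3_is_s2 or s4_is_s1 or s4_is_s2:
                continue
            move = (int(i), int(j), int(k), int(l), 2)
            break
    i, j, k, l, mode = move
    cand = net.copy()
    W = cand.weights
    B = cand.bandwidths

    def _swap(a, b, c, d):
        W[a, b], W[c, d] = W[c, d], W[a, b]
        if B is not None:
            B[a, b], B[c, d] = B[c, d], B[a, b]

    _swap(i, j, k, l)
    if mode == 2:
        _swap(mirror[i], mirror[j], mirror[k], mirror[l])
    return cand, move
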