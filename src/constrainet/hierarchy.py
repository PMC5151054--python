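"""Module-hierarchy detection and comparison.

Partitions are scored with the directed weighted modularity

    Q = (1/v) Σ_ij [ w_ij − γ · s_i^out s_j^in / v ] δ(m_i, m_j),

where v is the total network weight and γ a resolution parameter (higher γ
→ smaller modules).  Characteristic partitions per γ come from consensus
clustering over many local-maxima partitions of a randomized greedy
multi-level (Louvain-style) optimizer; partitions are called stable when
the consensus partition does not change over a γ interval of at least 0.2.
Partition similarity is the normalized mutual information
NMI = 2·I / (S1 + S2) (entropies in bits), 1 for identical partitions (up
to labels) and 0 for independent ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from numba import njit

from .network import Network, Partition, UNASSIGNED


# ------------------------------------------------------------ modularity

def _score_labels(W, sout, sin, v, gamma, labels) -> float:
    q = 0.0
    for m in np.unique(labels):
        idx = labels == m
        q += W[np.ix_(idx, idx)].sum() - gamma * sout[idx].sum() * sin[idx].sum() / v
    return q / v


def modularity(net: Network, part: Partition, gamma: float = 1.0) -> float:
    """Directed weighted modularity; UNASSIGNED nodes are scored as
    singleton modules."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    W = net.weights
    v = W.sum()
    if v == 0:
        raise ValueError("modularity undefined for a network with zero total weight")
    labels = part.modules.copy()
    nxt = part.n_modules
    for i in np.nonzero(labels == UNASSIGNED)[0]:
        labels[i] = nxt
        nxt += 1
    sout = W.sum(axis=1)
    sin = W.sum(axis=0)
    return float(_score_labels(W, sout, sin, v, gamma, labels))


# ------------------------------------------------------ Louvain optimizer

@njit(cache=True)
def _one_level_nb(W, gamma, v, seed, labels):
    """Greedy single-node moves to a local maximum (labels updated in place)."""
    np.random.seed(seed)
    n = W.shape[0]
    sout = np.zeros(n)
    sin = np.zeros(n)
    for i in range(n):
        for j in range(n):
            sout[i] += W[i, j]
            sin[j] += W[i, j]
    Sout = np.zeros(n)
    Sin = np.zeros(n)
    for i in range(n):
        Sout[labels[i]] += sout[i]
        Sin[labels[i]] += sin[i]
    w_to = np.zeros(n)
    w_from = np.zeros(n)
    improved = True
    while improved:
        improved = False
        perm = np.random.permutation(n)
        for t in range(n):
            i = perm[t]
            ci = labels[i]
            Sout[ci] -= sout[i]
            Sin[ci] -= sin[i]
            for c in range(n):
                w_to[c] = 0.0
                w_from[c] = 0.0
            for j in range(n):
                w_to[labels[j]] += W[i, j]
                w_from[labels[j]] += W[j, i]
            w_to[ci] -= W[i, i]  # self-loop is community-independent
            w_from[ci] -= W[i, i]
            best = ci
            best_gain = (w_to[ci] + w_from[ci]
                         - gamma * (sout[i] * Sin[ci] + sin[i] * Sout[ci]) / v)
            for c in range(n):
                if c == ci:
                    continue
                g = (w_to[c] + w_from[c]
                     - gamma * (sout[i] * Sin[c] + sin[i] * Sout[c]) / v)
                if g > best_gain + 1e-12:
                    best = c
                    best_gain = g
            if best != ci:
                improved = True
                labels[i] = best
            Sout[best] += sout[i]
            Sin[best] += sin[i]


def _one_level(W, gamma, v, rng, init=None):
    labels = np.arange(W.shape[0]) if init is None else np.asarray(init).copy()
    _one_level_nb(W, float(gamma), float(v), int(rng.integers(2**31)), labels)
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _louvain(W, gamma, rng):
    """Multi-level optimization followed by a single-node refinement pass
    on the original network (so the result is a local maximum under
    single-node moves)."""
    v = W.sum()
    labels = _one_level(W, gamma, v, rng)
    full = labels.copy()
    Wc = W
    while True:
        k = labels.max() + 1
        if k == Wc.shape[0]:
            break
        # aggregate communities into super-nodes (self-loops keep intra weight)
        agg = np.zeros((k, k))
        for m in range(k):
            idx = labels == m
            agg[m] = np.bincount(labels, weights=W_rows_sum(Wc, idx), minlength=k)
        Wc = agg
        labels = _one_level(Wc, gamma, v, rng)
        full = labels[full]
        if labels.max() + 1 == Wc.shape[0]:
            break
    full = _one_level(W, gamma, v, rng, init=full)
    return full


def W_rows_sum(W, idx):
    return W[idx].sum(axis=0)


def local_maxima_partitions(net: Network, gamma: float, n_restarts: int,
                            rng: np.random.Generator) -> list[Partition]:
    """Independent randomized restarts of the greedy optimizer."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    W = net.weights
    if W.sum() == 0:
        raise ValueError("cannot partition a network with zero total weight")
    return [Partition(_louvain(W, gamma, rng), gamma=gamma)
            for _ in range(n_restarts)]


# --------------------------------------------------------------- consensus

def _coassignment(partitions: list[Partition]) -> np.ndarray:
    n = partitions[0].n_nodes
    C = np.zeros((n, n))
    for p in partitions:
        m = p.modules
        same = (m[:, None] == m[None, :]) & (m[:, None] != UNASSIGNED)
        C += same
    C /= len(partitions)
    np.fill_diagonal(C, 0.0)
    return C


def _null_coassignment(partitions: list[Partition]) -> float:
    """Expected co-assignment of two distinct nodes under random label
    permutations (analytic)."""
    n = partitions[0].n_nodes
    acc = 0.0
    for p in partitions:
        sizes = np.bincount(p.modules[p.modules != UNASSIGNED]) \
            if p.n_modules else np.array([])
        acc += sum(s * (s - 1) for s in sizes) / (n * (n - 1))
    return acc / len(partitions)


def consensus_partition(partitions: list[Partition],
                        rng: np.random.Generator,
                        n_restarts: int | None = None,
                        max_rounds: int = 100) -> Partition:
    """Iterative consensus clustering: threshold the co-assignment matrix
    at its permutation-null expectation and re-cluster until all restarts
    agree."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValueError("partitions cover different node sets")
    if n_restarts is None:
        n_restarts = min(len(partitions), 32)

    current = partitions
    for _ in range(max_rounds):
        first = current[0]
        if all(first.same_up_to_labels(p) for p in current[1:]):
            return Partition(first.modules.copy(), gamma=first.gamma)
        C = _coassignment(current)
        tau = _null_coassignment(current)
        C = np.where(C >= tau, C, 0.0)
        if C.sum() == 0:  # no agreement above chance: all singletons
            return Partition(np.arange(n))
        net = Network(weights=C)
        current = local_maxima_partitions(net, 1.0, n_restarts, rng)
    return Partition(current[0].modules.copy())


# ------------------------------------------------------------------- NMI

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information 2·I/(S1+S2), in [0, 1]; UNASSIGNED is
    its own category.  Two partitions that are both single-category (zero
    entropy) are identical and score 1."""
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions cover different node sets")
    a = p1.modules
    b = p2.modules
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    joint = np.zeros((ka, kb))
    np.add.at(joint, (ai, bi), 1.0)
    s1 = _entropy(joint.sum(axis=1))
    s2 = _entropy(joint.sum(axis=0))
    s12 = _entropy(joint.ravel())
    if s1 + s2 == 0.0:
        return 1.0
    i = s1 + s2 - s12
    return float(np.clip(2.0 * i / (s1 + s2), 0.0, 1.0))


# ----------------------------------------------------------------- sweep

@dataclass
class StableRange:
    gamma_start: float
    gamma_end: float
    partition: Partition

    @property
    def gamma_rep(self) -> float:
        return 0.5 * (self.gamma_start + self.gamma_end)

    @property
    def length(self) -> float:
        return self.gamma_end - self.gamma_start


@dataclass
class SweepResult:
    gammas: np.ndarray
    partitions: list[Partition]         # consensus partition per gamma
    stable_ranges: list[StableRange]


def default_gamma_grid(start: float = 0.5, stop: float = 2.5,
                       step: float = 0.05) -> np.ndarray:
    k = int(round((stop - start) / step))
    return start + step * np.arange(k + 1)


def gamma_sweep(net: Network, gammas: np.ndarray | None = None,
                n_restarts: int = 1000, stability_len: float = 0.2,
                rng: np.random.Generator | None = None) -> SweepResult:
    """Consensus partition per resolution plus maximal stable γ ranges.

    A run of consecutive grid points whose consensus partitions are
    identical (up to labels) and whose γ span is at least ``stability_len``
    is reported as a stable range.
    """
    if gammas is None:
        gammas = default_gamma_grid()
    gammas = np.asarray(gammas, dtype=float)
    if np.any(np.diff(gammas) <= 0):
        raise ValueError("gamma grid must be strictly increasing")
    if stability_len <= 0:
        raise ValueError("stability_len must be positive")
    if rng is None:
        rng = np.random.default_rng()
    cons = []
    for g in gammas:
        parts = local_maxima_partitions(net, float(g), n_restarts, rng)
        cons.append(consensus_partition(parts, rng))
        cons[-1].gamma = float(g)

    ranges = []
    start = 0
    for i in range(1, len(gammas) + 1):
        if i == len(gammas) or not cons[start].same_up_to_labels(cons[i]):
            span = gammas[i - 1] - gammas[start]
            if span >= stability_len:
                ranges.append(StableRange(float(gammas[start]),
                                          float(gammas[i - 1]), cons[start]))
            start = i
    return SweepResult(gammas=gammas, partitions=cons, stable_ranges=ranges)


def hierarchy_accuracy(model_sweep: SweepResult,
                       levels: dict[str, tuple[float, Partition]]) -> dict[str, float]:
    """NMI between each reference level and the model's stable partition
    nearest in γ; 0 when the model has no stable partition.

    ``levels`` maps a level name (e.g. ``"high"``/``"low"``) to
    ``(gamma, partition)`` of the reference connectome.
    """
    out = {}
    for name, (g, ref_part) in levels.items():
        if not model_sweep.stable_ranges:
            out[name] = 0.0
            continue
        nearest = min(model_sweep.stable_ranges,
                      key=lambda r: abs(r.gamma_rep - g))
        out[name] = nmi(nearest.partition, ref_part)
    return out
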