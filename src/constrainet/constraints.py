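"""Network features, constraint specifications and the normalized error E.

Features are node strength (s_i^out = Σ_j w_ij, s_j^in = Σ_i w_ij), node
wiring cost (Σ_j d_ij b_ij per direction), and module weight
(l_uv = Σ_{i∈u} Σ_{j∈v} w_ij).  Every feature has a binary variant in which
weights (and, for wiring cost, bandwidths) are replaced by adjacencies.

The normalized constraint error of achieved values c against targets c̃ is

    e_i = mean_j |c_ij − c̃_ij| / mean_j |c̃_ij|       (per constraint type i)
    E   = ( (1/k) Σ_i e_i^q )^(1/q)                    (generalized mean)

with q = 2 by default (mean squared error); q = 1 gives the mean absolute
error and q → ∞ the maximum error.  E = 0 exactly when every constraint is
met, and a network scored against its own features satisfies E = 0 for
every q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .network import Network, Partition, UNASSIGNED


class Feature(str, Enum):
    OUT_STRENGTH = "out_strength"
    IN_STRENGTH = "in_strength"
    OUT_WIRING_COST = "out_wiring_cost"
    IN_WIRING_COST = "in_wiring_cost"
    INTRA_MODULE_WEIGHT = "intra_module_weight"
    INTER_MODULE_WEIGHT = "inter_module_weight"


class Variant(str, Enum):
    WEIGHTED = "weighted"
    BINARY = "binary"


_MODULE_FEATURES = {Feature.INTRA_MODULE_WEIGHT, Feature.INTER_MODULE_WEIGHT}
_COST_FEATURES = {Feature.OUT_WIRING_COST, Feature.IN_WIRING_COST}


@dataclass(frozen=True)
class ConstraintEntry:
    feature: Feature
    variant: Variant = Variant.WEIGHTED
    partition: Partition | None = None
    partition_name: str | None = None  # cosmetic tag, e.g. "high"/"low"

    def __post_init__(self):
        if self.feature in _MODULE_FEATURES and self.partition is None:
            raise ValueError(f"{self.feature.value} requires a partition")


@dataclass
class ConstraintSpec:
    """Ordered list of constraint entries; k = len(entries) counts each
    (feature, variant, partition) entry as one constraint type."""

    entries: list[ConstraintEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self, net: Network) -> None:
        for e in self.entries:
            if e.feature in _COST_FEATURES:
                if net.distances is None:
                    raise ValueError(f"{e.feature.value} requires a distance matrix")
                if e.variant is Variant.WEIGHTED and net.bandwidths is None:
                    raise ValueError(f"{e.feature.value} requires a bandwidth matrix")
            if e.feature in _MODULE_FEATURES and e.partition.n_nodes != net.n_nodes:
                raise ValueError("partition size does not match network")

    def to_config(self) -> list[dict]:
        return [
            {"feature": e.feature.value, "variant": e.variant.value,
             **({"partition": e.partition_name} if e.partition_name else {})}
            for e in self.entries
        ]


#: Achieved (or target) values: one vector per constraint entry.
ConstraintValues = list[np.ndarray]


# ------------------------------------------------------------- features

def node_strength(net: Network, direction: str, binary: bool = False) -> np.ndarray:
    """Out-strength s_i = Σ_j w_ij or in-strength s_j = Σ_i w_ij
    (degrees for the binary variant)."""
    w = net.adjacency if binary else net.weights
    if direction == "out":
        return w.sum(axis=1)
    if direction == "in":
        return w.sum(axis=0)
    raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")


def node_wiring_cost(net: Network, direction: str, binary: bool = False) -> np.ndarray:
    """Σ_j d_ij·b_ij per node (binary: b_ij replaced by a_ij, so only
    existing connections count)."""
    if net.distances is None:
        raise ValueError("network has no distance matrix (distances missing)")
    if binary:
        b = net.adjacency
    else:
        if net.bandwidths is None:
            raise ValueError("network has no bandwidth matrix (bandwidths missing)")
        b = net.bandwidths
    c = net.distances * b
    np.fill_diagonal(c, 0.0)
    if direction == "out":
        return c.sum(axis=1)
    if direction == "in":
        return c.sum(axis=0)
    raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")


def module_weight_matrix(net: Network, part: Partition, binary: bool = False) -> np.ndarray:
    """M×M matrix of total weights l_uv between modules (diagonal = intra-
    module weight).  UNASSIGNED nodes contribute to no entry."""
    w = (net.adjacency if binary else net.weights).copy()
    np.fill_diagonal(w, 0.0)
    M = part.n_modules
    out = np.zeros((M, M))
    mods = part.modules
    ok = mods != UNASSIGNED
    idx = np.nonzero(ok)[0]
    sub = w[np.ix_(idx, idx)]
    m = mods[idx]
    for u in range(M):
        ru = sub[m == u]
        for v in range(M):
            out[u, v] = ru[:, m == v].sum()
    return out


def module_weight(net: Network, part: Partition, u: int, v: int,
                  binary: bool = False) -> float:
    """Total weight l_uv from module u to module v (l_uu = intra-module)."""
    M = part.n_modules
    if not (0 <= u < M) or not (0 <= v < M):
        raise KeyError(f"unknown module identifier in ({u}, {v})")
    return float(module_weight_matrix(net, part, binary=binary)[u, v])


def _entry_values(net: Network, e: ConstraintEntry) -> np.ndarray:
    binary = e.variant is Variant.BINARY
    if e.feature is Feature.OUT_STRENGTH:
        return node_strength(net, "out", binary)
    if e.feature is Feature.IN_STRENGTH:
        return node_strength(net, "in", binary)
    if e.feature is Feature.OUT_WIRING_COST:
        return node_wiring_cost(net, "out", binary)
    if e.feature is Feature.IN_WIRING_COST:
        return node_wiring_cost(net, "in", binary)
    lm = module_weight_matrix(net, e.partition, binary)
    if e.feature is Feature.INTRA_MODULE_WEIGHT:
        return np.diag(lm).copy()
    M = lm.shape[0]
    off = ~np.eye(M, dtype=bool)
    return lm[off]  # ordered module pairs u≠v, row-major


def evaluate(net: Network, spec: ConstraintSpec) -> ConstraintValues:
    """Evaluate every constraint entry on the network (deterministic)."""
    spec.validate(net)
    return [_entry_values(net, e) for e in spec.entries]


# -------------------------------------------------------------- error E

def constraint_error(values: ConstraintValues, targets: ConstraintValues,
                     q: float = 2.0) -> float:
    """Normalized constraint error E (generalized mean of per-type errors).

    ``q`` ≥ 1, or ``numpy.inf`` for the maximum error.  A constraint type
    whose targets are all zero has an undefined normalization and raises.
    """
    if len(values) != len(targets):
        raise ValueError("values and targets have different numbers of constraint types")
    if len(values) == 0:
        return 0.0
    if not (q >= 1.0):
        raise ValueError("q must be >= 1")
    errs = []
    for c, t in zip(values, targets):
        c = np.asarray(c, dtype=float)
        t = np.asarray(t, dtype=float)
        if c.shape != t.shape:
            raise ValueError("constraint vector shapes differ between values and targets")
        denom = np.abs(t).mean()
        if denom == 0:
            raise ValueError("constraint type with all-zero targets: normalization undefined")
        errs.append(np.abs(c - t).mean() / denom)
    errs = np.array(errs)
    if np.isinf(q):
        return float(errs.max())
    return float((np.mean(errs**q)) ** (1.0 / q))


# -------------------------------------------------------------- presets

PRESETS = ("wiring_cost", "wiring_cost_strength", "intra_module_only",
           "basic_hallmark", "benchmark")


def build_preset(name: str, high: Partition | None = None,
                 low: Partition | None = None,
                 binary_variants: bool = True) -> ConstraintSpec:
    """Assemble the constraint set of a named model.

    * ``wiring_cost``          — out/in node wiring cost.
    * ``wiring_cost_strength`` — wiring cost plus out/in node strength.
    * ``intra_module_only``    — intra-module weight (high-resolution
      partition) without node strength.
    * ``basic_hallmark``       — intra-module weight plus node strength.
    * ``benchmark``            — intra- and inter-module weight at both the
      high- and low-resolution partitions, plus node strength.

    ``binary_variants=False`` builds the weighted-only variant used by the
    soft-constraint sampler and the weighted-only hard-constraint sampler.
    """
    variants = [Variant.WEIGHTED, Variant.BINARY] if binary_variants else [Variant.WEIGHTED]

    def need_high():
        if high is None:
            raise ValueError(f"preset {name!r} requires a high-resolution partition")

    features: list[tuple[Feature, Partition | None, str | None]] = []
    if name == "wiring_cost":
        features = [(Feature.OUT_WIRING_COST, None, None),
                    (Feature.IN_WIRING_COST, None, None)]
    elif name == "wiring_cost_strength":
        features = [(Feature.OUT_WIRING_COST, None, None),
                    (Feature.IN_WIRING_COST, None, None),
                    (Feature.OUT_STRENGTH, None, None),
                    (Feature.IN_STRENGTH, None, None)]
    elif name == "intra_module_only":
        need_high()
        features = [(Feature.INTRA_MODULE_WEIGHT, high, "high")]
    elif name == "basic_hallmark":
        need_high()
        features = [(Feature.INTRA_MODULE_WEIGHT, high, "high"),
                    (Feature.OUT_STRENGTH, None, None),
                    (Feature.IN_STRENGTH, None, None)]
    elif name == "benchmark":
        need_high()
        if low is None:
            raise ValueError("preset 'benchmark' requires a low-resolution partition")
        features = [(Feature.INTRA_MODULE_WEIGHT, high, "high"),
                    (Feature.INTER_MODULE_WEIGHT, high, "high"),
                    (Feature.INTRA_MODULE_WEIGHT, low, "low"),
                    (Feature.INTER_MODULE_WEIGHT, low, "low"),
                    (Feature.OUT_STRENGTH, None, None),
                    (Feature.IN_STRENGTH, None, None)]
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")

    entries = [ConstraintEntry(f, v, p, pn)
               for (f, p, pn) in features for v in variants]
    return ConstraintSpec(entries)
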