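"""Data model for weighted directed networks and node partitions.

A :class:`Network` holds a dense non-negative weights matrix ``W = {w_ij}``
(row = source, column = target, zero = absent connection, zero diagonal),
optionally together with per-slot pathway lengths ``d_ij``, per-connection
bandwidths ``b_ij``, node labels, and a bilateral symmetry pairing mapping
each node to its contralateral homologue (midline nodes map to themselves).

A :class:`Partition` assigns each node to a module, or to
:data:`UNASSIGNED` for nodes that belong to no module (e.g. diversely
connected hub areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Module identifier for nodes that belong to no module.
UNASSIGNED = -1


def _as_matrix(x, n: int | None, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")
    if n is not None and m.shape[0] != n:
        raise ValueError(f"{name} has {m.shape[0]} nodes, expected {n}")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(m < 0):
        raise ValueError(f"{name} contains negative entries")
    return m


def pairs_to_mirror(pairs, n: int) -> np.ndarray:
    """Convert a list of (i, j) index pairs to a mirror permutation array.

    Nodes absent from every pair are treated as midline nodes (self-mirrored).
    The result must be an involution: mirror[mirror[i]] == i.
    """
    mirror = np.arange(n, dtype=np.int64)
    for i, j in pairs:
        mirror[i] = j
        mirror[j] = i
    if not np.array_equal(mirror[mirror], np.arange(n)):
        raise ValueError("symmetry pairing is not an involution")
    return mirror


@dataclass
class Network:
    """Weighted directed network with optional distances, bandwidths and
    bilateral symmetry pairing."""

    weights: np.ndarray
    distances: np.ndarray | None = None
    bandwidths: np.ndarray | None = None
    labels: list[str] | None = None
    mirror: np.ndarray | None = None  # involution; mirror[i] = contralateral node

    def __post_init__(self):
        self.weights = _as_matrix(self.weights, None, "weights")
        n = self.weights.shape[0]
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-connections (nonzero diagonal) are not allowed")
        if self.distances is not None:
            self.distances = _as_matrix(self.distances, n, "distances")
        if self.bandwidths is not None:
            self.bandwidths = _as_matrix(self.bandwidths, n, "bandwidths")
            if np.any(np.diag(self.bandwidths) != 0):
                raise ValueError("bandwidths must have zero diagonal")
        if self.labels is None:
            self.labels = [str(i) for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("number of labels does not match number of nodes")
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if self.mirror is not None:
            self.mirror = np.asarray(self.mirror, dtype=np.int64)
            if self.mirror.shape != (n,):
                raise ValueError("mirror must be a length-n permutation")
            if not np.array_equal(self.mirror[self.mirror], np.arange(n)):
                raise ValueError("symmetry pairing is not an involution")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency a_ij = 1 where w_ij > 0."""
        return (self.weights > 0).astype(float)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_connections / (n * (n - 1))

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def copy(self) -> "Network":
        return Network(
            weights=self.weights.copy(),
            distances=None if self.distances is None else self.distances.copy(),
            bandwidths=None if self.bandwidths is None else self.bandwidths.copy(),
            labels=list(self.labels),
            mirror=None if self.mirror is None else self.mirror.copy(),
        )

    def with_weights(self, weights: np.ndarray, bandwidths: np.ndarray | None = None) -> "Network":
        """Same metadata, new weights (and optionally new bandwidths)."""
        return Network(
            weights=np.asarray(weights, dtype=float),
            distances=None if self.distances is None else self.distances.copy(),
            bandwidths=bandwidths if bandwidths is not None
            else (None if self.bandwidths is None else self.bandwidths.copy()),
            labels=list(self.labels),
            mirror=None if self.mirror is None else self.mirror.copy(),
        )


def bilateral_symmetry_score(net: Network) -> float:
    """Spearman rank correlation between each directed weight and its
    bilaterally mirrored counterpart, over all off-diagonal slots.

    Exactly mirrored weights score 1.0; requires a symmetry pairing.
    """
    if net.mirror is None:
        raise ValueError("network has no bilateral symmetry pairing")
    n = net.n_nodes
    i, j = np.where(~np.eye(n, dtype=bool))
    w = net.weights[i, j]
    wm = net.weights[net.mirror[i], net.mirror[j]]
    rho = stats.spearmanr(w, wm).statistic
    return float(rho)


@dataclass
class Partition:
    """Node-to-module assignment at one resolution.

    ``modules`` holds one integer module id per node; :data:`UNASSIGNED`
    (-1) marks nodes that belong to no module.  ``gamma`` optionally records
    the resolution at which the partition was detected.
    """

    modules: np.ndarray
    gamma: float | None = None

    def __post_init__(self):
        self.modules = np.asarray(self.modules, dtype=np.int64)
        if self.modules.ndim != 1:
            raise ValueError("modules must be a 1-D array of module ids")
        if np.all(self.modules == UNASSIGNED):
            raise ValueError("partition has no non-empty module")
        # relabel assigned modules to consecutive ids 0..M-1 (stable order)
        assigned = self.modules != UNASSIGNED
        ids = np.unique(self.modules[assigned])
        remap = {int(m): k for k, m in enumerate(ids)}
        out = self.modules.copy()
        for i in np.nonzero(assigned)[0]:
            out[i] = remap[int(self.modules[i])]
        self.modules = out

    @property
    def n_nodes(self) -> int:
        return self.modules.shape[0]

    @property
    def n_modules(self) -> int:
        assigned = self.modules[self.modules != UNASSIGNED]
        return int(assigned.max()) + 1 if assigned.size else 0

    @property
    def assigned(self) -> np.ndarray:
        return self.modules != UNASSIGNED

    def members(self, module: int) -> np.ndarray:
        if module < 0 or module >= self.n_modules:
            raise KeyError(f"unknown module identifier {module}")
        return np.nonzero(self.modules == module)[0]

    def same_up_to_labels(self, other: "Partition") -> bool:
        """True if the two partitions induce the same grouping (UNASSIGNED
        counts as its own category)."""
        if self.n_nodes != other.n_nodes:
            return False
        pair = {}
        rev = {}
        for a, b in zip(self.modules, other.modules):
            a, b = int(a), int(b)
            if pair.setdefault(a, b) != b or rev.setdefault(b, a) != a:
                return False
        return True
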