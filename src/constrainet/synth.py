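"""Synthetic interareal-connectome generator.

Emulates the statistical structure of dense interareal connectome
reconstructions: a two-level planted module hierarchy (high-resolution
modules nested inside low-resolution modules, both bilateral), unassigned
hub nodes with high strength and connection diversity that interconnect
densely (the planted rich club), heavy-tailed (log-normal) weights spanning
several orders of magnitude, bilateral symmetry between hemispheres with
optional relative noise, spatial embedding in 3-D (module members
co-located, hemispheres mirrored through the midline plane) yielding
pathway distances, and high connection density.

Bandwidths either equal connection weights (the convention used when no
pathway cross-section data exist) or are drawn independently of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, Partition, UNASSIGNED


@dataclass
class SynthSpec:
    """Generator parameters; defaults define the study conditions used
    throughout the package's tests."""

    n_areas_per_hemisphere: int = 28
    n_high_modules: int = 7
    n_low_modules: int = 4
    nesting: tuple = (0, 0, 1, 1, 2, 2, 3)  # high module -> low module
    n_hubs: int = 4                          # per hemisphere, unassigned
    density: float = 0.6
    weight_mu: float = 0.0                   # ln-scale location of weights
    weight_sigma: float = 0.75               # ln-scale spread; with the module/hub
    # factors the realized weights span ~4 orders of magnitude
    intra_weight_boost: float = 6.0          # low-module factor; high-module factor is its square
    hub_boost: float = 6.0                   # hub connection factor; hub-hub weights get its square
    spatial_dim: int = 3
    mirror_noise: float = 0.1                # relative ln-scale noise between hemispheres
    bandwidth_mode: str = "proportional"     # or "independent"
    seed: int = 0

    def __post_init__(self):
        if len(self.nesting) != self.n_high_modules:
            raise ValueError("nesting must map every high module to a low module")
        if set(self.nesting) != set(range(self.n_low_modules)):
            raise ValueError("nesting must be a surjection onto the low modules")
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.intra_weight_boost < 1 or self.hub_boost < 1:
            raise ValueError("boost factors must be >= 1")
        if self.n_areas_per_hemisphere - self.n_hubs < self.n_high_modules:
            raise ValueError("not enough assigned areas to populate the high modules")
        if self.bandwidth_mode not in ("proportional", "independent"):
            raise ValueError("bandwidth_mode must be 'proportional' or 'independent'")


@dataclass
class GroundTruth:
    high: Partition
    low: Partition
    hubs: np.ndarray                 # node indices of the planted hub set
    clubs: dict = field(default_factory=dict)  # name -> node index array


def _positions(spec: SynthSpec, high_mod, rng) -> np.ndarray:
    """Module-clustered 3-D positions; hemisphere 1 mirrored in x."""
    nh = spec.n_areas_per_hemisphere
    dim = spec.spatial_dim
    low_centers = rng.normal(0, 1, size=(spec.n_low_modules, dim))
    low_centers *= 4.0 / np.maximum(np.linalg.norm(low_centers, axis=1, keepdims=True), 1e-9)
    high_centers = np.array([low_centers[spec.nesting[h]] for h in range(spec.n_high_modules)])
    high_centers += rng.normal(0, 1.0, size=high_centers.shape)
    pos = np.zeros((2 * nh, dim))
    for i in range(nh):
        if high_mod[i] == UNASSIGNED:
            pos[i] = rng.normal(0, 0.8, size=dim)  # hubs near the centre
        else:
            pos[i] = high_centers[high_mod[i]] + rng.normal(0, 0.6, size=dim)
        pos[i, 0] = abs(pos[i, 0]) + 1.0          # hemisphere offset from midline
    pos[nh:] = pos[:nh]
    pos[nh:, 0] *= -1.0                            # mirrored hemisphere
    return pos


def generate(spec: SynthSpec) -> tuple[Network, GroundTruth]:
    """Generate a synthetic connectome with planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    nh = spec.n_areas_per_hemisphere
    n = 2 * nh
    n_assigned = nh - spec.n_hubs

    high_mod = np.full(n, UNASSIGNED, dtype=np.int64)
    for i in range(n_assigned):
        high_mod[i] = i % spec.n_high_modules
    high_mod[nh:nh + n_assigned] = high_mod[:n_assigned]
    low_mod = np.full(n, UNASSIGNED, dtype=np.int64)
    ok = high_mod != UNASSIGNED
    low_mod[ok] = np.array(spec.nesting)[high_mod[ok]]
    hubs = np.concatenate([np.arange(n_assigned, nh),
                           np.arange(nh + n_assigned, 2 * nh)])
    mirror = np.concatenate([np.arange(nh, 2 * nh), np.arange(nh)])

    pos = _positions(spec, high_mod, rng)
    D = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))

    # relative connection propensity and weight factors
    b = spec.intra_weight_boost
    h = spec.hub_boost
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    same_low = (low_mod[:, None] == low_mod[None, :]) & ok[:, None] & ok[None, :]
    same_high = (high_mod[:, None] == high_mod[None, :]) & ok[:, None] & ok[None, :]
    F = np.ones((n, n))
    F[same_low] = b
    F[same_high] = b * b
    hub_any = is_hub[:, None] | is_hub[None, :]
    hub_both = is_hub[:, None] & is_hub[None, :]
    F[hub_any] = h
    F[hub_both] = h * h
    np.fill_diagonal(F, 0.0)
    # weight-magnitude factors: hub links are strong as well as dense
    G = F.copy()
    G[hub_any] = h
    G[hub_both] = h * h

    # scale propensities to the target density, honouring the 0.98 cap
    n_off = n * (n - 1)
    cap = 0.98
    if cap * np.count_nonzero(F) / n_off < spec.density:
        raise ValueError("requested density is infeasible for the planted structure")
    lo, hi = 0.0, cap * n_off / F.sum()
    while np.minimum(hi * F, cap).sum() / n_off < spec.density:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * F, cap).sum() / n_off < spec.density:
            lo = mid
        else:
            hi = mid
    P = np.minimum(hi * F, cap)
    np.fill_diagonal(P, 0.0)

    # draw the representative hemisphere-orbit of each slot, then mirror
    W = np.zeros((n, n))
    Bw = np.zeros((n, n))
    independent_bw = spec.bandwidth_mode == "independent"
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            mi, mj = mirror[i], mirror[j]
            if (mi, mj) < (i, j):
                continue  # not the orbit representative
            if rng.random() >= P[i, j]:
                continue
            w = G[i, j] * rng.lognormal(spec.weight_mu, spec.weight_sigma)
            bw = rng.lognormal(spec.weight_mu, spec.weight_sigma) if independent_bw else w
            W[i, j] = w
            Bw[i, j] = bw
            if (mi, mj) != (i, j):
                f = (np.exp(spec.mirror_noise * rng.normal())
                     if spec.mirror_noise > 0 else 1.0)
                W[mi, mj] = w * f
                Bw[mi, mj] = (bw * (np.exp(spec.mirror_noise * rng.normal())
                                    if spec.mirror_noise > 0 else 1.0)
                              if independent_bw else W[mi, mj])

    labels = [f"{'L' if i < nh else 'R'}{i % nh:02d}" for i in range(n)]
    net = Network(weights=W, distances=D, bandwidths=Bw, labels=labels,
                  mirror=mirror)
    truth = GroundTruth(high=Partition(high_mod), low=Partition(low_mod),
                        hubs=hubs, clubs={"hubs": hubs})
    return net, truth
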