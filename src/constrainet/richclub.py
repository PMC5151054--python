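"""Normalized rich-club density.

For a club node set R, the density of a model network relative to the
reference connectome is

    D(R) = Σ_{i,j ∈ R, i≠j} w_ij(model) / Σ_{i,j ∈ R, i≠j} w_ij(reference),

summing both directed orientations and excluding the diagonal.  D is the
inverse rich-club coefficient: a network lacks the rich club when D(R) < 1
and possesses it otherwise (the boundary D = 1 counts as possessing it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network


def _club_weight(net: Network, club: np.ndarray) -> float:
    sub = net.weights[np.ix_(club, club)].copy()
    np.fill_diagonal(sub, 0.0)
    return float(sub.sum())


def rich_club_density(model: Network, reference: Network,
                      club_nodes) -> float:
    """Model/reference intra-club weight ratio D(R)."""
    club = np.asarray(club_nodes, dtype=np.int64)
    if club.size < 2:
        raise ValueError("a rich club needs at least 2 nodes")
    n = reference.n_nodes
    if np.any(club < 0) or np.any(club >= n) or len(set(club.tolist())) != club.size:
        raise ValueError("club_nodes must be distinct valid node indices")
    ref_w = _club_weight(reference, club)
    if ref_w <= 0:
        raise ValueError("reference intra-club weight is zero: density undefined")
    return _club_weight(model, club) / ref_w


def has_rich_club(density: float) -> bool:
    """False iff D(R) < 1 (strict)."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return density >= 1.0


@dataclass
class DensitySummary:
    densities: np.ndarray       # per-sample D(R)
    median: float
    iqr: tuple[float, float]
    mean_network_density: float


def ensemble_density(models: list[Network], reference: Network,
                     club_nodes) -> DensitySummary:
    """Per-sample densities plus median, IQR and the density of the
    ensemble-mean network (equal to the mean density: D is linear in the
    model weights)."""
    if len(models) == 0:
        raise ValueError("empty ensemble")
    d = np.array([rich_club_density(m, reference, club_nodes) for m in models])
    mean_w = np.mean([m.weights for m in models], axis=0)
    mean_net = Network(weights=mean_w)
    d_mean = rich_club_density(mean_net, reference, club_nodes)
    q1, q3 = np.percentile(d, [25, 75])
    return DensitySummary(densities=d, median=float(np.median(d)),
                          iqr=(float(q1), float(q3)),
                          mean_network_density=float(d_mean))
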