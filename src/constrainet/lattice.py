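"""Cost-minimized lattice generative model.

The model re-places the reference's weight multiset onto the spatially
shortest available pathways: the M positive weights, sorted descending, are
assigned one-to-one to the M off-diagonal slots with the smallest
(noise-perturbed) distances, so progressively stronger weights occupy
progressively shorter pathways.  By the rearrangement inequality this
minimizes the total wiring cost Σ d_ij · w_ij over all assignments to those
slots; the small uniform distance noise (default half-width 1% of the
median existing-connection distance) only breaks near-ties between
similar-length pathways.

Candidate slots are all ordered off-diagonal node pairs with a defined
distance, not only the reference's existing connections — a lattice must be
free to re-place connections, which is what gives it its unrealistically
low wiring cost.
"""

from __future__ import annotations

import numpy as np

from .network import Network


def minimized_cost_lattice(reference: Network, noise_frac: float = 0.01,
                           rng: np.random.Generator | None = None) -> Network:
    """Assign the reference's positive weights, strongest first, to the
    shortest perturbed-distance slots."""
    if reference.distances is None:
        raise ValueError("lattice model requires a distance matrix")
    if rng is None:
        rng = np.random.default_rng()
    n = reference.n_nodes
    W = reference.weights
    D = reference.distances

    pos = W > 0
    weights = np.sort(W[pos])[::-1]
    M = weights.size
    if M == 0:
        raise ValueError("reference network has no connections")

    offdiag = ~np.eye(n, dtype=bool)
    slots = np.nonzero(offdiag)[0], np.nonzero(offdiag)[1]
    if M > slots[0].size:
        raise ValueError("more connections than available off-diagonal slots")

    med = float(np.median(D[pos]))
    d = D[slots].astype(float)
    if noise_frac > 0:
        d = d + rng.uniform(-noise_frac * med, noise_frac * med, size=d.size)
    order = np.argsort(d, kind="stable")[:M]

    out = np.zeros((n, n))
    out[slots[0][order], slots[1][order]] = weights
    return reference.with_weights(out, bandwidths=None)


def sample_lattice_ensemble(reference: Network, n_samples: int,
                            noise_frac: float = 0.01,
                            seed: int = 0) -> list[Network]:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = np.random.SeedSequence(seed).spawn(n_samples)
    return [minimized_cost_lattice(reference, noise_frac, np.random.default_rng(s))
            for s in ss]
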