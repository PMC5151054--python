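"""Alternative sampling method: exact maximum-likelihood maximum-entropy
ensembles with soft node-strength and module-weight constraints.

For first-order constraints the maximum-entropy network probability
factorizes over connections: each off-diagonal integer weight w_ij follows
a geometric distribution P_ij(w) = (1 − p_ij) p_ij^w with success parameter

    p_ij = x_i · y_j · z_uv

built from per-node out (x) and in (y) auxiliary variables and a
per-module-pair variable z_uv (u, v the modules of i and j; slots touching
an unassigned node carry z = 1 and are constrained only through strengths).
The expectation of each weight is p_ij / (1 − p_ij), so the
maximum-likelihood conditions are the coupled nonlinear equations

    Σ_j p_ij/(1−p_ij) = s̃_i^out,   Σ_i p_ij/(1−p_ij) = s̃_j^in,
    Σ_{i∈u, j∈v} p_ij/(1−p_ij) = l̃_uv.

They are solved in log-variables by damped Newton iteration with an
analytic Jacobian and a feasibility-preserving line search (p < 1 at every
step), warm-started by a few monotone coordinate sweeps.

Real-valued weights are linearly mapped to integers with a configurable
precision factor before fitting and mapped back after sampling.  Empirical
connection weights are not preserved, binary features are not constrained,
and wiring-cost constraints are not representable in this family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constraints import (ConstraintSpec, ConstraintValues, evaluate,
                          constraint_error)
from .network import Network, Partition, UNASSIGNED


def weight_expectation(p: float) -> float:
    """Mean p/(1−p) of the geometric distribution on {0, 1, 2, ...}."""
    p = float(p)
    if not (0.0 <= p < 1.0):
        raise ValueError("geometric success parameter must satisfy 0 <= p < 1")
    return p / (1.0 - p)


@dataclass
class MaxEntSolution:
    """Fitted auxiliary variables and the induced success-parameter matrix."""

    x: np.ndarray                 # per-node out variables
    y: np.ndarray                 # per-node in variables
    z: np.ndarray                 # per-module-pair variables (M×M), or (0,0)
    p: np.ndarray                 # n×n success parameters, diagonal 0
    partition: Partition | None
    s_out: np.ndarray             # targets on the integer-scaled domain
    s_in: np.ndarray
    l_mod: np.ndarray | None      # M×M module-weight targets (NaN = unconstrained)
    scale: float                  # real weight = integer weight / scale
    residual: float               # max-norm residual of the fitted equations

    @property
    def expected_weights(self) -> np.ndarray:
        """Analytic expectation E[w_ij] on the original (real) weight scale."""
        return self.p / (1.0 - self.p) / self.scale


class _System:
    """The coupled equations in multiplicative variables (x, y, z)."""

    def __init__(self, s_out, s_in, mods, M, l_mod):
        self.s_out = s_out
        self.s_in = s_in
        self.mods = mods
        self.M = M
        self.l_mod = l_mod
        n = s_out.size
        self.n = n
        self.act_out = s_out > 0
        self.act_in = s_in > 0
        # constrained module pairs with positive targets; zero targets force z=0
        self.pairs = []
        if l_mod is not None:
            for u in range(M):
                for v in range(M):
                    if not np.isnan(l_mod[u, v]) and l_mod[u, v] > 0:
                        self.pairs.append((u, v))
        # per-slot module-pair index into self.pairs (-1: no multiplier)
        self.pair_idx = np.full((n, n), -1, dtype=np.int64)
        # slots structurally forced to zero (inactive node or zero module target)
        self.dead = np.zeros((n, n), dtype=bool)
        self.dead |= ~self.act_out[:, None]
        self.dead |= ~self.act_in[None, :]
        np.fill_diagonal(self.dead, True)
        if l_mod is not None:
            lut = {uv: k for k, uv in enumerate(self.pairs)}
            for i in range(n):
                for j in range(n):
                    u, v = mods[i], mods[j]
                    if u < 0 or v < 0 or np.isnan(l_mod[u, v]):
                        continue
                    if l_mod[u, v] <= 0:
                        self.dead[i, j] = True
                    else:
                        self.pair_idx[i, j] = lut[(u, v)]
        self.K = len(self.pairs)

    def p_matrix(self, x, y, z):
        p = np.outer(x, y)
        if self.K:
            zm = np.ones((self.n, self.n))
            mask = self.pair_idx >= 0
            zm[mask] = z[self.pair_idx[mask]]
            p = p * zm
        p[self.dead] = 0.0
        return p

    def residuals(self, p):
        ew = p / (1.0 - p)
        r_out = ew.sum(axis=1) - self.s_out
        r_in = ew.sum(axis=0) - self.s_in
        r_mod = np.array([ew[self.pair_idx == k].sum() - self.l_mod[uv]
                          for k, uv in enumerate(self.pairs)])
        return r_out[self.act_out], r_in[self.act_in], r_mod, ew

    def max_residual(self, p):
        r_out, r_in, r_mod, _ = self.residuals(p)
        parts = [np.abs(r_out).max(initial=0.0), np.abs(r_in).max(initial=0.0)]
        if r_mod.size:
            parts.append(np.abs(r_mod).max())
        return max(parts)


def _coordinate_sweeps(sys: _System, x, y, z, n_sweeps: int):
    """Monotone exact coordinate updates (warm start / fallback)."""

    def g(t):
        return t / (1.0 - t)

    def solve_scalar(target, coef):
        if target <= 0 or not np.any(coef > 0):
            return 0.0
        cmax = coef.max()
        v_hi = (1.0 - 1e-12) / cmax

        def f(v):
            return g(v * coef).sum() - target

        if f(v_hi) <= 0:
            return v_hi
        return brentq(f, 0.0, v_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)

    n = sys.n
    for _ in range(n_sweeps):
        for i in range(n):
            if not sys.act_out[i]:
                x[i] = 0.0
                continue
            coef = y.copy()
            live = ~sys.dead[i]
            coef[~live] = 0.0
            if sys.K:
                m = sys.pair_idx[i] >= 0
                coef[m] *= z[sys.pair_idx[i][m]]
            x[i] = solve_scalar(sys.s_out[i], coef)
        for j in range(n):
            if not sys.act_in[j]:
                y[j] = 0.0
                continue
            coef = x.copy()
            live = ~sys.dead[:, j]
            coef[~live] = 0.0
            if sys.K:
                m = sys.pair_idx[:, j] >= 0
                coef[m] *= z[sys.pair_idx[:, j][m]]
            y[j] = solve_scalar(sys.s_in[j], coef)
        for k, (u, v) in enumerate(sys.pairs):
            mask = sys.pair_idx == k
            coef = np.outer(x, y)[mask]
            z[k] = solve_scalar(sys.l_mod[u, v], coef)
    return x, y, z


def _newton(sys: _System, x, y, z, tol_abs: float, max_iter: int = 200):
    """Damped Newton on log-variables with feasibility line search."""
    n = sys.n
    io = np.nonzero(sys.act_out)[0]
    ii = np.nonzero(sys.act_in)[0]
    K = sys.K

    def pack(x, y, z):
        return np.concatenate([np.log(x[io]), np.log(y[ii]),
                               np.log(z) if K else np.zeros(0)])

    def unpack(v):
        x2 = np.zeros(n)
        y2 = np.zeros(n)
        x2[io] = np.exp(v[:io.size])
        y2[ii] = np.exp(v[io.size:io.size + ii.size])
        z2 = np.exp(v[io.size + ii.size:]) if K else np.zeros(0)
        return x2, y2, z2

    def full_F(p):
        r_out, r_in, r_mod, ew = sys.residuals(p)
        return np.concatenate([r_out, r_in, r_mod]), ew

    v = pack(x, y, z)
    x, y, z = unpack(v)
    p = sys.p_matrix(x, y, z)
    F, ew = full_F(p)
    fnorm = np.abs(F).max()

    out_pos = {g: a for a, g in enumerate(io)}
    in_pos = {g: a for a, g in enumerate(ii)}
    no, ni = io.size, ii.size

    for _ in range(max_iter):
        if fnorm <= tol_abs:
            break
        # h_ij = dg/d(log t) = t/(1-t)^2
        h = p / (1.0 - p) ** 2
        h[sys.dead] = 0.0
        dim = no + ni + K
        J = np.zeros((dim, dim))
        hrow = h[io]            # (no, n)
        hcol = h[:, ii]         # (n, ni)
        J[:no, :no][np.diag_indices(no)] = hrow.sum(axis=1)
        J[:no, no:no + ni] = hrow[:, ii]
        J[no:no + ni, no:no + ni][np.diag_indices(ni)] = hcol.sum(axis=0)
        J[no:no + ni, :no] = hcol[io].T
        for k in range(K):
            mask = sys.pair_idx == k
            hk = np.where(mask, h, 0.0)
            J[:no, no + ni + k] = hk[io].sum(axis=1)
            J[no:no + ni, no + ni + k] = hk[:, ii].sum(axis=0)
            J[no + ni + k, :no] = hk[io].sum(axis=1)
            J[no + ni + k, no:no + ni] = hk[:, ii].sum(axis=0)
            J[no + ni + k, no + ni + k] = hk.sum()
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        # backtracking line search keeping p < 1 and reducing ||F||_inf
        s = 1.0
        improved = False
        for _ in range(40):
            v_try = v + s * step
            x2, y2, z2 = unpack(v_try)
            p2 = sys.p_matrix(x2, y2, z2)
            if p2.max() < 1.0 - 1e-14:
                F2, _ = full_F(p2)
                f2 = np.abs(F2).max()
                if f2 < fnorm:
                    v, x, y, z, p, F, fnorm = v_try, x2, y2, z2, p2, F2, f2
                    improved = True
                    break
            s *= 0.5
        if not improved:
            # fall back to monotone coordinate sweeps and retry
            x, y, z = _coordinate_sweeps(sys, x, y, z, 2)
            v = pack(x, y, z)
            x, y, z = unpack(v)
            p = sys.p_matrix(x, y, z)
            F, ew = full_F(p)
            f_new = np.abs(F).max()
            if f_new >= fnorm * (1 - 1e-12):
                break  # no progress from either method
            fnorm = f_new
    return x, y, z, p, fnorm


def solve_multipliers(s_out, s_in, partition: Partition | None = None,
                      l_mod=None, tol: float = 1e-10, max_sweeps: int = 5,
                      scale: float = 1.0) -> MaxEntSolution:
    """Fit the auxiliary variables to strength (and module-weight) targets.

    ``s_out``/``s_in`` are target out/in strengths on the integer-scaled
    domain (use :func:`fit` for the end-to-end path from a network).
    ``l_mod`` is an M×M matrix of module-weight targets with NaN for
    unconstrained module pairs.  ``tol`` is relative: the residual max-norm
    is driven below ``tol × max(1, total weight / n)``.  Raises on
    inconsistent targets.
    """
    s_out = np.asarray(s_out, dtype=float)
    s_in = np.asarray(s_in, dtype=float)
    n = s_out.size
    if s_in.size != n:
        raise ValueError("s_out and s_in have different lengths")
    if np.any(s_out < 0) or np.any(s_in < 0):
        raise ValueError("strength targets must be non-negative")
    tot_out, tot_in = s_out.sum(), s_in.sum()
    if not np.isclose(tot_out, tot_in, rtol=1e-8, atol=1e-8):
        raise ValueError(
            f"inconsistent targets: sum of out-strengths ({tot_out}) differs "
            f"from sum of in-strengths ({tot_in})")

    mods = (partition.modules if partition is not None
            else np.full(n, UNASSIGNED, dtype=np.int64))
    M = partition.n_modules if partition is not None else 0
    if l_mod is not None:
        l_mod = np.asarray(l_mod, dtype=float)
        if partition is None:
            raise ValueError("module-weight targets require a partition")
        if l_mod.shape != (M, M):
            raise ValueError("l_mod must be M×M for the partition's M modules")
        con = ~np.isnan(l_mod)
        if np.any(l_mod[con] < 0):
            raise ValueError("module-weight targets must be non-negative")
        if np.nansum(l_mod) > tot_out * (1 + 1e-8) + 1e-8:
            raise ValueError("inconsistent targets: module weights exceed total weight")

    sys = _System(s_out, s_in, mods, M, l_mod)

    if tot_out == 0:
        p = np.zeros((n, n))
        return MaxEntSolution(x=np.zeros(n), y=np.zeros(n),
                              z=np.zeros(len(sys.pairs)), p=p,
                              partition=partition, s_out=s_out, s_in=s_in,
                              l_mod=l_mod, scale=scale, residual=0.0)

    # configuration-model-like start, rescaled into feasibility
    tot = max(tot_out, 1.0)
    x = s_out / np.sqrt(tot)
    y = s_in / np.sqrt(tot)
    hi = np.outer(x, y).max()
    if hi >= 0.5:
        f = np.sqrt(0.5 / hi)
        x *= f
        y *= f
    z = np.ones(len(sys.pairs))

    x, y, z = _coordinate_sweeps(sys, x, y, z, max_sweeps)
    tol_abs = tol * max(1.0, tot_out / n)
    x, y, z, p, resid = _newton(sys, x, y, z, tol_abs)

    z_full = np.zeros((M, M)) if l_mod is not None else np.zeros((0, 0))
    if l_mod is not None:
        for k, (u, v) in enumerate(sys.pairs):
            z_full[u, v] = z[k]
    return MaxEntSolution(x=x, y=y, z=z_full, p=p, partition=partition,
                          s_out=s_out, s_in=s_in, l_mod=l_mod, scale=scale,
                          residual=float(resid))


def fit(reference: Network, partition: Partition | None = None,
        constrain_modules: bool = True, intra_only: bool = True,
        precision: float | None = None, tol: float = 1e-10) -> MaxEntSolution:
    """Fit the soft-constraint model to a reference network.

    Targets are the reference's out/in strengths and (optionally) its
    intra-module weights (``intra_only=False`` also constrains every
    ordered inter-module pair).  Real weights are scaled by ``precision``
    (default 10^4 / median positive weight), so the geometric law lives on
    integers fine enough to resolve the empirical weight range.
    """
    if precision is None:
        pos = reference.weights[reference.weights > 0]
        precision = 1.0 if pos.size == 0 else 1e4 / float(np.median(pos))
    s_out = reference.weights.sum(axis=1) * precision
    s_in = reference.weights.sum(axis=0) * precision
    l_mod = None
    part = partition if constrain_modules else None
    if part is not None:
        from .constraints import module_weight_matrix
        lm = module_weight_matrix(reference, part) * precision
        if intra_only:
            l_mod = np.full_like(lm, np.nan)
            np.fill_diagonal(l_mod, np.diag(lm))
        else:
            l_mod = lm
    return solve_multipliers(s_out, s_in, partition=part, l_mod=l_mod,
                             tol=tol, scale=precision)


def sample_network(solution: MaxEntSolution, rng: np.random.Generator,
                   template: Network | None = None) -> Network:
    """Draw one network: independent geometric weights per off-diagonal
    slot, mapped back to the real scale."""
    p = solution.p
    n = p.shape[0]
    w = np.zeros((n, n))
    mask = p > 0
    # numpy's geometric is on {1, 2, ...} with success prob (1 - p)
    w[mask] = rng.geometric(1.0 - p[mask]) - 1
    np.fill_diagonal(w, 0.0)
    w = w / solution.scale
    if template is not None:
        return template.with_weights(w, bandwidths=None)
    return Network(weights=w)


def sample_ensemble(solution: MaxEntSolution, n_samples: int,
                    rng: np.random.Generator,
                    template: Network | None = None) -> list[Network]:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return [sample_network(solution, rng, template) for _ in range(n_samples)]


def mean_network(solution: MaxEntSolution, template: Network | None = None) -> Network:
    """The analytic expectation matrix E[w_ij] as a network."""
    ew = solution.expected_weights
    if template is not None:
        return template.with_weights(ew, bandwidths=None)
    return Network(weights=ew)


def ensemble_constraint_error(nets: list[Network], spec: ConstraintSpec,
                              targets: ConstraintValues, q: float = 2.0):
    """Constraint error of the ensemble mean network, plus per-sample errors.

    Soft constraints hold on the ensemble average, so the mean-network error
    shrinks (≈ N^(−1/2)) with ensemble size while per-sample errors do not.
    """
    if len(nets) == 0:
        raise ValueError("empty ensemble")
    mean_w = np.mean([net.weights for net in nets], axis=0)
    mean_net = nets[0].with_weights(mean_w, bandwidths=None)
    e_mean = constraint_error(evaluate(mean_net, spec), targets, q=q)
    per_sample = [constraint_error(evaluate(net, spec), targets, q=q)
                  for net in nets]
    return e_mean, per_sample
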