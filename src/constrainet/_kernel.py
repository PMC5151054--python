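"""Numba kernel for hard-constraint simulated-annealing randomization.

Constraint state is tracked incrementally: each candidate move exchanges the
weights (and bandwidths) of two off-diagonal slots together with their
bilaterally mirrored slots, touching at most 4 slots, so each affected
constraint vector is updated in O(1) and the per-type sums of absolute
deviations (``sabs``) follow.  A full recomputation once per temperature
stage bounds floating-point drift.

Constraint type codes (one per constraint entry):

====  ==========================================
code  feature
====  ==========================================
0     out-strength, weighted
1     in-strength, weighted
2     out-strength, binary (out-degree)
3     in-strength, binary (in-degree)
4     out wiring cost, weighted (Σ d·b)
5     in wiring cost, weighted
6     out wiring cost, binary (Σ d·a)
7     in wiring cost, binary
8     intra-module weight, weighted
9     intra-module weight, binary
10    inter-module weight, weighted
11    inter-module weight, binary
====  ==========================================

Module codes use the partition in slot ``parts[t]`` (0 or 1); unassigned
nodes (id −1) contribute to no module entry.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_MAX_ITERS = 1


@njit(cache=True, inline="always")
def _pair_index(mu, mv, M):
    # compact row-major index over ordered module pairs with u != v
    if mv < mu:
        return mu * (M - 1) + mv
    return mu * (M - 1) + mv - 1


@njit(cache=True)
def _update_slot(a, b, dw, da, db, D, mod1, mod2, M1, M2,
                 codes, parts, cur, tgt, sabs):
    """Apply the (dw, da, db) change at slot (a, b) to every constraint."""
    for t in range(codes.shape[0]):
        code = codes[t]
        idx = -1
        delta = 0.0
        if code == 0:
            idx = a
            delta = dw
        elif code == 1:
            idx = b
            delta = dw
        elif code == 2:
            idx = a
            delta = da
        elif code == 3:
            idx = b
            delta = da
        elif code == 4:
            idx = a
            delta = D[a, b] * db
        elif code == 5:
            idx = b
            delta = D[a, b] * db
        elif code == 6:
            idx = a
            delta = D[a, b] * da
        elif code == 7:
            idx = b
            delta = D[a, b] * da
        else:
            if parts[t] == 0:
                mu = mod1[a]
                mv = mod1[b]
                M = M1
            else:
                mu = mod2[a]
                mv = mod2[b]
                M = M2
            if mu < 0 or mv < 0:
                continue
            if code == 8 or code == 9:
                if mu != mv:
                    continue
                idx = mu
                delta = dw if code == 8 else da
            else:
                if mu == mv:
                    continue
                idx = _pair_index(mu, mv, M)
                delta = dw if code == 10 else da
        if delta == 0.0:
            continue
        old = cur[t, idx]
        new = old + delta
        tv = tgt[t, idx]
        sabs[t] += abs(new - tv) - abs(old - tv)
        cur[t, idx] = new


@njit(cache=True)
def _exchange(W, B, i, j, k, l, D, mod1, mod2, M1, M2,
              codes, parts, cur, tgt, sabs):
    """Exchange the contents (weight + bandwidth) of slots (i,j) and (k,l)."""
    w1 = W[i, j]
    w2 = W[k, l]
    b1 = B[i, j]
    b2 = B[k, l]
    a1 = 1.0 if w1 > 0.0 else 0.0
    a2 = 1.0 if w2 > 0.0 else 0.0
    W[i, j] = w2
    W[k, l] = w1
    B[i, j] = b2
    B[k, l] = b1
    _update_slot(i, j, w2 - w1, a2 - a1, b2 - b1, D, mod1, mod2, M1, M2,
                 codes, parts, cur, tgt, sabs)
    _update_slot(k, l, w1 - w2, a1 - a2, b1 - b2, D, mod1, mod2, M1, M2,
                 codes, parts, cur, tgt, sabs)


@njit(cache=True)
def _raw_exchange(W, B, i, j, k, l):
    w1 = W[i, j]
    W[i, j] = W[k, l]
    W[k, l] = w1
    b1 = B[i, j]
    B[i, j] = B[k, l]
    B[k, l] = b1


@njit(cache=True)
def _recompute(W, B, D, mod1, mod2, M1, M2, codes, parts, cur, tgt, sabs, lens):
    n = W.shape[0]
    for t in range(codes.shape[0]):
        code = codes[t]
        for idx in range(lens[t]):
            cur[t, idx] = 0.0
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                w = W[a, b]
                aa = 1.0 if w > 0.0 else 0.0
                if code == 0:
                    cur[t, a] += w
                elif code == 1:
                    cur[t, b] += w
                elif code == 2:
                    cur[t, a] += aa
                elif code == 3:
                    cur[t, b] += aa
                elif code == 4:
                    cur[t, a] += D[a, b] * B[a, b]
                elif code == 5:
                    cur[t, b] += D[a, b] * B[a, b]
                elif code == 6:
                    cur[t, a] += D[a, b] * aa
                elif code == 7:
                    cur[t, b] += D[a, b] * aa
                else:
                    if parts[t] == 0:
                        mu = mod1[a]
                        mv = mod1[b]
                        M = M1
                    else:
                        mu = mod2[a]
                        mv = mod2[b]
                        M = M2
                    if mu < 0 or mv < 0:
                        continue
                    if code == 8:
                        if mu == mv:
                            cur[t, mu] += w
                    elif code == 9:
                        if mu == mv:
                            cur[t, mu] += aa
                    elif code == 10:
                        if mu != mv:
                            cur[t, _pair_index(mu, mv, M)] += w
                    else:
                        if mu != mv:
                            cur[t, _pair_index(mu, mv, M)] += aa
        s = 0.0
        for idx in range(lens[t]):
            s += abs(cur[t, idx] - tgt[t, idx])
        sabs[t] = s


@njit(cache=True)
def _error(sabs, denom, q):
    k = sabs.shape[0]
    if k == 0:
        return 0.0
    acc = 0.0
    for t in range(k):
        e = sabs[t] / denom[t]
        acc += e ** q
    return (acc / k) ** (1.0 / q)


@njit(cache=True, inline="always")
def _draw_move(n, mirror):
    """Draw a candidate mirrored slot exchange.

    Returns (i, j, k, l, mode) where mode is 2 (apply both the drawn
    exchange and its mirror), 1 (the mirror coincides with the drawn
    exchange: apply once), or 0 (partial overlap between the drawn slots
    and their mirrors: discard the proposal).
    """
    i = np.random.randint(0, n)
    j = np.random.randint(0, n)
    while j == i:
        j = np.random.randint(0, n)
    while True:
        k = np.random.randint(0, n)
        l = np.random.randint(0, n)
        if k != l and not (k == i and l == j):
            break
    mi = mirror[i]
    mj = mirror[j]
    mk = mirror[k]
    ml = mirror[l]
    s3_is_s1 = mi == i and mj == j
    s3_is_s2 = mi == k and mj == l
    s4_is_s1 = mk == i and ml == j
    s4_is_s2 = mk == k and ml == l
    if (s3_is_s1 and s4_is_s2) or (s3_is_s2 and s4_is_s1):
        return i, j, k, l, 1
    if s3_is_s1 or s3_is_s2 or s4_is_s1 or s4_is_s2:
        return i, j, k, l, 0
    return i, j, k, l, 2


@njit(cache=True)
def run_anneal(W, B, D, mirror, mod1, mod2, M1, M2, codes, parts, tgt, denom,
               lens, q, T0, cool, stage_len, max_iters, tol, seed, n_shuffle):
    """Anneal W (and B) in place; returns
    (status, iters, E_final, best_E, n_stages, it_trace, T_trace, E_trace)."""
    np.random.seed(seed)
    n = W.shape[0]
    k = codes.shape[0]
    cur = np.zeros_like(tgt)
    sabs = np.zeros(k)

    # unconstrained randomization with preserved bilateral relationships
    it = 0
    done = 0
    while done < n_shuffle and it < max_iters:
        it += 1
        i, j, kk, ll, mode = _draw_move(n, mirror)
        if mode == 0:
            continue
        _raw_exchange(W, B, i, j, kk, ll)
        if mode == 2:
            _raw_exchange(W, B, mirror[i], mirror[j], mirror[kk], mirror[ll])
        done += 1

    _recompute(W, B, D, mod1, mod2, M1, M2, codes, parts, cur, tgt, sabs, lens)
    E = _error(sabs, denom, q)
    best_E = E

    max_stages = int(max_iters // stage_len) + 2
    it_trace = np.zeros(max_stages, dtype=np.int64)
    T_trace = np.zeros(max_stages)
    E_trace = np.zeros(max_stages)
    n_stages = 0
    T = T0

    if E <= tol:
        it_trace[0] = it
        T_trace[0] = T
        E_trace[0] = E
        return (STATUS_OK, it, E, best_E, 1, it_trace, T_trace, E_trace)

    while it < max_iters:
        for _ in range(stage_len):
            it += 1
            i, j, kk, ll, mode = _draw_move(n, mirror)
            if mode == 0:
                continue
            mi = mirror[i]
            mj = mirror[j]
            mk = mirror[kk]
            ml = mirror[ll]
            E_old = E
            _exchange(W, B, i, j, kk, ll, D, mod1, mod2, M1, M2,
                      codes, parts, cur, tgt, sabs)
            if mode == 2:
                _exchange(W, B, mi, mj, mk, ml, D, mod1, mod2, M1, M2,
                          codes, parts, cur, tgt, sabs)
            E_new = _error(sabs, denom, q)
            dE = E_new - E_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                E = E_new
                if E < best_E:
                    best_E = E
                if E <= tol:
                    # verify against a fresh full evaluation before stopping
                    _recompute(W, B, D, mod1, mod2, M1, M2, codes, parts,
                               cur, tgt, sabs, lens)
                    E = _error(sabs, denom, q)
                    if E <= tol:
                        if E < best_E:
                            best_E = E
                        it_trace[n_stages] = it
                        T_trace[n_stages] = T
                        E_trace[n_stages] = E
                        n_stages += 1
                        return (STATUS_OK, it, E, best_E, n_stages,
                                it_trace, T_trace, E_trace)
            else:
                # revert (the exchange is its own inverse)
                if mode == 2:
                    _exchange(W, B, mi, mj, mk, ml, D, mod1, mod2, M1, M2,
                              codes, parts, cur, tgt, sabs)
                _exchange(W, B, i, j, kk, ll, D, mod1, mod2, M1, M2,
                          codes, parts, cur, tgt, sabs)
        # stage boundary: resync state, log, cool
        _recompute(W, B, D, mod1, mod2, M1, M2, codes, parts, cur, tgt, sabs, lens)
        E = _error(sabs, denom, q)
        if E < best_E:
            best_E = E
        it_trace[n_stages] = it
        T_trace[n_stages] = T
        E_trace[n_stages] = E
        n_stages += 1
        if E <= tol:
            return (STATUS_OK, it, E, best_E, n_stages, it_trace, T_trace, E_trace)
        T *= cool

    return (STATUS_MAX_ITERS, it, E, best_E, n_stages, it_trace, T_trace, E_trace)
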