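"""Numba kernels: inside/outside partition recursions and stochastic traceback.

Array conventions (all 0-based):

``W[i, j]``
    Scaled Boltzmann sum over all structures of the half-open segment
    ``[i, j)`` viewed as loop content.  ``W[i, i] = 1``.
``Vx[a, b]``
    Scaled sum over structures of ``a..b`` (inclusive) in which (a, b) pair,
    as seen from the enclosing loop (helix-outermost context): the inner
    branch carries the stack factor, the non-stacked branch the
    isolated-pair factor.
``Vp[a, b]``
    Same but in the stacked-under-parent context, where the pair is never
    isolated (no isolated factor on the non-stacked branch).

Each position contributes a factor 1/s (``s`` = scale) so that the scaled
partition value ``W[0, L]`` stays within float64 range; ``Z = W[0, L] *
s**L``.  The ``Wd/Vxd/Vpd`` companions propagate the derivative of the
partition value with respect to a multiplier attached to every base pair
(forward-mode dual), giving the exact expected number of pairs as
``Wd[0, L] / W[0, L]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def inside_dp(can, bst, biso, s):
    L = can.shape[0]
    W = np.zeros((L + 1, L + 1))
    Wd = np.zeros((L + 1, L + 1))
    Vx = np.zeros((L, L))
    Vxd = np.zeros((L, L))
    Vp = np.zeros((L, L))
    Vpd = np.zeros((L, L))
    for i in range(L + 1):
        W[i, i] = 1.0
    sinv = 1.0 / s
    s2i = sinv * sinv
    for ln in range(1, L + 1):
        if ln >= 5:
            for a in range(L - ln + 1):
                b = a + ln - 1
                if not can[a, b]:
                    continue
                w_in = W[a + 1, b]      # interior segment [a+1, b)
                wd_in = Wd[a + 1, b]
                st = 0.0
                vp_in = 0.0
                vpd_in = 0.0
                wx = w_in
                wxd = wd_in
                if can[a + 1, b - 1]:
                    st = bst[a, b]
                    vp_in = Vp[a + 1, b - 1]
                    vpd_in = Vpd[a + 1, b - 1]
                    wx = w_in - Vx[a + 1, b - 1]
                    wxd = wd_in - Vxd[a + 1, b - 1]
                vx = (st * vp_in + biso * wx) * s2i
                vp = (st * vp_in + wx) * s2i
                Vx[a, b] = vx
                Vp[a, b] = vp
                Vxd[a, b] = vx + (st * vpd_in + biso * wxd) * s2i
                Vpd[a, b] = vp + (st * vpd_in + wxd) * s2i
        for i in range(L - ln + 1):
            j = i + ln
            acc = W[i, j - 1] * sinv
            accd = Wd[i, j - 1] * sinv
            for k in range(i, j - 4):
                if can[k, j - 1]:
                    acc += W[i, k] * Vx[k, j - 1]
                    accd += Wd[i, k] * Vx[k, j - 1] + W[i, k] * Vxd[k, j - 1]
            W[i, j] = acc
            Wd[i, j] = accd
    return W, Wd, Vx, Vxd, Vp, Vpd


@njit(cache=True)
def outside_dp(can, bst, biso, s, W, Vx, Vp):
    """Base-pair probability matrix via the outside recursion.

    ``OVe[a, b]`` is the scaled outside weight of pair (a, b) occurring
    helix-outermost in some loop (the exterior, or the interior of a
    directly enclosing pair); ``OVp[a, b]`` the outside weight of (a, b)
    stacked directly under (a-1, b+1).  ``T[p, j]`` accumulates, for each
    potential enclosing pair opening at p, the loop-context weight times
    the loop content to the right of a contained segment ending at j.
    """
    L = can.shape[0]
    OVe = np.zeros((L, L))
    OVp = np.zeros((L, L))
    T = np.zeros((L, L))
    P = np.zeros((L, L))
    s2i = 1.0 / (s * s)
    zhat = W[0, L]
    for ln in range(L, 4, -1):
        for a in range(L - ln + 1):
            b = a + ln - 1
            if not can[a, b]:
                continue
            enclosed = a > 0 and b < L - 1 and can[a - 1, b + 1]
            if enclosed:
                OVp[a, b] = bst[a - 1, b + 1] * (
                    OVe[a - 1, b + 1] + OVp[a - 1, b + 1]) * s2i
            acc = W[0, a] * W[b + 1, L]
            for p in range(a):
                if T[p, b] != 0.0:
                    acc += T[p, b] * W[p + 1, a]
            if enclosed:
                # (a-1, b+1) as direct parent with (a, b) spanning its whole
                # interior is the stack context, not a loop context
                acc -= (biso * OVe[a - 1, b + 1] + OVp[a - 1, b + 1]) * s2i
            OVe[a, b] = acc
            prob = (Vx[a, b] * acc + Vp[a, b] * OVp[a, b]) / zhat
            P[a, b] = prob
            P[b, a] = prob
        for a in range(L - ln + 1):
            b = a + ln - 1
            if not can[a, b]:
                continue
            lo = (biso * OVe[a, b] + OVp[a, b]) * s2i
            if lo != 0.0:
                for j in range(a + 1, b):
                    T[a, j] += lo * W[j + 1, b]
    return P


@njit(cache=True)
def sample_dp(can, bst, biso, s, W, Vx, Vp, count, seed):
    """Stochastic traceback: draw ``count`` structures, Boltzmann-weighted.

    Returns an int32 array (count, L) of 0-based partners (-1 unpaired).
    Task modes: 0 = free segment [i, j); 1 = pair (i, j) seen from a loop;
    2 = pair (i, j) stacked under its parent; 3 = segment [i, j) that must
    not pair (i, j-1) together (interior of a non-stacked pair).
    """
    np.random.seed(seed)
    L = can.shape[0]
    out = np.full((count, L), -1, dtype=np.int32)
    sinv = 1.0 / s
    s2i = sinv * sinv
    stack = np.empty((L + 8, 3), dtype=np.int64)
    for c in range(count):
        top = 0
        stack[top, 0] = 0
        stack[top, 1] = 0
        stack[top, 2] = L
        top = 1
        while top > 0:
            top -= 1
            mode = stack[top, 0]
            i = stack[top, 1]
            j = stack[top, 2]
            if mode == 0 or mode == 3:
                excl = mode == 3
                while j - i >= 1:
                    tot = W[i, j]
                    if excl and can[i, j - 1]:
                        tot -= Vx[i, j - 1]
                    r = np.random.random() * tot
                    t = W[i, j - 1] * sinv
                    if r < t:
                        j -= 1
                        excl = False
                        continue
                    r -= t
                    chosen = -1
                    lastk = -1
                    for k in range(i, j - 4):
                        if can[k, j - 1] and not (excl and k == i):
                            t = W[i, k] * Vx[k, j - 1]
                            if t > 0.0:
                                lastk = k
                                if r < t:
                                    chosen = k
                                    break
                                r -= t
                    if chosen < 0:
                        # roundoff residue: fall back to the last positive
                        # option, or to "unpaired" if there was none
                        chosen = lastk
                    if chosen < 0:
                        j -= 1
                        excl = False
                        continue
                    stack[top, 0] = 1
                    stack[top, 1] = chosen
                    stack[top, 2] = j - 1
                    top += 1
                    j = chosen
                    excl = False
            else:
                a = i
                b = j
                out[c, a] = b
                out[c, b] = a
                inner = can[a + 1, b - 1]
                tot = Vx[a, b] if mode == 1 else Vp[a, b]
                r = np.random.random() * tot
                t = bst[a, b] * Vp[a + 1, b - 1] * s2i if inner else 0.0
                if r < t:
                    stack[top, 0] = 2
                    stack[top, 1] = a + 1
                    stack[top, 2] = b - 1
                else:
                    stack[top, 0] = 3 if inner else 0
                    stack[top, 1] = a + 1
                    stack[top, 2] = b
                top += 1
    return out


@njit(cache=True)
def exterior_counts(ptab):
    """Per-structure exterior-loop statistics from partner tables.

    For each row: n = unpaired positions outside all pairs, m = helices
    whose closing pair is not enclosed by any other pair.
    """
    count, L = ptab.shape
    n_arr = np.empty(count, dtype=np.int64)
    m_arr = np.empty(count, dtype=np.int64)
    for c in range(count):
        n = 0
        m = 0
        i = 0
        while i < L:
            p = ptab[c, i]
            if p > i:
                m += 1
                i = p + 1
            else:
                n += 1
                i += 1
        n_arr[c] = n
        m_arr[c] = m
    return n_arr, m_arr
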