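"""Low-level chain recursions over the joint (genotype, clone) state space.

The joint transition kernel factorizes as a Kronecker product of the two
per-chain kernels, and each per-chain kernel is a diagonal (stay) plus a
uniform off-diagonal spill, so one frame update costs O(G*Z) instead of
O((G*Z)^2).  All recursions use per-frame scaling.  Chromosomes restart the
chains from the prior, which makes them independent blocks.

Kernels are JIT-compiled with numba when available and fall back to the
identical pure-Python implementations otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _mix_rows_forward(a, rho, out):
    """Forward transition along the last axis: out[g, j] = sum_i Q(i->j) a[g, i]."""
    G, K = a.shape
    if K == 1:
        for g in range(G):
            out[g, 0] = a[g, 0]
        return
    for g in range(G):
        s = 0.0
        for i in range(K):
            s += a[g, i] * (1.0 - rho[i])
        for j in range(K):
            out[g, j] = rho[j] * a[g, j] + (s - a[g, j] * (1.0 - rho[j])) / (K - 1)


@njit(cache=True)
def _mix_cols_forward(a, rho, out):
    """Forward transition along the first axis."""
    K, Z = a.shape
    if K == 1:
        for z in range(Z):
            out[0, z] = a[0, z]
        return
    for z in range(Z):
        s = 0.0
        for i in range(K):
            s += a[i, z] * (1.0 - rho[i])
        for j in range(K):
            out[j, z] = rho[j] * a[j, z] + (s - a[j, z] * (1.0 - rho[j])) / (K - 1)


@njit(cache=True)
def _mix_rows_backward(b, rho, out):
    """Backward mix along the last axis: out[g, j] = sum_i Q(j->i) b[g, i]."""
    G, K = b.shape
    if K == 1:
        for g in range(G):
            out[g, 0] = b[g, 0]
        return
    for g in range(G):
        s = 0.0
        for i in range(K):
            s += b[g, i]
        for j in range(K):
            out[g, j] = rho[j] * b[g, j] + (1.0 - rho[j]) / (K - 1) * (s - b[g, j])


@njit(cache=True)
def _mix_cols_backward(b, rho, out):
    K, Z = b.shape
    if K == 1:
        for z in range(Z):
            out[0, z] = b[0, z]
        return
    for z in range(Z):
        s = 0.0
        for i in range(K):
            s += b[i, z]
        for j in range(K):
            out[j, z] = rho[j] * b[j, z] + (1.0 - rho[j]) / (K - 1) * (s - b[j, z])


@njit(cache=True)
def forward_backward_kernel(logE, rhoG, rhoZ, start, piG, piZ):
    """Scaled forward-backward over the factorized joint chain.

    Returns (alpha, beta, scale, emax, loglik) where alpha[t] is the scaled
    forward message (sums to 1), beta[t] the matching scaled backward message
    (so alpha*beta is the per-frame posterior), scale[t] the per-frame
    normalizer of the forward recursion and emax[t] the per-frame emission
    log-max subtracted before exponentiation.
    """
    T, G, Z = logE.shape
    alpha = np.empty((T, G, Z))
    beta = np.empty((T, G, Z))
    scale = np.empty(T)
    emax = np.empty(T)
    tmp = np.empty((G, Z))
    pred = np.empty((G, Z))
    loglik = 0.0
    for t in range(T):
        m = -1.0e300
        for g in range(G):
            for z in range(Z):
                if logE[t, g, z] > m:
                    m = logE[t, g, z]
        emax[t] = m
        if start[t]:
            for g in range(G):
                for z in range(Z):
                    pred[g, z] = piG[g] * piZ[z]
        else:
            _mix_rows_forward(alpha[t - 1], rhoZ[t], tmp)
            _mix_cols_forward(tmp, rhoG[t], pred)
        c = 0.0
        for g in range(G):
            for z in range(Z):
                w = pred[g, z] * np.exp(logE[t, g, z] - m)
                alpha[t, g, z] = w
                c += w
        for g in range(G):
            for z in range(Z):
                alpha[t, g, z] /= c
        scale[t] = c
        loglik += np.log(c) + m
    B = np.empty((G, Z))
    for g in range(G):
        for z in range(Z):
            beta[T - 1, g, z] = 1.0
    for t in range(T - 2, -1, -1):
        if start[t + 1]:
            for g in range(G):
                for z in range(Z):
                    beta[t, g, z] = 1.0
            continue
        for g in range(G):
            for z in range(Z):
                B[g, z] = (np.exp(logE[t + 1, g, z] - emax[t + 1])
                           * beta[t + 1, g, z] / scale[t + 1])
        _mix_rows_backward(B, rhoZ[t + 1], tmp)
        _mix_cols_backward(tmp, rhoG[t + 1], beta[t])
    return alpha, beta, scale, emax, loglik


@njit(cache=True)
def transition_stats_kernel(logE, rhoG, rhoZ, start, alpha, beta, scale, emax):
    """Expected same-state transition mass per frame and per chain state.

    stayG[t, j] = P(G_{t-1}=j, G_t=j | data) summed over the clone chain, and
    symmetrically for stayZ.  Frames that restart a chromosome are zero.
    """
    T, G, Z = logE.shape
    stayG = np.zeros((T, G))
    stayZ = np.zeros((T, Z))
    B = np.empty((G, Z))
    W = np.empty((G, Z))
    V = np.empty((G, Z))
    for t in range(1, T):
        if start[t]:
            continue
        for g in range(G):
            for z in range(Z):
                B[g, z] = (np.exp(logE[t, g, z] - emax[t])
                           * beta[t, g, z] / scale[t])
        _mix_rows_backward(B, rhoZ[t], W)
        _mix_cols_backward(B, rhoG[t], V)
        for j in range(G):
            s = 0.0
            for z in range(Z):
                s += alpha[t - 1, j, z] * W[j, z]
            stayG[t, j] = rhoG[t, j] * s
        for z in range(Z):
            s = 0.0
            for g in range(G):
                s += alpha[t - 1, g, z] * V[g, z]
            stayZ[t, z] = rhoZ[t, z] * s
    return stayG, stayZ


@njit(cache=True)
def viterbi_kernel(logE, lstayG, lmoveG, lstayZ, lmoveZ, start, lpiG, lpiZ):
    """Most probable joint path; ties resolve to the lowest (g, z) index.

    lstay*/lmove* are per-frame log stay probabilities and log per-target
    move probabilities (already divided by K-1).  Returns the genotype path,
    clone path and the path log score (summed across chromosomes).
    """
    T, G, Z = logE.shape
    delta = np.empty((T, G, Z))
    ptrG = np.zeros((T, G, Z), np.int32)
    ptrZ = np.zeros((T, G, Z), np.int32)
    tmpv = np.empty((G, Z))
    tmpa = np.zeros((G, Z), np.int32)
    for t in range(T):
        if start[t]:
            carry = 0.0
            if t > 0:
                best = -1.0e300
                for g in range(G):
                    for z in range(Z):
                        if delta[t - 1, g, z] > best:
                            best = delta[t - 1, g, z]
                carry = best
            for g in range(G):
                for z in range(Z):
                    delta[t, g, z] = carry + lpiG[g] + lpiZ[z] + logE[t, g, z]
        else:
            for g in range(G):
                for z2 in range(Z):
                    best = -1.0e300
                    barg = 0
                    for z in range(Z):
                        if z == z2:
                            v = delta[t - 1, g, z] + lstayZ[t, z]
                        else:
                            v = delta[t - 1, g, z] + lmoveZ[t, z]
                        if v > best:
                            best = v
                            barg = z
                    tmpv[g, z2] = best
                    tmpa[g, z2] = barg
            for g2 in range(G):
                for z2 in range(Z):
                    best = -1.0e300
                    barg = 0
                    for g in range(G):
                        if g == g2:
                            v = tmpv[g, z2] + lstayG[t, g]
                        else:
                            v = tmpv[g, z2] + lmoveG[t, g]
                        if v > best:
                            best = v
                            barg = g
                    delta[t, g2, z2] = best + logE[t, g2, z2]
                    ptrG[t, g2, z2] = barg
                    ptrZ[t, g2, z2] = tmpa[barg, z2]
    gpath = np.empty(T, np.int64)
    zpath = np.empty(T, np.int64)
    best = -1.0e300
    bg, bz = 0, 0
    for g in range(G):
        for z in range(Z):
            if delta[T - 1, g, z] > best:
                best = delta[T - 1, g, z]
                bg, bz = g, z
    loglik = best
    gpath[T - 1] = bg
    zpath[T - 1] = bz
    for t in range(T - 2, -1, -1):
        if start[t + 1]:
            bb = -1.0e300
            for g in range(G):
                for z in range(Z):
                    if delta[t, g, z] > bb:
                        bb = delta[t, g, z]
                        bg, bz = g, z
        else:
            g2, z2 = bg, bz
            bg = ptrG[t + 1, g2, z2]
            bz = ptrZ[t + 1, g2, z2]
        gpath[t] = bg
        zpath[t] = bz
    return gpath, zpath, loglik
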