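"""Compiled inner loop of the filter (numba).

Numerically equivalent to the pure-numpy path in ``kalman.run_filter``
(verified in the test suite); exists because the per-step numpy call
overhead dominates for small networks.  Everything is passed as plain
arrays; the module is import-guarded so the package works without numba.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:                                    # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=True)
def _chol_lower(P, L):
    """In-place lower Cholesky; returns 0 on success, 1 if not PD."""
    n = P.shape[0]
    for i in range(n):
        for j in range(n):
            L[i, j] = 0.0
    for i in range(n):
        for j in range(i + 1):
            s = P[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return 1
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return 0


@njit(cache=True)
def _filter_loop(ys, x0, P0, Q, R, H, lo, hi, v_idx, z_idx, a_idx, tau,
                 internal, src, gamma, v0, slope, delta, u, scale, wm, wc,
                 infl_rel, infl_floor, decay, min_rel, analytic,
                 jit_start, jit_stop):
    # min_rel is per-connection: the decayed inflation rate never falls
    # below it for that connection's gain entry
    n_steps, n_ch = ys.shape
    n = x0.shape[0]
    nc = v_idx.shape[0]
    npop = gamma.shape[0]
    npts = 2 * n + 1
    sq2 = math.sqrt(2.0)

    means = np.empty((n_steps, n))
    stds = np.empty((n_steps, n))
    innovs = np.empty((n_steps, n_ch))

    mean = x0.copy()
    P = P0.copy()
    L = np.empty((n, n))
    X = np.empty((n, npts))
    eye = np.eye(n)

    for t in range(n_steps):
        # --- sigma points with escalating jitter --------------------------
        tr = 0.0
        for i in range(n):
            tr += P[i, i]
        sc_tr = max(tr / n, 1.0)
        ok = _chol_lower(P, L)
        if ok != 0:
            jit = jit_start
            while jit <= jit_stop:
                Pj = P + jit * sc_tr * eye
                ok = _chol_lower(Pj, L)
                if ok == 0:
                    break
                jit *= 100.0
            if ok != 0:
                return means, stds, innovs, t, 1
        for i in range(n):
            X[i, 0] = mean[i]
            for j in range(n):
                X[i, 1 + j] = mean[i] + scale * L[i, j]
                X[i, 1 + n + j] = mean[i] - scale * L[i, j]
        for k in range(nc):               # constrain gain coordinates:
            # symmetric truncation of each +/- pair about the mean keeps the
            # sample set unbiased; one-sided clamp only if the mean sits on
            # a bound
            r = a_idx[k]
            m_r = X[r, 0]
            room = min(hi[r] - m_r, m_r - lo[r])
            for j in range(n):
                d = X[r, 1 + j] - m_r
                a = abs(d)
                if room > 0.0:
                    if a > room:
                        f = room / a
                        X[r, 1 + j] = m_r + d * f
                        X[r, 1 + n + j] = m_r - d * f
                else:
                    if X[r, 1 + j] < lo[r]:
                        X[r, 1 + j] = lo[r]
                    elif X[r, 1 + j] > hi[r]:
                        X[r, 1 + j] = hi[r]
                    if X[r, 1 + n + j] < lo[r]:
                        X[r, 1 + n + j] = lo[r]
                    elif X[r, 1 + n + j] > hi[r]:
                        X[r, 1 + n + j] = hi[r]

        # --- propagate sigma points ---------------------------------------
        pot = gamma @ X                   # (npop, npts)
        rates = np.empty((npop, npts))
        for i in range(npop):
            for j in range(npts):
                rates[i, j] = 0.5 * (math.erf(
                    (pot[i, j] - v0) / (sq2 * slope)) + 1.0)
        Xp = X.copy()
        for k in range(nc):
            vi, zi, ai = v_idx[k], z_idx[k], a_idx[k]
            tk = tau[k]
            for j in range(npts):
                drive = rates[src[k], j] if internal[k] else u
                Xp[vi, j] = X[vi, j] + delta * X[zi, j]
                Xp[zi, j] = X[zi, j] + delta * (
                    (X[ai, j] * drive - 2.0 * X[zi, j]) / tk
                    - X[vi, j] / (tk * tk))

        # --- prior mean ---------------------------------------------------
        m_prior = np.empty(n)
        if analytic:
            G = gamma @ P                 # (npop, n)
            mu = gamma @ mean
            erate = np.empty(npop)
            for i in range(npop):
                var = 0.0
                for j in range(n):
                    var += G[i, j] * gamma[i, j]
                if var < 0.0:
                    var = 0.0
                erate[i] = 0.5 * (math.erf(
                    (mu[i] - v0) / math.sqrt(2.0 * (slope * slope + var)))
                    + 1.0)
            for i in range(n):
                m_prior[i] = mean[i]
            for k in range(nc):
                vi, zi, ai = v_idx[k], z_idx[k], a_idx[k]
                tk = tau[k]
                drive = erate[src[k]] if internal[k] else u
                m_prior[vi] = mean[vi] + delta * mean[zi]
                m_prior[zi] = mean[zi] + delta * (
                    (mean[ai] * drive - 2.0 * mean[zi]) / tk
                    - mean[vi] / (tk * tk))
        else:
            for i in range(n):
                s = 0.0
                for j in range(npts):
                    s += wm[j] * Xp[i, j]
                m_prior[i] = s
        for k in range(nc):
            r = a_idx[k]
            if m_prior[r] < lo[r]:
                m_prior[r] = lo[r]
            elif m_prior[r] > hi[r]:
                m_prior[r] = hi[r]

        # --- prior covariance ---------------------------------------------
        Y = np.empty((n, npts))
        Yw = np.empty((n, npts))
        for i in range(n):
            for j in range(npts):
                d = Xp[i, j] - m_prior[i]
                Y[i, j] = d
                Yw[i, j] = d * wc[j]
        Pp = Yw @ Y.T
        for i in range(n):
            for j in range(i + 1):
                s = 0.5 * (Pp[i, j] + Pp[j, i]) + Q[i, j]
                Pp[i, j] = s
                Pp[j, i] = s
        if infl_rel > 0.0:
            base_rel = infl_rel if decay <= 0.0 else \
                infl_rel * math.exp(-t * delta / decay)
            for k in range(nc):
                rel = max(base_rel, min_rel[k])
                r = a_idx[k]
                m = abs(m_prior[r])
                if m < infl_floor[k]:
                    m = infl_floor[k]
                Pp[r, r] += (rel * m) * (rel * m)

        # --- measurement update -------------------------------------------
        PHt = Pp @ H.T                    # (n, n_ch)
        S = H @ PHt + R
        Kt = np.linalg.solve(S, PHt.T)    # (n_ch, n)
        innov = np.empty(n_ch)
        for c in range(n_ch):
            s = ys[t, c]
            for i in range(n):
                s -= H[c, i] * m_prior[i]
            innov[c] = s
        for i in range(n):
            s = m_prior[i]
            for c in range(n_ch):
                s += Kt[c, i] * innov[c]
            mean[i] = s
        for k in range(nc):
            r = a_idx[k]
            if mean[r] < lo[r]:
                mean[r] = lo[r]
            elif mean[r] > hi[r]:
                mean[r] = hi[r]
        IKH = eye - Kt.T @ H
        P = IKH @ Pp @ IKH.T + Kt.T @ R @ Kt
        for i in range(n):
            for j in range(i):
                s = 0.5 * (P[i, j] + P[j, i])
                P[i, j] = s
                P[j, i] = s

        bad = False
        for i in range(n):
            if not math.isfinite(mean[i]):
                bad = True
        if bad:
            return means, stds, innovs, t, 2
        for i in range(n):
            means[t, i] = mean[i]
            d = P[i, i]
            stds[t, i] = math.sqrt(d) if d > 0.0 else 0.0
        for c in range(n_ch):
            innovs[t, c] = innov[c]

    return means, stds, innovs, -1, 0
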