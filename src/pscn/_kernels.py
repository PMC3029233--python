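"""Numba kernels for the Gaussian-mixture changepoint filters and smoother.

All linear algebra is on 2x2 symmetric matrices, packed as (m00, m01, m11)
triples, with hand-written inverses; mixture weights are carried in linear
scale after per-step normalization while per-candidate scores are handled
in log space.  The kernels are deliberately free of Python objects so the
per-SNP cost is a few hundred flops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


@njit(cache=True, fastmath=True, inline="always")
def _inv2(p00, p01, p11):
    det = p00 * p11 - p01 * p01
    return p11 / det, -p01 / det, p00 / det, det


@njit(cache=True, fastmath=True, inline="always")
def _logpdf_cov(d0, d1, s00, s01, s11):
    """log N(d; 0, S) with S packed."""
    det = s00 * s11 - s01 * s01
    quad = (s11 * d0 * d0 - 2.0 * s01 * d0 * d1 + s00 * d1 * d1) / det
    return -LOG2PI - 0.5 * np.log(det) - 0.5 * quad


@njit(cache=True, fastmath=True, inline="always")
def _logpdf_prec(d0, d1, q00, q01, q11, logdet_cov):
    """log N(d; 0, Q^{-1}) given the precision Q and log|Q^{-1}|."""
    quad = q00 * d0 * d0 + 2.0 * q01 * d0 * d1 + q11 * d1 * d1
    return -LOG2PI - 0.5 * logdet_cov - 0.5 * quad


@njit(cache=True, fastmath=True)
def forward_kernel(u, g, Apack, Sig, Siginv, logdetSig, B, ASi,
                   mu0, z, V, Vinv, p, r, s, M, K):
    """One-sided filter: P(theta_t | u_{1..t}) as point mass + Gaussians.

    Returns per-SNP normalized baseline weight, component weights,
    change-time indices, packed natural parameters (precision, linear
    term) and active component counts.
    """
    n = u.shape[0]
    fb = np.zeros(n)
    fn = np.zeros(n, np.int64)
    fw = np.zeros((n, M))
    fj = np.zeros((n, M), np.int64)
    fP = np.zeros((n, M, 3))
    fh = np.zeros((n, M, 2))
    err = np.full(1, -1, np.int64)

    pi_n = r / (r + p)
    pi_v = p / (r + p)

    # natural parameters of the variant prior N(z, V)
    hz0 = Vinv[0] * z[0] + Vinv[1] * z[1]
    hz1 = Vinv[1] * z[0] + Vinv[2] * z[1]

    # scratch for candidates: index 0 unused; comps kept in ascending j
    cw = np.zeros(M + 1)
    cj = np.zeros(M + 1, np.int64)
    cP = np.zeros((M + 1, 3))
    ch = np.zeros((M + 1, 2))
    logs = np.zeros(M + 2)

    m_prev = 0
    b_prev = 0.0

    for t in range(n):
        gt = g[t]
        a00, a01, a10, a11 = Apack[gt, 0], Apack[gt, 1], Apack[gt, 2], Apack[gt, 3]
        u0, u1 = u[t, 0], u[t, 1]

        # transition-mixed prior masses
        if t == 0:
            prior_base = pi_n
            prior_new = pi_v
        else:
            sv = 0.0
            for i in range(m_prev):
                sv += fw[t - 1, i]
            prior_base = b_prev * (1.0 - p) + sv * r
            prior_new = b_prev * p + sv * s

        # baseline candidate: theta = mu0
        mb0 = a00 * mu0[0] + a01 * mu0[1]
        mb1 = a10 * mu0[0] + a11 * mu0[1]
        lbase = (-LOG2PI - 0.5 * logdetSig[gt]
                 - 0.5 * (Siginv[gt, 0] * (u0 - mb0) ** 2
                          + 2.0 * Siginv[gt, 1] * (u0 - mb0) * (u1 - mb1)
                          + Siginv[gt, 2] * (u1 - mb1) ** 2))
        log_base = np.log(prior_base) + lbase if prior_base > 0 else -np.inf

        nc = 0
        # continuing components
        if t > 0:
            stay = 1.0 - r - s
            for i in range(m_prev):
                wprev = fw[t - 1, i]
                if wprev * stay <= 0.0:
                    continue
                p00, p01, p11 = fP[t - 1, i, 0], fP[t - 1, i, 1], fP[t - 1, i, 2]
                c00, c01, c11, _ = _inv2(p00, p01, p11)
                h0, h1 = fh[t - 1, i, 0], fh[t - 1, i, 1]
                m0 = c00 * h0 + c01 * h1
                m1 = c01 * h0 + c11 * h1
                # predictive covariance A C A' + Sigma
                ac00 = a00 * c00 + a01 * c01
                ac01 = a00 * c01 + a01 * c11
                ac10 = a10 * c00 + a11 * c01
                ac11 = a10 * c01 + a11 * c11
                s00 = ac00 * a00 + ac01 * a01 + Sig[gt, 0]
                s01 = ac00 * a10 + ac01 * a11 + Sig[gt, 1]
                s11 = ac10 * a10 + ac11 * a11 + Sig[gt, 2]
                d0 = u0 - (a00 * m0 + a01 * m1)
                d1 = u1 - (a10 * m0 + a11 * m1)
                logs[nc] = np.log(wprev * stay) + _logpdf_cov(d0, d1, s00, s01, s11)
                cj[nc] = fj[t - 1, i]
                cP[nc, 0] = p00 + B[gt, 0]
                cP[nc, 1] = p01 + B[gt, 1]
                cP[nc, 2] = p11 + B[gt, 2]
                ch[nc, 0] = h0 + ASi[gt, 0] * u0 + ASi[gt, 1] * u1
                ch[nc, 1] = h1 + ASi[gt, 2] * u0 + ASi[gt, 3] * u1
                nc += 1

        # fresh changepoint at t: prior N(z, V)
        if prior_new > 0.0:
            av00 = a00 * V[0] + a01 * V[1]
            av01 = a00 * V[1] + a01 * V[2]
            av10 = a10 * V[0] + a11 * V[1]
            av11 = a10 * V[1] + a11 * V[2]
            s00 = av00 * a00 + av01 * a01 + Sig[gt, 0]
            s01 = av00 * a10 + av01 * a11 + Sig[gt, 1]
            s11 = av10 * a10 + av11 * a11 + Sig[gt, 2]
            d0 = u0 - (a00 * z[0] + a01 * z[1])
            d1 = u1 - (a10 * z[0] + a11 * z[1])
            logs[nc] = np.log(prior_new) + _logpdf_cov(d0, d1, s00, s01, s11)
            cj[nc] = t
            cP[nc, 0] = Vinv[0] + B[gt, 0]
            cP[nc, 1] = Vinv[1] + B[gt, 1]
            cP[nc, 2] = Vinv[2] + B[gt, 2]
            ch[nc, 0] = hz0 + ASi[gt, 0] * u0 + ASi[gt, 1] * u1
            ch[nc, 1] = hz1 + ASi[gt, 2] * u0 + ASi[gt, 3] * u1
            nc += 1

        # normalize (log-sum-exp over baseline + components)
        mx = log_base
        for i in range(nc):
            if logs[i] > mx:
                mx = logs[i]
        if not np.isfinite(mx):
            # all candidates impossible: numerical failure at this SNP
            err[0] = t
            return (fb, fn, fw, fj, fP, fh, err)
        tot = np.exp(log_base - mx)
        for i in range(nc):
            tot += np.exp(logs[i] - mx)
        b_new = np.exp(log_base - mx) / tot
        for i in range(nc):
            cw[i] = np.exp(logs[i] - mx) / tot

        # BCMIX pruning: drop the lowest-weight component outside the K
        # most recent change-times until at most M remain
        while nc > M:
            lim = nc - K
            worst = -1
            wmin = 2.0
            for i in range(lim):
                if cw[i] < wmin:
                    wmin = cw[i]
                    worst = i
            for i in range(worst, nc - 1):
                cw[i] = cw[i + 1]
                cj[i] = cj[i + 1]
                cP[i, 0] = cP[i + 1, 0]
                cP[i, 1] = cP[i + 1, 1]
                cP[i, 2] = cP[i + 1, 2]
                ch[i, 0] = ch[i + 1, 0]
                ch[i, 1] = ch[i + 1, 1]
            nc -= 1
            tot2 = b_new
            for i in range(nc):
                tot2 += cw[i]
            b_new /= tot2
            for i in range(nc):
                cw[i] /= tot2

        fb[t] = b_new
        fn[t] = nc
        for i in range(nc):
            fw[t, i] = cw[i]
            fj[t, i] = cj[i]
            fP[t, i, 0] = cP[i, 0]
            fP[t, i, 1] = cP[i, 1]
            fP[t, i, 2] = cP[i, 2]
            fh[t, i, 0] = ch[i, 0]
            fh[t, i, 1] = ch[i, 1]
        m_prev = nc
        b_prev = b_new

    return (fb, fn, fw, fj, fP, fh, err)


@njit(cache=True, fastmath=True, inline="always")
def _log_norm_at(p00, p01, p11, h0, h1, t0, t1):
    """log N(t; m, P^{-1}) where m = P^{-1} h, evaluated at t."""
    c00, c01, c11, det = _inv2(p00, p01, p11)
    m0 = c00 * h0 + c01 * h1
    m1 = c01 * h0 + c11 * h1
    d0, d1 = t0 - m0, t1 - m1
    quad = p00 * d0 * d0 + 2.0 * p01 * d0 * d1 + p11 * d1 * d1
    return -LOG2PI + 0.5 * np.log(det) - 0.5 * quad


@njit(cache=True, fastmath=True)
def smooth_kernel(fb, fn, fw, fP, fh, bb, bn, bw, bP, bh,
                  mu0, z, Vinv, p, r, s):
    """Bayes combination of forward state t and backward state t+1.

    Inputs are forward-filter arrays and backward-filter arrays already
    aligned to the original SNP order (backward index t represents the
    posterior given u_{t..n}).  Returns the posterior mean track, the
    posterior baseline mass, and the packed posterior covariance.
    """
    n = fb.shape[0]
    theta = np.zeros((n, 2))
    base_mass = np.zeros(n)
    cov = np.zeros((n, 3))

    pi_n = r / (r + p)
    pi_v = p / (r + p)
    hz0 = Vinv[0] * z[0] + Vinv[1] * z[1]
    hz1 = Vinv[1] * z[0] + Vinv[2] * z[1]
    log_stay = np.log((1.0 - r - s) / pi_v)

    maxc = fw.shape[1]
    # per-t candidate store: baseline + forward-only + pairs
    cap = 1 + maxc + maxc * maxc
    clog = np.zeros(cap)
    cm = np.zeros((cap, 2))
    cC = np.zeros((cap, 3))

    for t in range(n):
        nf = fn[t]
        if t == n - 1:
            nb = 0
            sb = 0.0
            bbt = 0.0
        else:
            nb = bn[t + 1]
            sb = 0.0
            for j in range(nb):
                sb += bw[t + 1, j]
            bbt = bb[t + 1]

        k = 0
        # baseline at t
        if t == n - 1:
            w = fb[t]
        else:
            w = fb[t] * ((1.0 - p) * bbt / pi_n + p * sb / pi_v)
        clog[k] = np.log(w) if w > 0 else -np.inf
        cm[k, 0], cm[k, 1] = mu0[0], mu0[1]
        cC[k, 0] = cC[k, 1] = cC[k, 2] = 0.0
        k += 1

        # forward components, change right after t (or t = n-1)
        if t == n - 1:
            fac = 1.0
        else:
            fac = r * bbt / pi_n + s * sb / pi_v
        for i in range(nf):
            w = fw[t, i] * fac
            p00, p01, p11 = fP[t, i, 0], fP[t, i, 1], fP[t, i, 2]
            c00, c01, c11, _ = _inv2(p00, p01, p11)
            h0, h1 = fh[t, i, 0], fh[t, i, 1]
            clog[k] = np.log(w) if w > 0 else -np.inf
            cm[k, 0] = c00 * h0 + c01 * h1
            cm[k, 1] = c01 * h0 + c11 * h1
            cC[k, 0], cC[k, 1], cC[k, 2] = c00, c01, c11
            k += 1

        # fused pairs: variant run spanning t and t+1
        if t < n - 1:
            for i in range(nf):
                # components below weight 1e-13 cannot influence the
                # posterior mean at any useful precision
                if fw[t, i] < 1e-13:
                    continue
                lwi = np.log(fw[t, i])
                pf0, pf1, pf2 = fP[t, i, 0], fP[t, i, 1], fP[t, i, 2]
                hf0, hf1 = fh[t, i, 0], fh[t, i, 1]
                for j in range(nb):
                    if bw[t + 1, j] < 1e-13:
                        continue
                    lwj = np.log(bw[t + 1, j])
                    q00 = pf0 + bP[t + 1, j, 0] - Vinv[0]
                    q01 = pf1 + bP[t + 1, j, 1] - Vinv[1]
                    q11 = pf2 + bP[t + 1, j, 2] - Vinv[2]
                    det = q00 * q11 - q01 * q01
                    if det <= 0.0 or q00 <= 0.0:
                        continue
                    e0 = hf0 + bh[t + 1, j, 0] - hz0
                    e1 = hf1 + bh[t + 1, j, 1] - hz1
                    c00, c01, c11, _ = _inv2(q00, q01, q11)
                    m0 = c00 * e0 + c01 * e1
                    m1 = c01 * e0 + c11 * e1
                    # scalar of the Gaussian product/ratio, evaluated at m
                    logk = (_log_norm_at(pf0, pf1, pf2, hf0, hf1, m0, m1)
                            + _log_norm_at(bP[t + 1, j, 0], bP[t + 1, j, 1],
                                           bP[t + 1, j, 2], bh[t + 1, j, 0],
                                           bh[t + 1, j, 1], m0, m1)
                            - _log_norm_at(Vinv[0], Vinv[1], Vinv[2],
                                           hz0, hz1, m0, m1)
                            - (-LOG2PI + 0.5 * np.log(det)))
                    clog[k] = log_stay + lwi + lwj + logk
                    cm[k, 0], cm[k, 1] = m0, m1
                    cC[k, 0], cC[k, 1], cC[k, 2] = c00, c01, c11
                    k += 1

        # normalize and accumulate moments
        mx = -np.inf
        for i in range(k):
            if clog[i] > mx:
                mx = clog[i]
        tot = 0.0
        for i in range(k):
            tot += np.exp(clog[i] - mx)
        th0 = 0.0
        th1 = 0.0
        m200 = 0.0
        m201 = 0.0
        m211 = 0.0
        for i in range(k):
            wi = np.exp(clog[i] - mx) / tot
            th0 += wi * cm[i, 0]
            th1 += wi * cm[i, 1]
            m200 += wi * (cC[i, 0] + cm[i, 0] * cm[i, 0])
            m201 += wi * (cC[i, 1] + cm[i, 0] * cm[i, 1])
            m211 += wi * (cC[i, 2] + cm[i, 1] * cm[i, 1])
        theta[t, 0] = th0
        theta[t, 1] = th1
        base_mass[t] = np.exp(clog[0] - mx) / tot
        cov[t, 0] = m200 - th0 * th0
        cov[t, 1] = m201 - th0 * th1
        cov[t, 2] = m211 - th1 * th1

    return theta, base_mass, cov
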