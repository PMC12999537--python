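"""Fused numba kernels for the sampler's hot path.

Each kernel performs one pass over the person-by-item cells, fusing the
propensity construction, softmax normalization and gathering steps that
would otherwise take several large temporary arrays per Metropolis block.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def resp_loglik(tt, ft, g, y, use_tt, use_ft, out):
    """log p(y | class) per cell.

    ``g`` is the (I, K+1) intercept row of one class; ``tt``/``ft`` the
    (N, I, K+1) trait and faking propensity terms (ignored when the flag is
    off); ``out`` is (N, I).
    """
    N, I = y.shape
    K1 = g.shape[1]
    for n in range(N):
        for i in range(I):
            m = -1.0e300
            for k in range(K1):
                v = g[i, k]
                if use_tt:
                    v += tt[n, i, k]
                if use_ft:
                    v += ft[n, i, k]
                if v > m:
                    m = v
            ssum = 0.0
            for k in range(K1):
                v = g[i, k]
                if use_tt:
                    v += tt[n, i, k]
                if use_ft:
                    v += ft[n, i, k]
                ssum += np.exp(v - m)
            k = y[n, i]
            v = g[i, k]
            if use_tt:
                v += tt[n, i, k]
            if use_ft:
                v += ft[n, i, k]
            out[n, i] = v - m - np.log(ssum)


@njit(cache=True, fastmath=True)
def class_logp(psi, nu_psi, beta, out):
    """Normalized partial-credit class log-probabilities, out (N, I, 3)."""
    N = psi.shape[0]
    I = beta.shape[0]
    for n in range(N):
        s1 = nu_psi * psi[n]
        for i in range(I):
            a0 = beta[i, 0]
            a1 = s1 + beta[i, 1]
            a2 = 2.0 * s1 + beta[i, 2]
            m = a0
            if a1 > m:
                m = a1
            if a2 > m:
                m = a2
            ls = m + np.log(np.exp(a0 - m) + np.exp(a1 - m) + np.exp(a2 - m))
            out[n, i, 0] = a0 - ls
            out[n, i, 1] = a1 - ls
            out[n, i, 2] = a2 - ls


@njit(cache=True, fastmath=True)
def mix3_marginal(clp, c0, c1, c2, out):
    """Per-cell marginal log-likelihood of the 3-class mixture, out (N, I)."""
    N, I = out.shape
    for n in range(N):
        for i in range(I):
            a0 = clp[n, i, 0] + c0[n, i]
            a1 = clp[n, i, 1] + c1[n, i]
            a2 = clp[n, i, 2] + c2[n, i]
            m = a0
            if a1 > m:
                m = a1
            if a2 > m:
                m = a2
            out[n, i] = m + np.log(np.exp(a0 - m) + np.exp(a1 - m) + np.exp(a2 - m))


@njit(cache=True, fastmath=True)
def resp_prob_loglik(tt, ft, g, y, use_tt, use_ft, p, ccll):
    """Fused softmax: category probabilities ``p`` (N, I, K+1) and observed
    log-likelihood ``ccll`` (N, I) for one class."""
    N, I = y.shape
    K1 = g.shape[1]
    for n in range(N):
        for i in range(I):
            m = -1.0e300
            for k in range(K1):
                v = g[i, k]
                if use_tt:
                    v += tt[n, i, k]
                if use_ft:
                    v += ft[n, i, k]
                p[n, i, k] = v
                if v > m:
                    m = v
            ssum = 0.0
            for k in range(K1):
                e = np.exp(p[n, i, k] - m)
                p[n, i, k] = e
                ssum += e
            inv = 1.0 / ssum
            for k in range(K1):
                p[n, i, k] *= inv
            ccll[n, i] = np.log(p[n, i, y[n, i]])


@njit(cache=True, fastmath=True)
def resp_grad(p, r, y, w_trait, alpha_t, theta, w_fake, alpha_f, eta,
              use_tt, use_ft, ggrad, xg_theta, ag, xg_eta, fg):
    """Accumulate response-model gradients for one class.

    ``p`` (N, I, K+1) category probabilities, ``r`` (N, I) cell
    responsibilities of the class.  Accumulates into the category-intercept
    gradient ``ggrad`` (I, K+1), trait-score gradient ``xg_theta`` (N, D),
    trait-slope gradient ``ag`` (I, D), faking-score gradient ``xg_eta``
    (N,) and faking-slope gradient ``fg`` (I,).
    """
    N, I = y.shape
    K1 = p.shape[2]
    D = w_trait.shape[1]
    for n in range(N):
        for i in range(I):
            rr = r[n, i]
            yk = y[n, i]
            for k in range(K1):
                Gk = -rr * p[n, i, k]
                if k == yk:
                    Gk += rr
                ggrad[i, k] += Gk
                if use_tt:
                    for dd in range(D):
                        wv = w_trait[i, dd, k]
                        if wv != 0.0:
                            xg_theta[n, dd] += Gk * alpha_t[i, dd] * wv
                            ag[i, dd] += Gk * theta[n, dd] * wv
                if use_ft:
                    wv = w_fake[i, k]
                    if wv != 0.0:
                        xg_eta[n] += Gk * alpha_f[i] * wv
                        fg[i] += Gk * eta[n] * wv


@njit(cache=True, fastmath=True)
def mix3_resp(clp, c0, c1, c2, ll, r):
    """Cell-mixture marginal log-likelihood and responsibilities.

    ``ll`` (N, I) receives the per-cell marginal; ``r`` (N, I, 3) the
    normalized class responsibilities.
    """
    N, I = ll.shape
    for n in range(N):
        for i in range(I):
            a0 = clp[n, i, 0] + c0[n, i]
            a1 = clp[n, i, 1] + c1[n, i]
            a2 = clp[n, i, 2] + c2[n, i]
            m = a0
            if a1 > m:
                m = a1
            if a2 > m:
                m = a2
            e0 = np.exp(a0 - m)
            e1 = np.exp(a1 - m)
            e2 = np.exp(a2 - m)
            s = e0 + e1 + e2
            if s > 0.0:
                ll[n, i] = m + np.log(s)
                r[n, i, 0] = e0 / s
                r[n, i, 1] = e1 / s
                r[n, i, 2] = e2 / s
            else:  # degenerate state (diverged trajectory): flag, don't crash
                ll[n, i] = -1.0e300
                r[n, i, 0] = 1.0 / 3.0
                r[n, i, 1] = 1.0 / 3.0
                r[n, i, 2] = 1.0 / 3.0


@njit(cache=True, fastmath=True)
def mix3_select(clp, c0, c1, c2, zeta, out):
    """Complete-data log-likelihood at sampled classes, out (N, I)."""
    N, I = out.shape
    for n in range(N):
        for i in range(I):
            z = zeta[n, i]
            if z == 0:
                out[n, i] = clp[n, i, 0] + c0[n, i]
            elif z == 1:
                out[n, i] = clp[n, i, 1] + c1[n, i]
            else:
                out[n, i] = clp[n, i, 2] + c2[n, i]
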