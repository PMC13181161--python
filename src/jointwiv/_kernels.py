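"""Fused numba kernels for the joint log-likelihood and its gradient.

These mirror the vectorised numpy implementation in ``posterior`` (which
remains the reference path and the one exercised by the dual-route tests)
but fuse the element-wise chains over observations and quadrature nodes
into single passes.  The kernels cover the common model structure: any
number of fixed effects per submodel, at most one random intercept per
(submodel, biomarker), and CV/LP association.  Unsupported structures fall
back to the numpy path automatically.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


_EXP_CLIP = 350.0


@njit(cache=True, fastmath=False)
def longitudinal_kernel(
    X_mu, X_sig, subj, y, beta_mu, beta_sig, b,
    mu_col, sig_col,
    g_beta_mu, g_beta_sig, G_b, per_subject,
):
    """One biomarker's Gaussian location-scale log-likelihood + gradients.

    mu_col / sig_col: column of b holding the random intercept (-1 if the
    submodel has no random effect).  Gradient arrays are accumulated into.
    """
    n = y.shape[0]
    p_mu = X_mu.shape[1]
    p_sig = X_sig.shape[1]
    ll = 0.0
    log2pi_half = 0.9189385332046727
    for i in range(n):
        s = subj[i]
        eta_mu = 0.0
        for j in range(p_mu):
            eta_mu += X_mu[i, j] * beta_mu[j]
        if mu_col >= 0:
            eta_mu += b[s, mu_col]
        eta_sig = 0.0
        for j in range(p_sig):
            eta_sig += X_sig[i, j] * beta_sig[j]
        if sig_col >= 0:
            eta_sig += b[s, sig_col]
        r = y[i] - eta_mu
        a = -2.0 * eta_sig
        if a > _EXP_CLIP:
            a = _EXP_CLIP
        e2 = np.exp(a)
        row = -log2pi_half - eta_sig - 0.5 * r * r * e2
        ll += row
        per_subject[s] += row
        d_mu = r * e2
        d_sig = -1.0 + r * r * e2
        for j in range(p_mu):
            g_beta_mu[j] += X_mu[i, j] * d_mu
        for j in range(p_sig):
            g_beta_sig[j] += X_sig[i, j] * d_sig
        if mu_col >= 0:
            G_b[s, mu_col] += d_mu
        if sig_col >= 0:
            G_b[s, sig_col] += d_sig
    return ll


@njit(cache=True, fastmath=False)
def event_kernel(
    BT, Bq, cq, W, delta,
    XT, Xq, pcols, re_col, is_cv_sigma, beta_stack, alpha,
    gamma, gamma_h0, b,
    g_beta_stack, g_gamma, g_alpha, g_gh, G_b, per_subject,
):
    """Event log-likelihood with CV/LP association + gradients.

    XT: (J, N, pmax), Xq: (J, N, Q, pmax) padded fixed designs per
    association term; beta_stack: (J, pmax) padded coefficient rows;
    re_col[j]: b column of the term's random intercept (-1 if none);
    is_cv_sigma[j]: 1 when the term enters as exp(eta) (CV, sigma part).
    """
    N, Q = cq.shape
    L = BT.shape[1]
    J = pcols.shape[0]
    pw = W.shape[1]
    ll = 0.0
    m_T = np.empty(J)
    m_q = np.empty(J)
    for i in range(N):
        wgam = 0.0
        for j in range(pw):
            wgam += W[i, j] * gamma[j]
        # log hazard at the observed time
        logh_T = wgam
        for l in range(L):
            logh_T += BT[i, l] * gamma_h0[l]
        for t in range(J):
            m = 0.0
            for j in range(pcols[t]):
                m += XT[t, i, j] * beta_stack[t, j]
            if re_col[t] >= 0:
                m += b[i, re_col[t]]
            if is_cv_sigma[t] == 1:
                if m > _EXP_CLIP:
                    m = _EXP_CLIP
                m = np.exp(m)
            m_T[t] = m
            logh_T += alpha[t] * m
        d_i = delta[i]
        contrib = d_i * logh_T
        # quadrature over the at-risk interval
        cum = 0.0
        for q in range(Q):
            logh = wgam
            for l in range(L):
                logh += Bq[i, q, l] * gamma_h0[l]
            for t in range(J):
                m = 0.0
                for j in range(pcols[t]):
                    m += Xq[t, i, q, j] * beta_stack[t, j]
                if re_col[t] >= 0:
                    m += b[i, re_col[t]]
                if is_cv_sigma[t] == 1:
                    if m > _EXP_CLIP:
                        m = _EXP_CLIP
                    m = np.exp(m)
                m_q[t] = m
                logh += alpha[t] * m
            if logh > _EXP_CLIP:
                logh = _EXP_CLIP
            H = cq[i, q] * np.exp(logh)
            cum += H
            # gradient weight -H at this node
            for l in range(L):
                g_gh[l] -= H * Bq[i, q, l]
            for j in range(pw):
                g_gamma[j] -= H * W[i, j]
            for t in range(J):
                m = m_q[t]
                g_alpha[t] -= H * m
                w = alpha[t] * H
                if is_cv_sigma[t] == 1:
                    w *= m
                for j in range(pcols[t]):
                    g_beta_stack[t, j] -= w * Xq[t, i, q, j]
                if re_col[t] >= 0:
                    G_b[i, re_col[t]] -= w
        contrib -= cum
        ll += contrib
        per_subject[i] += contrib
        if d_i != 0.0:
            for l in range(L):
                g_gh[l] += d_i * BT[i, l]
            for j in range(pw):
                g_gamma[j] += d_i * W[i, j]
            for t in range(J):
                g_alpha[t] += d_i * m_T[t]
                w = d_i * alpha[t]
                if is_cv_sigma[t] == 1:
                    w *= m_T[t]
                for j in range(pcols[t]):
                    g_beta_stack[t, j] += w * XT[t, i, j]
                if re_col[t] >= 0:
                    G_b[i, re_col[t]] += w
    return ll
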