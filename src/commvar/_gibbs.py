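"""Numba-compiled MCMC kernels for both inference stages.

Stage 1 (multispecies Gompertz state-space model) uses adaptive
Metropolis-within-Gibbs: per-year vector random-walk updates of the latent
log abundances, scalar adaptive random-walk updates of r, k, delta, tau, and
two complementary moves for the environmental covariance C — a random walk
on its log-Cholesky parameters and an inverse-Wishart independence proposal
matched to the current process residuals (nearly exact when demographic
noise is small, which is the regime these data live in).

Stage 2 (mixed model on stage-1 summaries) is conjugate Gibbs for all
location parameters with scalar Metropolis updates for the two uniform-prior
standard deviations.

Proposal scales adapt by Robbins-Monro during burn-in only and are frozen
afterwards, so retained draws come from a fixed Markov kernel.
"""

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


# ---------------------------------------------------------------------------
# linear-algebra helpers (manual Cholesky avoids exceptions inside numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _chol_inplace(Sig, L):
    """Lower Cholesky of Sig into L; returns 1 if not positive definite."""
    S = Sig.shape[0]
    for i in range(S):
        for j in range(i + 1):
            acc = Sig[i, j]
            for m in range(j):
                acc -= L[i, m] * L[j, m]
            if i == j:
                if acc <= 0.0:
                    return 1
                L[i, i] = np.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
        for j in range(i + 1, S):
            L[i, j] = 0.0
    return 0


@njit(cache=True)
def _mvn_ll(resid, Sig, L, zv):
    """MVN(0, Sig) log density at resid; L, zv are scratch. -inf if not PD."""
    S = Sig.shape[0]
    if _chol_inplace(Sig, L) != 0:
        return -np.inf
    logdet = 0.0
    quad = 0.0
    for i in range(S):
        acc = resid[i]
        for m in range(i):
            acc -= L[i, m] * zv[m]
        zv[i] = acc / L[i, i]
        logdet += np.log(L[i, i])
        quad += zv[i] * zv[i]
    return -0.5 * (S * LOG2PI + quad) - logdet


@njit(cache=True)
def _pair_ll(nprev, ncur, r, k, dl, C, Sig, L, zv, resid):
    """Log density of one process transition nprev -> ncur."""
    S = r.size
    for i in range(S):
        for j in range(S):
            Sig[i, j] = C[i, j]
    for i in range(S):
        Sig[i, i] = C[i, i] + dl[i] * dl[i] * np.exp(-nprev[i])
        resid[i] = ncur[i] - nprev[i] - r[i] * (1.0 - nprev[i] / k[i])
    return _mvn_ll(resid, Sig, L, zv)


@njit(cache=True)
def _proc_ll(n, r, k, dl, C, Sig, L, zv, resid):
    """Full process log likelihood over all T-1 transitions."""
    T = n.shape[0]
    ll = 0.0
    for t in range(1, T):
        ll += _pair_ll(n[t - 1], n[t], r, k, dl, C, Sig, L, zv, resid)
        if ll == -np.inf:
            return -np.inf
    return ll


@njit(cache=True)
def _obs_ll_i(y, obs, n, tau_i, i):
    """Observation log likelihood for species i at its current states."""
    T = y.shape[0]
    ll = 0.0
    has_obs = False
    for t in range(T):
        if obs[t, i]:
            has_obs = True
            d = y[t, i] - n[t, i]
            ll += -0.5 * (LOG2PI + d * d / (tau_i * tau_i)) - np.log(tau_i)
    if has_obs and tau_i <= 1e-12:
        return -np.inf
    return ll


@njit(cache=True)
def _latent_ll(nt, t, n, y, obs, r, k, dl, ta, C, mu0, sd0, Sig, L, zv, resid):
    """Log conditional (up to a constant) of the year-t state vector nt."""
    T, S = n.shape
    ll = 0.0
    for i in range(S):
        if obs[t, i]:
            d = y[t, i] - nt[i]
            ll += -0.5 * d * d / (ta[i] * ta[i])
    if t == 0:
        for i in range(S):
            d = nt[i] - mu0[i]
            ll += -0.5 * d * d / (sd0 * sd0)
    else:
        ll += _pair_ll(n[t - 1], nt, r, k, dl, C, Sig, L, zv, resid)
    if t < T - 1:
        ll += _pair_ll(nt, n[t + 1], r, k, dl, C, Sig, L, zv, resid)
    return ll


@njit(cache=True)
def _logdet_and_inv(C, L, Cinv):
    """Log determinant and inverse of a PD matrix via Cholesky."""
    S = C.shape[0]
    if _chol_inplace(C, L) != 0:
        return np.inf
    logdet = 0.0
    for i in range(S):
        logdet += 2.0 * np.log(L[i, i])
    # invert L (lower triangular), then Cinv = Linv^T Linv
    Linv = np.zeros((S, S))
    for i in range(S):
        Linv[i, i] = 1.0 / L[i, i]
        for j in range(i - 1, -1, -1):
            acc = 0.0
            for m in range(j + 1, i + 1):
                acc -= L[m, j] * Linv[i, m]
            Linv[i, j] = acc / L[j, j]
    for i in range(S):
        for j in range(S):
            acc = 0.0
            for m in range(max(i, j), S):
                acc += Linv[m, i] * Linv[m, j]
            Cinv[i, j] = acc
    return logdet


@njit(cache=True)
def _prior_c_ll(C, df, L, Cinv):
    """Inverse-Wishart(df, I) log prior on C, up to a constant."""
    S = C.shape[0]
    logdet = _logdet_and_inv(C, L, Cinv)
    if logdet == np.inf:
        return -np.inf
    tr = 0.0
    for i in range(S):
        tr += Cinv[i, i]
    return -0.5 * (df + S + 1) * logdet - 0.5 * tr


@njit(cache=True)
def _theta_to_chol(theta, Lc):
    """Unpack log-Cholesky parameters (row-major lower triangle) into Lc."""
    S = Lc.shape[0]
    idx = 0
    for i in range(S):
        for j in range(i + 1):
            if i == j:
                Lc[i, j] = np.exp(theta[idx])
            else:
                Lc[i, j] = theta[idx]
            idx += 1
        for j in range(i + 1, S):
            Lc[i, j] = 0.0


@njit(cache=True)
def _chol_to_theta(Lc, theta):
    S = Lc.shape[0]
    idx = 0
    for i in range(S):
        for j in range(i + 1):
            if i == j:
                theta[idx] = np.log(Lc[i, j])
            else:
                theta[idx] = Lc[i, j]
            idx += 1


@njit(cache=True)
def _log_jac_theta(theta, S):
    """log |d C / d theta| for the log-Cholesky parameterization."""
    lj = S * np.log(2.0)
    idx = 0
    for i in range(S):
        for j in range(i + 1):
            if i == j:
                lj += (S - i + 1.0) * theta[idx]
            idx += 1
    return lj


@njit(cache=True)
def _accept_prob(delta):
    if delta >= 0.0:
        return 1.0
    if delta < -50.0:
        return 0.0
    return np.exp(delta)


# ---------------------------------------------------------------------------
# stage-1 chain
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_first_chain(
    y,
    obs,
    kmin,
    kmax,
    r_scale,
    sd_upper,
    df,
    n_iter,
    burn,
    thin,
    seed,
    n0,
    r0,
    k0,
    dl0,
    ta0,
    C0,
    fix_r,
    fix_k,
    fix_dl,
    fix_ta,
    fix_C,
    mu0,
    sd0,
):
    """One MCMC chain for the multispecies Gompertz state-space model.

    Returns retained draws of (n, r, k, delta, tau, C).
    """
    np.random.seed(seed)
    T, S = y.shape
    n = n0.copy()
    r = r0.copy()
    k = k0.copy()
    dl = dl0.copy()
    ta = ta0.copy()
    C = C0.copy()

    # scratch
    Sig = np.empty((S, S))
    L = np.empty((S, S))
    Lc = np.empty((S, S))
    Cinv = np.empty((S, S))
    zv = np.empty(S)
    resid = np.empty(S)
    prop_vec = np.empty(S)
    cur_vec = np.empty(S)

    ntheta = S * (S + 1) // 2
    theta = np.empty(ntheta)
    _chol_inplace(C, Lc)
    _chol_to_theta(Lc, theta)

    n_ret = (n_iter - burn) // thin
    out_n = np.empty((n_ret, T, S))
    out_r = np.empty((n_ret, S))
    out_k = np.empty((n_ret, S))
    out_dl = np.empty((n_ret, S))
    out_ta = np.empty((n_ret, S))
    out_C = np.empty((n_ret, S, S))

    # adaptive log proposal scales
    ls_n = np.full(T, np.log(0.2))
    ls_r = np.full(S, np.log(0.1))
    ls_k = np.full(S, np.log(0.1))
    ls_dl = np.full(S, np.log(0.2))
    ls_ta = np.full(S, np.log(0.2))
    ls_sc = np.full(S, np.log(0.3))
    ls_th = np.log(0.05)
    tmp_col = np.empty(T)

    cur_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
    cur_obs = np.empty(S)
    for i in range(S):
        cur_obs[i] = _obs_ll_i(y, obs, n, ta[i], i)
    cur_cprior = _prior_c_ll(C, df, L, Cinv)

    Cp = np.empty((S, S))
    thp = np.empty(ntheta)
    Sres = np.empty((S, S))
    Psiq = np.empty((S, S))
    A = np.empty((S, S))
    Ainv = np.empty((S, S))
    G = np.empty((S, S))
    Lps = np.empty((S, S))

    ret = 0
    for it in range(n_iter):
        adapt = it < burn
        gam = min(0.25, 2.0 / np.sqrt(it + 1.0))

        # ---- latent states: per-year vector random walks ----
        for t in range(T):
            sc = np.exp(ls_n[t])
            for i in range(S):
                cur_vec[i] = n[t, i]
                prop_vec[i] = n[t, i] + sc * np.random.standard_normal()
            ll_old = _latent_ll(cur_vec, t, n, y, obs, r, k, dl, ta, C, mu0, sd0, Sig, L, zv, resid)
            ll_new = _latent_ll(prop_vec, t, n, y, obs, r, k, dl, ta, C, mu0, sd0, Sig, L, zv, resid)
            d = ll_new - ll_old
            ap = _accept_prob(d)
            if np.random.random() < ap:
                for i in range(S):
                    n[t, i] = prop_vec[i]
            if adapt:
                ls_n[t] += gam * (ap - 0.25)
        cur_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
        for i in range(S):
            cur_obs[i] = _obs_ll_i(y, obs, n, ta[i], i)

        # ---- growth rates r_i (half-normal prior) ----
        if not fix_r:
            for i in range(S):
                rp = r[i] + np.exp(ls_r[i]) * np.random.standard_normal()
                if rp <= 0.0:
                    ap = 0.0
                else:
                    rold = r[i]
                    r[i] = rp
                    prop_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
                    d = (prop_proc - cur_proc) - 0.5 * (rp * rp - rold * rold) / (r_scale * r_scale)
                    ap = _accept_prob(d)
                    if np.random.random() < ap:
                        cur_proc = prop_proc
                    else:
                        r[i] = rold
                if adapt:
                    ls_r[i] += gam * (ap - 0.44)

        # ---- log carrying capacities k_i (uniform prior in bounds) ----
        if not fix_k:
            for i in range(S):
                kp = k[i] + np.exp(ls_k[i]) * np.random.standard_normal()
                if kp < kmin[i] or kp > kmax[i]:
                    ap = 0.0
                else:
                    kold = k[i]
                    k[i] = kp
                    prop_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
                    d = prop_proc - cur_proc
                    ap = _accept_prob(d)
                    if np.random.random() < ap:
                        cur_proc = prop_proc
                    else:
                        k[i] = kold
                if adapt:
                    ls_k[i] += gam * (ap - 0.44)

        # ---- demographic SDs delta_i (uniform(0, sd_upper) prior) ----
        if not fix_dl:
            for i in range(S):
                dp = dl[i] + np.exp(ls_dl[i]) * np.random.standard_normal()
                if dp < 0.0 or dp > sd_upper:
                    ap = 0.0
                else:
                    dold = dl[i]
                    dl[i] = dp
                    prop_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
                    d = prop_proc - cur_proc
                    ap = _accept_prob(d)
                    if np.random.random() < ap:
                        cur_proc = prop_proc
                    else:
                        dl[i] = dold
                if adapt:
                    ls_dl[i] += gam * (ap - 0.44)

        # ---- observation SDs tau_i (uniform(0, sd_upper) prior) ----
        if not fix_ta:
            for i in range(S):
                tp = ta[i] + np.exp(ls_ta[i]) * np.random.standard_normal()
                if tp <= 0.0 or tp > sd_upper:
                    ap = 0.0
                else:
                    prop_obs = _obs_ll_i(y, obs, n, tp, i)
                    d = prop_obs - cur_obs[i]
                    ap = _accept_prob(d)
                    if np.random.random() < ap:
                        ta[i] = tp
                        cur_obs[i] = prop_obs
                if adapt:
                    ls_ta[i] += gam * (ap - 0.44)

        # ---- joint (tau_i, states) scaling move ----
        # Rescaling the state-observation residuals together with tau walks
        # along the ridge that couples them; plain scalar tau updates mix
        # slowly across it. Jacobian of the scaling is f^(n_obs + 1).
        if not fix_ta:
            for i in range(S):
                h = np.exp(ls_sc[i]) * np.random.standard_normal()
                f = np.exp(h)
                tp = ta[i] * f
                if tp <= 0.0 or tp > sd_upper:
                    ap = 0.0
                else:
                    nobs_i = 0
                    for t in range(T):
                        tmp_col[t] = n[t, i]
                        if obs[t, i]:
                            n[t, i] = y[t, i] + f * (n[t, i] - y[t, i])
                            nobs_i += 1
                    prop_proc = _proc_ll(n, r, k, dl, C, Sig, L, zv, resid)
                    prop_obs = _obs_ll_i(y, obs, n, tp, i)
                    d = (prop_proc - cur_proc) + (prop_obs - cur_obs[i]) + (nobs_i + 1.0) * h
                    if obs[0, i]:
                        dn = n[0, i] - mu0[i]
                        do = tmp_col[0] - mu0[i]
                        d += -0.5 * (dn * dn - do * do) / (sd0 * sd0)
                    ap = _accept_prob(d)
                    if np.random.random() < ap:
                        ta[i] = tp
                        cur_proc = prop_proc
                        cur_obs[i] = prop_obs
                    else:
                        for t in range(T):
                            n[t, i] = tmp_col[t]
                if adapt:
                    ls_sc[i] += gam * (ap - 0.44)

        # ---- environmental covariance C ----
        if not fix_C:
            # (a) random walk on log-Cholesky parameters
            sc = np.exp(ls_th)
            for j in range(ntheta):
                thp[j] = theta[j] + sc * np.random.standard_normal()
            _theta_to_chol(thp, Lc)
            for i in range(S):
                for j in range(S):
                    acc = 0.0
                    for m in range(S):
                        acc += Lc[i, m] * Lc[j, m]
                    Cp[i, j] = acc
            prop_proc = _proc_ll(n, r, k, dl, Cp, Sig, L, zv, resid)
            prop_cprior = _prior_c_ll(Cp, df, L, Cinv)
            d = (
                prop_proc
                + prop_cprior
                + _log_jac_theta(thp, S)
                - cur_proc
                - cur_cprior
                - _log_jac_theta(theta, S)
            )
            ap = _accept_prob(d)
            if np.random.random() < ap:
                for j in range(ntheta):
                    theta[j] = thp[j]
                for i in range(S):
                    for j in range(S):
                        C[i, j] = Cp[i, j]
                cur_proc = prop_proc
                cur_cprior = prop_cprior
            if adapt:
                ls_th += gam * (ap - 0.25)

            # (b) inverse-Wishart independence proposal from process residuals
            for i in range(S):
                for j in range(S):
                    Sres[i, j] = 0.0
            for t in range(1, T):
                for i in range(S):
                    resid[i] = n[t, i] - n[t - 1, i] - r[i] * (1.0 - n[t - 1, i] / k[i])
                for i in range(S):
                    for j in range(S):
                        Sres[i, j] += resid[i] * resid[j]
            dfq = df + (T - 1.0)
            for i in range(S):
                for j in range(S):
                    Psiq[i, j] = Sres[i, j]
                Psiq[i, i] += 1.0  # Omega = identity
            if _chol_inplace(Psiq, Lps) == 0:
                # Bartlett draw: C* = Lps (A A^T)^{-1} Lps^T ~ IW(dfq, Psiq)
                for i in range(S):
                    for j in range(S):
                        A[i, j] = 0.0
                for i in range(S):
                    A[i, i] = np.sqrt(2.0 * np.random.gamma(0.5 * (dfq - i), 1.0))
                    for j in range(i):
                        A[i, j] = np.random.standard_normal()
                for i in range(S):
                    Ainv[i, i] = 1.0 / A[i, i]
                    for j in range(i + 1, S):
                        Ainv[i, j] = 0.0
                    for j in range(i - 1, -1, -1):
                        acc = 0.0
                        for m in range(j + 1, i + 1):
                            acc -= A[m, j] * Ainv[i, m]
                        Ainv[i, j] = acc / A[j, j]
                for i in range(S):
                    for j in range(S):
                        acc = 0.0
                        for m in range(max(i, j), S):
                            acc += Ainv[m, i] * Ainv[m, j]
                        G[i, j] = acc
                for i in range(S):
                    for j in range(S):
                        acc = 0.0
                        for m in range(S):
                            for q in range(S):
                                acc += Lps[i, m] * G[m, q] * Lps[j, q]
                        Cp[i, j] = acc
                # symmetrize against rounding
                for i in range(S):
                    for j in range(i):
                        v = 0.5 * (Cp[i, j] + Cp[j, i])
                        Cp[i, j] = v
                        Cp[j, i] = v
                prop_proc = _proc_ll(n, r, k, dl, Cp, Sig, L, zv, resid)
                prop_cprior = _prior_c_ll(Cp, df, L, Cinv)
                # log q(C; dfq, Psiq) up to Psiq-only constants
                ld_p = _logdet_and_inv(Cp, L, Cinv)
                trq_p = 0.0
                for i in range(S):
                    for j in range(S):
                        trq_p += Psiq[i, j] * Cinv[j, i]
                lq_p = -0.5 * (dfq + S + 1.0) * ld_p - 0.5 * trq_p
                ld_c = _logdet_and_inv(C, L, Cinv)
                trq_c = 0.0
                for i in range(S):
                    for j in range(S):
                        trq_c += Psiq[i, j] * Cinv[j, i]
                lq_c = -0.5 * (dfq + S + 1.0) * ld_c - 0.5 * trq_c
                d = (prop_proc + prop_cprior - lq_p) - (cur_proc + cur_cprior - lq_c)
                if np.random.random() < _accept_prob(d):
                    for i in range(S):
                        for j in range(S):
                            C[i, j] = Cp[i, j]
                    cur_proc = prop_proc
                    cur_cprior = prop_cprior
                    _chol_inplace(C, Lc)
                    _chol_to_theta(Lc, theta)

        # ---- retain ----
        if it >= burn and (it - burn) % thin == 0:
            for t in range(T):
                for i in range(S):
                    out_n[ret, t, i] = n[t, i]
            for i in range(S):
                out_r[ret, i] = r[i]
                out_k[ret, i] = k[i]
                out_dl[ret, i] = dl[i]
                out_ta[ret, i] = ta[i]
                for j in range(S):
                    out_C[ret, i, j] = C[i, j]
            ret += 1

    return out_n, out_r, out_k, out_dl, out_ta, out_C


# ---------------------------------------------------------------------------
# stage-2 chains
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_second_chain_random(
    p, sp2, c, z, K, n_iter, burn, thin, seed, alpha0, beta0, mu00, sa0, se0
):
    """Random-intercept mixed model chain: p_x ~ N(alpha_z + beta*c_x, se^2 + sp2_x)."""
    np.random.seed(seed)
    nobs = p.size
    alpha = alpha0.copy()
    beta = beta0
    mu = mu00
    sa = sa0
    se = se0
    prior_prec = 1e-4  # Normal(0, 10000) on mu and beta
    sd_upper = 10.0

    n_ret = (n_iter - burn) // thin
    out_alpha = np.empty((n_ret, K))
    out_beta = np.empty(n_ret)
    out_mu = np.empty(n_ret)
    out_sa = np.empty(n_ret)
    out_se = np.empty(n_ret)

    ls_sa = np.log(0.2)
    ls_se = np.log(0.2)

    ret = 0
    for it in range(n_iter):
        adapt = it < burn
        gam = min(0.25, 2.0 / np.sqrt(it + 1.0))

        # alpha_g | rest (conjugate)
        for g in range(K):
            prec = 1.0 / (sa * sa)
            m = mu / (sa * sa)
            for x in range(nobs):
                if z[x] == g:
                    v = se * se + sp2[x]
                    prec += 1.0 / v
                    m += (p[x] - beta * c[x]) / v
            m /= prec
            alpha[g] = m + np.random.standard_normal() / np.sqrt(prec)

        # beta | rest (conjugate)
        prec = prior_prec
        m = 0.0
        for x in range(nobs):
            if c[x] != 0.0:
                v = se * se + sp2[x]
                prec += c[x] * c[x] / v
                m += c[x] * (p[x] - alpha[z[x]]) / v
        m /= prec
        beta = m + np.random.standard_normal() / np.sqrt(prec)

        # mu | alpha (conjugate)
        prec = prior_prec + K / (sa * sa)
        m = 0.0
        for g in range(K):
            m += alpha[g]
        m = (m / (sa * sa)) / prec
        mu = m + np.random.standard_normal() / np.sqrt(prec)

        # sa: Metropolis, Uniform(0, 10) prior on the SD
        sp = sa + np.exp(ls_sa) * np.random.standard_normal()
        if sp <= 0.0 or sp > sd_upper:
            ap = 0.0
        else:
            d = 0.0
            for g in range(K):
                dev = alpha[g] - mu
                d += -0.5 * dev * dev / (sp * sp) - np.log(sp)
                d -= -0.5 * dev * dev / (sa * sa) - np.log(sa)
            ap = _accept_prob(d)
            if np.random.random() < ap:
                sa = sp
        if adapt:
            ls_sa += gam * (ap - 0.44)

        # se: Metropolis
        sp_ = se + np.exp(ls_se) * np.random.standard_normal()
        if sp_ <= 0.0 or sp_ > sd_upper:
            ap = 0.0
        else:
            d = 0.0
            for x in range(nobs):
                mean = alpha[z[x]] + beta * c[x]
                dev = p[x] - mean
                vn = sp_ * sp_ + sp2[x]
                vo = se * se + sp2[x]
                d += -0.5 * (np.log(vn) + dev * dev / vn)
                d -= -0.5 * (np.log(vo) + dev * dev / vo)
            ap = _accept_prob(d)
            if np.random.random() < ap:
                se = sp_
        if adapt:
            ls_se += gam * (ap - 0.44)

        if it >= burn and (it - burn) % thin == 0:
            for g in range(K):
                out_alpha[ret, g] = alpha[g]
            out_beta[ret] = beta
            out_mu[ret] = mu
            out_sa[ret] = sa
            out_se[ret] = se
            ret += 1

    return out_alpha, out_beta, out_mu, out_sa, out_se


@njit(cache=True)
def run_second_chain_factorial(p, sp2, X, n_iter, burn, thin, seed, theta0, se0):
    """Fixed-effects variant: p_x ~ N(X theta, se^2 + sp2_x).

    The last column of X is the factor dummy, so beta = theta[-1]; the
    remaining columns are intercept and community contrasts.
    """
    np.random.seed(seed)
    nobs, P = X.shape
    theta = theta0.copy()
    se = se0
    prior_prec = 1e-4
    sd_upper = 10.0

    n_ret = (n_iter - burn) // thin
    out_theta = np.empty((n_ret, P))
    out_se = np.empty(n_ret)

    ls_se = np.log(0.2)
    prec = np.empty((P, P))
    Lp = np.empty((P, P))
    b = np.empty(P)
    zv = np.empty(P)
    w = np.empty(P)

    ret = 0
    for it in range(n_iter):
        adapt = it < burn
        gam = min(0.25, 2.0 / np.sqrt(it + 1.0))

        # theta | se (conjugate MVN)
        for i in range(P):
            b[i] = 0.0
            for j in range(P):
                prec[i, j] = prior_prec if i == j else 0.0
        for x in range(nobs):
            v = se * se + sp2[x]
            for i in range(P):
                b[i] += X[x, i] * p[x] / v
                for j in range(P):
                    prec[i, j] += X[x, i] * X[x, j] / v
        _chol_inplace(prec, Lp)
        # solve prec * m = b via Cholesky, then theta = m + Lp^{-T} z
        for i in range(P):
            acc = b[i]
            for m in range(i):
                acc -= Lp[i, m] * zv[m]
            zv[i] = acc / Lp[i, i]
        for i in range(P - 1, -1, -1):
            acc = zv[i]
            for m in range(i + 1, P):
                acc -= Lp[m, i] * w[m]
            w[i] = acc / Lp[i, i]  # w = posterior mean
        for i in range(P):
            zv[i] = np.random.standard_normal()
        for i in range(P - 1, -1, -1):
            acc = zv[i]
            for m in range(i + 1, P):
                acc -= Lp[m, i] * theta[m]
            theta[i] = acc / Lp[i, i]
        for i in range(P):
            theta[i] += w[i]

        # se: Metropolis
        sp_ = se + np.exp(ls_se) * np.random.standard_normal()
        if sp_ <= 0.0 or sp_ > sd_upper:
            ap = 0.0
        else:
            d = 0.0
            for x in range(nobs):
                mean = 0.0
                for i in range(P):
                    mean += X[x, i] * theta[i]
                dev = p[x] - mean
                vn = sp_ * sp_ + sp2[x]
                vo = se * se + sp2[x]
                d += -0.5 * (np.log(vn) + dev * dev / vn)
                d -= -0.5 * (np.log(vo) + dev * dev / vo)
            ap = _accept_prob(d)
            if np.random.random() < ap:
                se = sp_
        if adapt:
            ls_se += gam * (ap - 0.44)

        if it >= burn and (it - burn) % thin == 0:
            for i in range(P):
                out_theta[ret, i] = theta[i]
            out_se[ret] = se
            ret += 1

    return out_theta, out_se
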