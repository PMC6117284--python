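"""Numba kernel for the adaptive random-walk Metropolis sampler.

The chain runs in unconstrained coordinates: each factor level's proportion
simplex is mapped to R^(K-1) by the isometric log-ratio (ILR) transform, and
residual scales are sampled on the log scale. The target density therefore
carries the ILR Jacobian (sum of log p_k per level) and the log-tau Jacobian
on top of the Dirichlet prior and Gaussian likelihood. Source means and SDs
are redrawn from their closed-form sources-only posterior every iteration
(scaled inverse-chi-square for the variance, conditional normal for the
mean), and the current state's log posterior is re-evaluated under the fresh
draw before each Metropolis comparison.

Proposal scales adapt per block (one block per level plus one for the taus)
by Robbins-Monro toward 0.3 acceptance, during burn-in only, so the retained
portion of the chain satisfies detailed balance.
"""

import numpy as np
from numba import njit

LOG_2PI = 1.8378770664093453


def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal Helmert-type contrast basis: columns span {1}^perp in R^k."""
    if k < 2:
        raise ValueError("need at least 2 components")
    v = np.zeros((k, k - 1))
    for d in range(1, k):
        v[:d, d - 1] = 1.0 / d
        v[d, d - 1] = -1.0
        v[:, d - 1] *= np.sqrt(d / (d + 1.0))
    return v


def ilr(p: np.ndarray) -> np.ndarray:
    """Forward ILR: simplex point -> R^(K-1)."""
    p = np.asarray(p, float)
    clr = np.log(p) - np.mean(np.log(p))
    return ilr_basis(p.shape[-1]).T @ clr


def ilr_inv(z: np.ndarray) -> np.ndarray:
    """Inverse ILR: R^(K-1) -> simplex point (softmax of the basis expansion)."""
    z = np.asarray(z, float)
    e = ilr_basis(z.shape[-1] + 1) @ z
    e = np.exp(e - e.max())
    return e / e.sum()


@njit(cache=True)
def _logpost(z, logtau, mu, sig, y, lev, conc, alpha, residual_err, tau_sample,
             tau_upper, basis, mlev, vlev):
    n_lev = z.shape[0]
    k = basis.shape[0]
    j_n = y.shape[1]
    lp = 0.0
    for l in range(n_lev):
        emax = -1.0e308
        e = np.empty(k)
        for a in range(k):
            acc = 0.0
            for d in range(k - 1):
                acc += basis[a, d] * z[l, d]
            e[a] = acc
            if acc > emax:
                emax = acc
        ssum = 0.0
        for a in range(k):
            e[a] = np.exp(e[a] - emax)
            ssum += e[a]
        for a in range(k):
            # Dirichlet(alpha) prior plus ILR Jacobian: (alpha-1)+1 = alpha
            lp += alpha[a] * np.log(e[a] / ssum)
        for j in range(j_n):
            den = 0.0
            for a in range(k):
                den += (e[a] / ssum) * conc[a, j]
            m = 0.0
            v = 0.0
            for a in range(k):
                pp = (e[a] / ssum) * conc[a, j] / den
                m += pp * mu[a, j]
                v += pp * pp * sig[a, j] * sig[a, j]
            mlev[l, j] = m
            vlev[l, j] = v
    tau2 = np.empty(j_n)
    for j in range(j_n):
        t = np.exp(logtau[j])
        if tau_sample:
            if t > tau_upper[j]:
                return -np.inf
            lp += logtau[j]  # log-scale Jacobian against the uniform tau prior
        tau2[j] = t * t
    for i in range(y.shape[0]):
        l = lev[i]
        for j in range(j_n):
            var = tau2[j] if residual_err else vlev[l, j]
            if var <= 0.0:
                return -np.inf
            d = y[i, j] - mlev[l, j]
            lp += -0.5 * (LOG_2PI + np.log(var)) - d * d / (2.0 * var)
    return lp


@njit(cache=True)
def run_chain(y, lev, n_lev, xbar, s, nobs, draw_src, conc, alpha, residual_err,
              tau_sample, logtau_init, tau_upper, basis, n_iter, burn, thin, seed):
    """One MCMC chain; returns retained draws (n_keep, n_lev*K + J)."""
    np.random.seed(seed)
    k, j_n = xbar.shape
    z = np.zeros((n_lev, k - 1))
    logtau = logtau_init.copy()
    mu = xbar.copy()
    sig = s.copy()
    mlev = np.empty((n_lev, j_n))
    vlev = np.empty((n_lev, j_n))
    n_keep = (n_iter - burn) // thin
    out = np.empty((n_keep, n_lev * k + j_n))
    n_blocks = n_lev + 1
    log_scale = np.full(n_blocks, np.log(0.3))
    kept = 0
    for t in range(n_iter):
        if draw_src:
            for a in range(k):
                for j in range(j_n):
                    sj = s[a, j]
                    nj = nobs[a, j]
                    if sj > 0.0 and nj >= 2.0:
                        chi = 2.0 * np.random.standard_gamma(0.5 * (nj - 1.0))
                        s2 = (nj - 1.0) * sj * sj / chi
                        sig[a, j] = np.sqrt(s2)
                        mu[a, j] = xbar[a, j] + np.random.standard_normal() * np.sqrt(s2 / nj)
                    else:
                        sig[a, j] = sj
                        mu[a, j] = xbar[a, j]
        lp_curr = _logpost(z, logtau, mu, sig, y, lev, conc, alpha, residual_err,
                           tau_sample, tau_upper, basis, mlev, vlev)
        gamma = 1.0 / (1.0 + 0.1 * t) ** 0.6
        for l in range(n_lev):
            zp = z.copy()
            step = np.exp(log_scale[l])
            for d in range(k - 1):
                zp[l, d] += step * np.random.standard_normal()
            lp_prop = _logpost(zp, logtau, mu, sig, y, lev, conc, alpha, residual_err,
                               tau_sample, tau_upper, basis, mlev, vlev)
            acc = np.exp(min(0.0, lp_prop - lp_curr))
            if np.random.random() < acc:
                z = zp
                lp_curr = lp_prop
            if t < burn:
                log_scale[l] += gamma * (acc - 0.3)
        if tau_sample:
            ltp = logtau.copy()
            step = np.exp(log_scale[n_lev])
            for j in range(j_n):
                ltp[j] += step * np.random.standard_normal()
            lp_prop = _logpost(z, ltp, mu, sig, y, lev, conc, alpha, residual_err,
                               tau_sample, tau_upper, basis, mlev, vlev)
            acc = np.exp(min(0.0, lp_prop - lp_curr))
            if np.random.random() < acc:
                logtau = ltp
                lp_curr = lp_prop
            if t < burn:
                log_scale[n_lev] += gamma * (acc - 0.3)
        if t >= burn and (t - burn) % thin == thin - 1:
            for l in range(n_lev):
                emax = -1.0e308
                e = np.empty(k)
                for a in range(k):
                    acc2 = 0.0
                    for d in range(k - 1):
                        acc2 += basis[a, d] * z[l, d]
                    e[a] = acc2
                    if acc2 > emax:
                        emax = acc2
                ssum = 0.0
                for a in range(k):
                    e[a] = np.exp(e[a] - emax)
                    ssum += e[a]
                for a in range(k):
                    out[kept, l * k + a] = e[a] / ssum
            for j in range(j_n):
                out[kept, n_lev * k + j] = np.exp(logtau[j])
            kept += 1
    return out
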