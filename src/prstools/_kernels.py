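"""Numba kernels: scalar conditional-posterior updates and the solvers.

These are the single source of truth for the per-SNP updates; the Python
wrappers in :mod:`prstools.vb` expose the same quantities with full
component detail for testing against numerical quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_NEG_INF = -1e300


@njit(cache=True)
def log_ndtr(x):
    """log of the standard normal CDF, stable in the lower tail.

    erfc stays representable down to x ~ -37; beyond that the asymptotic
    tail series takes over (its relative error there is ~1e-9).
    """
    if x > -35.0:
        return math.log(0.5 * math.erfc(-x / _SQRT2))
    x2 = x * x
    return -0.5 * x2 - _LOG_SQRT_2PI - math.log(-x) + math.log1p(
        -1.0 / x2 + 3.0 / (x2 * x2) - 15.0 / (x2 * x2 * x2)
    )


@njit(cache=True)
def mills_ratio(x):
    """phi(x) / Phi(x), stable for very negative x."""
    if x > -35.0:
        phi = math.exp(-0.5 * x * x - _LOG_SQRT_2PI)
        return phi / (0.5 * math.erfc(-x / _SQRT2))
    x2 = x * x
    return -x / (1.0 - 1.0 / x2 + 3.0 / (x2 * x2) - 15.0 / (x2 * x2 * x2))


@njit(cache=True)
def gaussian_mixture_update(t, xtx, s2e, weights, variances):
    """Posterior mean and second moment for a Gaussian-mixture prior.

    A zero prior variance denotes a point mass at zero. Responsibilities
    come from exact component marginal likelihoods, computed in log space.
    Returns (mean, second_moment).
    """
    C = weights.shape[0]
    logr = np.empty(C)
    mu = np.empty(C)
    v = np.empty(C)
    best = _NEG_INF
    for c in range(C):
        w = weights[c]
        if w <= 0.0:
            logr[c] = _NEG_INF
            mu[c] = 0.0
            v[c] = 0.0
            continue
        s2c = variances[c]
        if s2c <= 0.0:
            mu[c] = 0.0
            v[c] = 0.0
            logr[c] = math.log(w)
        else:
            denom = xtx + s2e / s2c
            mu[c] = t / denom
            v[c] = s2e / denom
            logr[c] = (
                math.log(w)
                + 0.5 * (math.log(v[c]) - math.log(s2c))
                + 0.5 * mu[c] * mu[c] / v[c]
            )
        if logr[c] > best:
            best = logr[c]
    z = 0.0
    for c in range(C):
        logr[c] = math.exp(logr[c] - best)
        z += logr[c]
    mean = 0.0
    second = 0.0
    for c in range(C):
        r = logr[c] / z
        mean += r * mu[c]
        second += r * (mu[c] * mu[c] + v[c])
    return mean, second


@njit(cache=True)
def laplace_update(t, xtx, s2e, rate):
    """Posterior mean and second moment under a double-exponential prior.

    The posterior is a two-piece truncated Gaussian; both pieces are
    handled in closed form with log-space piece weights.
    Returns (mean, second_moment).
    """
    s2 = s2e / xtx
    s = math.sqrt(s2)
    mu_p = (t - rate * s2e) / xtx
    mu_m = (t + rate * s2e) / xtx
    lw_p = 0.5 * mu_p * mu_p / s2 + log_ndtr(mu_p / s)
    lw_m = 0.5 * mu_m * mu_m / s2 + log_ndtr(-mu_m / s)
    mx = lw_p if lw_p > lw_m else lw_m
    wp = math.exp(lw_p - mx)
    wm = math.exp(lw_m - mx)
    z = wp + wm
    wp /= z
    wm /= z
    lam_p = mills_ratio(mu_p / s)   # hazard of the positive piece at 0
    lam_m = mills_ratio(-mu_m / s)  # hazard of the negative piece at 0
    e_p = mu_p + s * lam_p
    e_m = mu_m - s * lam_m
    s_p = mu_p * mu_p + s2 + s * mu_p * lam_p
    s_m = mu_m * mu_m + s2 - s * mu_m * lam_m
    return wp * e_p + wm * e_m, wp * s_p + wm * s_m


@njit(cache=True)
def laplace_mode(t, xtx, s2e, rate):
    """Posterior mode under a double-exponential prior (soft threshold)."""
    thr = rate * s2e
    if t > thr:
        return (t - thr) / xtx
    if t < -thr:
        return (t + thr) / xtx
    return 0.0


# ---------------------------------------------------------------------------
# summary-statistic sliding-window solver


@njit(cache=True)
def _window_variance(beta, indptr, indices, vals, i0, i1):
    """beta_w^T C_w beta_w with stored sparse LD and unit diagonal."""
    v = 0.0
    for j in range(i0, i1):
        bj = beta[j]
        if bj == 0.0:
            continue
        acc = bj
        for k in range(indptr[j], indptr[j + 1]):
            l = indices[k]
            if i0 <= l < i1:
                acc += vals[k] * beta[l]
        v += bj * acc
    return v


@njit(cache=True)
def solve_windows_kernel(nr, n, indptr, indices, vals, wstart, wend,
                         weights, variances, rates, use_laplace,
                         s2e, tol, max_iter, beta0):
    """Iterative conditional-mean updates over sliding windows.

    nr is X^T Y per SNP (= n * r); LD is the symmetric sparse store
    (diagonal implicit). Windows that fail to converge within max_iter
    are rolled back. Returns (beta, resets).
    """
    m = nr.shape[0]
    beta = beta0.copy()
    resets = 0
    nwin = wstart.shape[0]
    for w in range(nwin):
        i0 = wstart[w]
        i1 = wend[w]
        if i1 <= i0:
            continue
        saved = beta[i0:i1].copy()
        vold = _window_variance(beta, indptr, indices, vals, i0, i1)
        converged = False
        for _ in range(max_iter):
            for j in range(i0, i1):
                acc = 0.0
                for k in range(indptr[j], indptr[j + 1]):
                    acc += vals[k] * beta[indices[k]]
                t = nr[j] - n * acc
                if use_laplace:
                    bm, _ = laplace_update(t, n, s2e, rates[j])
                else:
                    bm, _ = gaussian_mixture_update(
                        t, n, s2e, weights, variances[j]
                    )
                beta[j] = bm
            vnew = _window_variance(beta, indptr, indices, vals, i0, i1)
            if abs(vnew - vold) < tol:
                converged = True
                break
            vold = vnew
        if not converged:
            beta[i0:i1] = saved
            resets += 1
    return beta, resets


# ---------------------------------------------------------------------------
# individual-level variational Bayes


@njit(cache=True)
def vb_individual_kernel(X, Y, weights, variances, rates, use_laplace,
                         use_mode, s2e, tol, max_iter, beta0):
    """Cyclic conditional-posterior updates with an exact residual vector.

    X must be standardized (X_j^T X_j = n). Convergence is declared when
    both the total posterior second moment (estimated genetic variance)
    and the residual variance move by less than tol between iterations.
    Starts from beta0 (warm start / checkpoint resume).
    Returns (beta, converged, iterations).
    """
    n, m = X.shape
    nf = float(n)
    beta = beta0.copy()
    resid = np.empty(n)
    for i in range(n):
        resid[i] = Y[i]
    for j in range(m):
        if beta[j] != 0.0:
            for i in range(n):
                resid[i] -= X[i, j] * beta[j]
    vold = -1.0
    rss_old = -1.0
    converged = 0
    it_done = 0
    for it in range(max_iter):
        vtot = 0.0
        for j in range(m):
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * resid[i]
            t = dot + nf * beta[j]
            if use_laplace:
                if use_mode:
                    bnew = laplace_mode(t, nf, s2e, rates[j])
                    snew = bnew * bnew
                else:
                    bnew, snew = laplace_update(t, nf, s2e, rates[j])
            else:
                bnew, snew = gaussian_mixture_update(
                    t, nf, s2e, weights, variances[j]
                )
            diff = beta[j] - bnew
            if diff != 0.0:
                for i in range(n):
                    resid[i] += X[i, j] * diff
                beta[j] = bnew
            vtot += snew
        rss = 0.0
        for i in range(n):
            rss += resid[i] * resid[i]
        rss /= nf
        it_done = it + 1
        if vold >= 0.0 and abs(vtot - vold) < tol and abs(rss - rss_old) < tol:
            converged = 1
            break
        vold = vtot
        rss_old = rss
    return beta, converged, it_done


# ---------------------------------------------------------------------------
# lasso coordinate descent


@njit(cache=True)
def lasso_cd_active(X, resid, beta, active, pf, lam, tol, max_iter):
    """Cyclic soft-threshold coordinate descent over an active set.

    Minimises 1/(2n) ||Y - X beta||^2 + lam * sum_j pf_j |beta_j|;
    resid and beta are updated in place. Returns number of sweeps used.
    """
    n = X.shape[0]
    nf = float(n)
    for sweep in range(max_iter):
        max_delta = 0.0
        for a in range(active.shape[0]):
            j = active[a]
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * resid[i]
            z = dot / nf + beta[j]
            thr = lam * pf[j]
            if z > thr:
                bnew = z - thr
            elif z < -thr:
                bnew = z + thr
            else:
                bnew = 0.0
            diff = beta[j] - bnew
            if diff != 0.0:
                for i in range(n):
                    resid[i] += X[i, j] * diff
                beta[j] = bnew
                ad = abs(diff)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return sweep + 1
    return max_iter


@njit(cache=True)
def gradient_abs(X, resid):
    """|X^T resid| / n for every column."""
    n, m = X.shape
    out = np.empty(m)
    for j in range(m):
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * resid[i]
        out[j] = abs(dot) / n
    return out


# ---------------------------------------------------------------------------
# haplotype-copying genotype simulator


@njit(cache=True)
def haplotype_copy_kernel(p, rho, nhap, seed):
    """First-order copying process: allele copied from the previous SNP
    with probability rho, else drawn fresh at that SNP's frequency.

    Copy runs are sampled as geometric run lengths (one draw per run)
    rather than one Bernoulli per SNP; the process is identical in
    distribution.
    """
    m = p.shape[0]
    np.random.seed(seed)
    H = np.empty((nhap, m), np.int8)
    if rho <= 0.0:
        for i in range(nhap):
            for j in range(m):
                H[i, j] = 1 if np.random.random() < p[j] else 0
        return H
    log_rho = math.log(rho)
    for i in range(nhap):
        j = 0
        while j < m:
            h = np.int8(1) if np.random.random() < p[j] else np.int8(0)
            # run of copies until the next fresh draw
            u = np.random.random()
            run = 1 + int(math.log(u) / log_rho)
            j_end = j + run
            if j_end > m:
                j_end = m
            for jj in range(j, j_end):
                H[i, jj] = h
            j = j_end
    return H
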