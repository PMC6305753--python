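"""Numba kernels for the penalized weighted-least-squares coordinate descent.

These kernels solve, for fixed weights ``w`` (all ones in the plain linear
case, IRLS working weights in the logistic case),

    min_{b0, beta}  (1/2n) sum_i w_i (y_i - b0 - x_i' beta)^2
                    + sum_j mcp(|beta_j|; lam1, gamma)
                    + lam2 * beta' Omega beta

by cyclic coordinate descent with the closed-form scalar MCP update.  The
intercept is never penalized.  Everything here operates on a standardized
design; back-transforms live in :mod:`phylosparse.solver`.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def mcp_value(t, lam1, gamma):
    """MCP penalty value at |t|: lam1*|t| - t^2/(2 gamma) up to saturation."""
    at = abs(t)
    if at <= gamma * lam1:
        return lam1 * at - at * at / (2.0 * gamma)
    return 0.5 * gamma * lam1 * lam1


@njit(cache=True)
def scalar_mcp_update(a, b, lam1, gamma):
    """argmin_t (a/2) t^2 - b t + mcp(|t|; lam1, gamma), requires a > 1/gamma."""
    ab = abs(b)
    if ab <= lam1:
        return 0.0
    if ab <= a * gamma * lam1:
        return np.sign(b) * (ab - lam1) / (a - 1.0 / gamma)
    return b / a


@njit(cache=True)
def _objective(r, w, beta, Omega, lam1, gamma, lam2, use_omega, n):
    obj = 0.0
    for i in range(r.shape[0]):
        obj += w[i] * r[i] * r[i]
    obj *= 0.5 / n
    for j in range(beta.shape[0]):
        obj += mcp_value(beta[j], lam1, gamma)
    if use_omega and lam2 > 0.0:
        quad = 0.0
        for j in range(beta.shape[0]):
            s = 0.0
            for k in range(beta.shape[0]):
                s += Omega[j, k] * beta[k]
            quad += beta[j] * s
        obj += lam2 * quad
    return obj


@njit(cache=True)
def cd_solve(X, y, w, Omega, use_omega, lam1, gamma, lam2,
             beta0, beta, update_intercept, tol, max_sweeps):
    """Cyclic coordinate descent to convergence; ``beta`` is updated in place.

    Returns ``(beta0, n_sweeps, converged, objective_trace)`` where the trace
    holds the penalized weighted objective after each full sweep.
    """
    n, p = X.shape
    fn = float(n)

    # curvature of each scalar subproblem: a_j = (1/n) sum w x^2 (+ ridge part)
    a_base = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        a_base[j] = s / fn

    r = np.empty(n)
    for i in range(n):
        s = beta0
        for j in range(p):
            if beta[j] != 0.0:
                s += X[i, j] * beta[j]
        r[i] = y[i] - s

    trace = np.empty(max_sweeps)
    converged = False
    sweep = 0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        max_beta = 0.0
        if update_intercept:
            num = 0.0
            den = 0.0
            for i in range(n):
                num += w[i] * r[i]
                den += w[i]
            d0 = num / den
            beta0 += d0
            for i in range(n):
                r[i] -= d0
        for j in range(p):
            bj = beta[j]
            g = 0.0
            for i in range(n):
                g += w[i] * X[i, j] * r[i]
            b = g / fn + a_base[j] * bj
            a = a_base[j]
            if use_omega and lam2 > 0.0:
                s = -Omega[j, j] * bj
                for k in range(p):
                    if beta[k] != 0.0:
                        s += Omega[j, k] * beta[k]
                b -= 2.0 * lam2 * s
                a += 2.0 * lam2 * Omega[j, j]
            new = scalar_mcp_update(a, b, lam1, gamma)
            d = new - bj
            if d != 0.0:
                beta[j] = new
                for i in range(n):
                    r[i] -= d * X[i, j]
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
            ab = abs(new)
            if ab > max_beta:
                max_beta = ab
        trace[sweep] = _objective(r, w, beta, Omega, lam1, gamma, lam2,
                                  use_omega, fn)
        ref = max_beta if max_beta > 1.0 else 1.0
        if max_delta < tol * ref:
            converged = True
            break
    return beta0, sweep + 1, converged, trace[: sweep + 1]
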