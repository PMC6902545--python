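"""Independent brute-force oracles used only by the test suite.

These share no code with the package's estimation paths: log-likelihoods are
written directly from the model definitions with plain scipy.stats calls and
maximized by Nelder-Mead followed by per-coordinate refinement.
"""

import numpy as np
from scipy import optimize, stats


def _polish(nll, x, sweeps=3, width=1e-2):
    """Per-coordinate refinement of a Nelder-Mead solution (grid + Brent)."""
    x = x.copy()
    for _ in range(sweeps):
        for j in range(len(x)):
            def f1(v, j=j):
                xx = x.copy()
                xx[j] = v
                return nll(xx)

            res = optimize.minimize_scalar(
                f1,
                bracket=(x[j] - width, x[j], x[j] + width),
                method="brent",
                options={"xtol": 1e-12},
            )
            if res.fun <= nll(x):
                x[j] = res.x
    return x


def oracle_probit(s, Z, start=None):
    """Probit MLE by direct Nelder-Mead on the Bernoulli log-likelihood."""
    s = np.asarray(s, dtype=float)
    Z = np.asarray(Z, dtype=float)
    q = 2.0 * s - 1.0

    def nll(g):
        return -float(np.sum(stats.norm.logcdf(q * (Z @ g))))

    x0 = np.zeros(Z.shape[1]) if start is None else np.asarray(start, float)
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000, "adaptive": True},
    )
    return _polish(nll, res.x)


def oracle_heckman_fiml(y, X, Z, s, start=None):
    """Continuous-outcome selection MLE over (beta, gamma, atanh rho, log sigma).

    The outcome is scaled by its observed SD (no centering) so every
    coordinate is O(1) for the simplex; results are returned on the natural
    scale as (beta, gamma, rho, sigma).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    sel = np.asarray(s) == 1
    sd = float(np.std(y[sel]))
    ys = y[sel] / sd
    Xs, Zs, Z0 = X[sel], Z[sel], Z[~sel]
    nb, ng = X.shape[1], Z.shape[1]

    def nll(theta):
        b, g = theta[:nb], theta[nb : nb + ng]
        rho, sig = np.tanh(theta[-2]), np.exp(theta[-1])
        a = (ys - Xs @ b) / sig
        w = (Zs @ g + rho * a) / np.sqrt(1.0 - rho**2)
        ll = np.sum(stats.norm.logcdf(-(Z0 @ g)))
        ll += np.sum(stats.norm.logpdf(a) - np.log(sig) + stats.norm.logcdf(w))
        return -float(ll)

    if start is None:
        b0, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        g0 = oracle_probit(np.asarray(s, float), Z)
        resid = ys - Xs @ b0
        x0 = np.concatenate([b0, g0, [0.0, np.log(np.std(resid))]])
    else:
        x0 = np.asarray(start, dtype=float)
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 200_000,
                 "maxfev": 200_000, "adaptive": True},
    )
    theta = _polish(nll, res.x, sweeps=4, width=1e-3)
    beta = theta[:nb] * sd
    gamma = theta[nb : nb + ng]
    rho = float(np.tanh(theta[-2]))
    sigma = float(np.exp(theta[-1])) * sd
    return beta, gamma, rho, sigma


def mills_highprec(u, digits=60):
    """Inverse Mills ratio via arbitrary-precision sympy arithmetic."""
    import sympy

    x = sympy.Float(u, digits)
    phi = sympy.exp(-x**2 / 2) / sympy.sqrt(2 * sympy.pi)
    Phi = sympy.erfc(-x / sympy.sqrt(2)) / 2
    return float(sympy.N(phi / Phi, digits))
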