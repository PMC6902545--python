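"""Heckman sample-selection estimators.

Two estimators for a continuous outcome observed only for a selected
subsample:

* the classical two-step correction — probit of the selection indicator on Z,
  then OLS of the outcome on X augmented with the inverse Mills ratio
  evaluated at the fitted selection index; and
* full-information maximum likelihood (FIML) of the joint model

      y_i = x_i' beta + mu_i,      s_i* = z_i' gamma + nu_i,
      (mu, nu) bivariate normal, sd(mu) = sigma, sd(nu) = 1, corr = rho,
      y observed iff s_i* > 0,

  with rho parameterized through atanh and sigma through log so the
  optimization is unconstrained; standard errors come from the observed
  information in the transformed space, delta-method back-transformed.

A bivariate-probit-with-selection variant covers binary outcomes, and
``test_rho_zero`` performs the likelihood-ratio (and Wald) test of
independent residuals — the diagnostic for endogenous selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import log_ndtr, ndtr, owens_t

from .exceptions import ConvergenceError, ParameterError
from .linear_probit import Z975, FitResult, ModelData, fit_ols, fit_probit, inverse_mills

logger = logging.getLogger(__name__)


@dataclass
class HeckmanFit:
    """Joint outcome/selection fit: beta, gamma, rho, sigma and lambda = rho*sigma."""

    beta: pd.Series
    gamma: pd.Series
    rho: float
    sigma: float
    lambda_coef: float
    se: pd.Series            # index: beta:<col>, gamma:<col>, rho, sigma, lambda
    loglik: float
    converged: bool
    method: str              # "two_step" | "fiml" | "probit_fiml"
    n_selected: int
    n_total: int
    se_atanh_rho: float = math.nan
    cov: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not abs(self.rho) <= 1.0:
            raise ParameterError(f"|rho| must be <= 1, got {self.rho}")
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        target = self.rho * self.sigma
        if abs(self.lambda_coef - target) > 1e-6 * max(1.0, abs(target)):
            raise ParameterError(
                f"lambda_coef ({self.lambda_coef}) must equal rho*sigma ({target})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Flat (parameter, estimate, se, ci_low, ci_high) table."""
        names = (
            [f"beta:{c}" for c in self.beta.index]
            + [f"gamma:{c}" for c in self.gamma.index]
            + ["rho", "sigma", "lambda"]
        )
        est = np.concatenate(
            [
                self.beta.to_numpy(),
                self.gamma.to_numpy(),
                [self.rho, self.sigma, self.lambda_coef],
            ]
        )
        se = self.se.reindex(names).to_numpy()
        return pd.DataFrame(
            {
                "parameter": names,
                "estimate": est,
                "se": se,
                "ci_low": est - Z975 * se,
                "ci_high": est + Z975 * se,
            }
        )


@dataclass
class RhoZeroTest:
    """Test of the null of independent outcome/selection residuals (rho = 0)."""

    statistic: float
    pvalue: float
    method: str              # "lr" or "wald"
    df: int = 1
    wald_statistic: float = math.nan
    wald_pvalue: float = math.nan


def selection_loglik(
    data: ModelData,
    beta: np.ndarray,
    gamma: np.ndarray,
    rho: float,
    sigma: float,
) -> float:
    """Log-likelihood of the continuous-outcome selection model at given parameters."""
    sel = data.s == 1
    X = data.X.to_numpy(dtype=float)[sel]
    Z = data.Z.to_numpy(dtype=float)
    y = data.y[sel]
    zg0 = Z[~sel] @ gamma
    a = (y - X @ beta) / sigma
    r1 = math.sqrt(max(1.0 - rho**2, 1e-12))
    w = (Z[sel] @ gamma + rho * a) / r1
    ll = float(np.sum(log_ndtr(-zg0)))
    ll += float(
        np.sum(-0.5 * math.log(2 * math.pi) - math.log(sigma) - 0.5 * a**2 + log_ndtr(w))
    )
    return ll


def heckman_two_step(data: ModelData) -> HeckmanFit:
    """Two-step correction: probit first stage, then OLS with the inverse Mills ratio.

    sigma is recovered from the step-2 residual variance plus the truncation
    correction; rho = lambda_coef / sigma, clamped to +/-0.99 with a warning.
    Step-2 SEs are the unadjusted OLS SEs (see the methods note for the caveat).
    """
    probit = fit_probit(data.s, data.Z)
    if not probit.converged:
        raise ConvergenceError("step-1 probit did not converge")
    sel = data.s == 1
    c = (data.Z.to_numpy(dtype=float) @ probit.coef.to_numpy())[sel]
    lam = inverse_mills(c)
    W = data.X.loc[sel].copy()
    W["_lambda"] = lam
    cond = float(np.linalg.cond(W.to_numpy()))
    logger.info("two-step augmented design condition number: %.3g", cond)
    if cond > 1e8:
        logger.warning(
            "inverse Mills ratio nearly collinear with X (condition number %.3g); "
            "estimates may be fragile without an exclusion restriction",
            cond,
        )
    res = sm.OLS(data.y[sel], W).fit()
    coef = pd.Series(res.params, index=W.columns)
    se2 = pd.Series(res.bse, index=W.columns)
    lambda_coef = float(coef["_lambda"])
    resid = data.y[sel] - W.to_numpy() @ coef.to_numpy()
    delta = lam * (lam + c)  # in (0, 1); truncation variance correction
    sigma2 = float(resid @ resid) / sel.sum() + float(np.mean(delta)) * lambda_coef**2
    sigma = math.sqrt(sigma2)
    rho = lambda_coef / sigma
    if abs(rho) > 0.99:
        logger.warning("two-step rho=%.4f clamped to +/-0.99", rho)
        rho = math.copysign(0.99, rho)
    beta = coef.drop("_lambda")
    se = pd.Series(
        np.concatenate(
            [
                se2.drop("_lambda").to_numpy(),
                probit.se.to_numpy(),
                [math.nan, math.nan, se2["_lambda"]],
            ]
        ),
        index=[f"beta:{c_}" for c_ in beta.index]
        + [f"gamma:{c_}" for c_ in probit.coef.index]
        + ["rho", "sigma", "lambda"],
    )
    ll = selection_loglik(data, beta.to_numpy(), probit.coef.to_numpy(), rho, sigma)
    return HeckmanFit(
        beta=beta,
        gamma=probit.coef.copy(),
        rho=rho,
        sigma=sigma,
        lambda_coef=rho * sigma,
        se=se,
        loglik=ll,
        converged=True,
        method="two_step",
        n_selected=int(sel.sum()),
        n_total=len(data.s),
    )


def _nll_and_grad(theta, y, Xs, Z, sel, scale):
    """Negative log-likelihood and analytic gradient, outcome pre-standardized."""
    nb = Xs.shape[1]
    ng = Z.shape[1]
    b = theta[:nb]
    g = theta[nb : nb + ng]
    t, ls = theta[-2], theta[-1]
    rho = math.tanh(t)
    sig = math.exp(ls)
    r1 = math.sqrt(1.0 - rho**2)
    Zs, Z0 = Z[sel], Z[~sel]
    a = (y - Xs @ b) / sig
    zg_s = Zs @ g
    w = (zg_s + rho * a) / r1
    m = inverse_mills(w)
    zg0 = Z0 @ g
    m0 = inverse_mills(-zg0)
    ll = float(np.sum(log_ndtr(-zg0)))
    ll += float(np.sum(-0.5 * math.log(2 * math.pi) - ls - 0.5 * a**2 + log_ndtr(w)))
    db = Xs.T @ (a - m * (rho / r1)) / sig
    dg = Zs.T @ m / r1 - Z0.T @ m0
    dt = float(np.sum(m * (a + rho * zg_s)) / r1)
    dls = float(np.sum(-1.0 + a**2 - m * rho * a / r1))
    grad = np.concatenate([db, dg, [dt, dls]])
    return -ll, -grad


def _num_hessian(fun, x, step=1e-5):
    """Central-difference Hessian of a scalar function (symmetrized)."""
    d = len(x)
    H = np.empty((d, d))
    h = step * (1.0 + np.abs(x))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def heckman_fiml(data: ModelData, init: HeckmanFit | None = None) -> HeckmanFit:
    """Full-information ML for the continuous-outcome selection model.

    Starts from the two-step fit (or a supplied one; falls back to
    OLS-on-selected plus probit with rho = 0 if the two-step fails).  The
    outcome is standardized internally so every optimization coordinate is
    O(1); estimates, SEs and the log-likelihood are reported on the natural
    scale.
    """
    sel = data.s == 1
    if init is None:
        try:
            init = heckman_two_step(data)
        except Exception as exc:
            logger.warning("two-step start failed (%s); falling back to rho=0 start", exc)
            ols = fit_ols(data, use_selected_only=True)
            probit = fit_probit(data.s, data.Z)
            resid = data.y[sel] - data.X.loc[sel].to_numpy() @ ols.coef.to_numpy()
            init = HeckmanFit(
                beta=ols.coef,
                gamma=probit.coef,
                rho=0.0,
                sigma=float(np.std(resid)),
                lambda_coef=0.0,
                se=pd.Series(dtype=float),
                loglik=math.nan,
                converged=True,
                method="two_step",
                n_selected=int(sel.sum()),
                n_total=len(data.s),
            )

    y_sel = data.y[sel]
    shift = float(np.mean(y_sel)) if "const" in data.X.columns else 0.0
    scale = float(np.std(y_sel))
    if scale <= 0:
        raise ParameterError("outcome has zero variance on the selected rows")
    ys = (y_sel - shift) / scale
    Xs = data.X.loc[sel].to_numpy(dtype=float)
    Z = data.Z.to_numpy(dtype=float)

    b0 = init.beta.reindex(data.X.columns).to_numpy() / scale
    if "const" in data.X.columns:
        b0[list(data.X.columns).index("const")] -= shift / scale
    g0 = init.gamma.reindex(data.Z.columns).to_numpy()
    t0 = math.atanh(float(np.clip(init.rho, -0.95, 0.95)))
    ls0 = math.log(init.sigma / scale)
    x0 = np.concatenate([b0, g0, [t0, ls0]])

    args = (ys, Xs, Z, sel, scale)
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=args,
        jac=True,
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    theta = res.x
    # Newton polish: BFGS line searches can stall in the nearly flat rho
    # direction; a few damped Newton steps on the observed information drive
    # the gradient to machine-level zero.
    fval, grad = _nll_and_grad(theta, *args)
    H = _num_hessian(lambda th: _nll_and_grad(th, *args)[0], theta)
    for _ in range(5):
        if float(np.max(np.abs(grad))) < 1e-6:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale_ls = 1.0
        for _ in range(12):
            cand = theta - scale_ls * step
            fc, gc = _nll_and_grad(cand, *args)
            if fc <= fval:
                theta, fval, grad = cand, fc, gc
                break
            scale_ls *= 0.5
        else:
            break
        H = _num_hessian(lambda th: _nll_and_grad(th, *args)[0], theta)
    gnorm = float(np.max(np.abs(grad)))
    converged = gnorm < 1e-4
    if not converged:
        logger.warning("FIML did not converge; max |gradient| = %.3g", gnorm)

    nb = Xs.shape[1]
    ng = Z.shape[1]
    try:
        cov_t = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("observed information singular; using pseudo-inverse")
        cov_t = np.linalg.pinv(H)
    if np.any(np.diag(cov_t) < 0):
        logger.warning("observed information not positive definite at the optimum")

    b = theta[:nb] * scale
    if "const" in data.X.columns:
        b[list(data.X.columns).index("const")] += shift
    g = theta[nb : nb + ng]
    t, ls = theta[-2], theta[-1]
    rho = math.tanh(t)
    sigma = math.exp(ls) * scale
    if abs(rho) > 0.995:
        logger.warning("FIML rho estimate %.4f is at the boundary", rho)

    # delta-method back-transform of the covariance
    jac = np.ones(nb + ng + 2)
    jac[:nb] = scale
    jac[-2] = 1.0 - rho**2          # d rho / d atanh(rho)
    jac[-1] = sigma                 # d sigma / d log(sigma/scale)
    cov_nat = cov_t * np.outer(jac, jac)
    se_params = np.sqrt(np.clip(np.diag(cov_nat), 0.0, np.inf))
    # lambda = rho * sigma from the (t, ls) block
    grad_l = np.array([(1.0 - rho**2) * sigma, rho * sigma])
    var_l = float(grad_l @ cov_t[-2:, -2:] @ grad_l)
    se_lambda = math.sqrt(max(var_l, 0.0))

    names = (
        [f"beta:{c}" for c in data.X.columns]
        + [f"gamma:{c}" for c in data.Z.columns]
        + ["rho", "sigma"]
    )
    se = pd.Series(np.append(se_params, se_lambda), index=names + ["lambda"])
    ll = -float(fval) - int(sel.sum()) * math.log(scale)
    return HeckmanFit(
        beta=pd.Series(b, index=data.X.columns),
        gamma=pd.Series(g, index=data.Z.columns),
        rho=float(rho),
        sigma=float(sigma),
        lambda_coef=float(rho * sigma),
        se=se,
        loglik=ll,
        converged=converged,
        method="fiml",
        n_selected=int(sel.sum()),
        n_total=len(data.s),
        se_atanh_rho=float(np.sqrt(max(cov_t[-2, -2], 0.0))),
        cov=pd.DataFrame(cov_nat, index=names, columns=names),
    )


def test_rho_zero(fit: HeckmanFit, data: ModelData) -> RhoZeroTest:
    """LR test of rho = 0 (primary), with the Wald test on atanh(rho) alongside.

    Under rho = 0 the likelihood factorizes, so the restricted maximum is
    closed form: the full-sample probit plus the Gaussian ML fit on the
    selected rows.
    """
    if not fit.converged:
        raise ParameterError("test_rho_zero requires a converged fit")
    wald_stat = math.nan
    wald_p = math.nan
    if math.isfinite(fit.se_atanh_rho) and fit.se_atanh_rho > 0:
        z = math.atanh(np.clip(fit.rho, -0.999999, 0.999999)) / fit.se_atanh_rho
        wald_stat = z * z
        wald_p = float(stats.chi2.sf(wald_stat, 1))
    if fit.method != "fiml":
        logger.warning(
            "LR test needs a FIML fit; returning the Wald test only (method=%s)",
            fit.method,
        )
        return RhoZeroTest(
            statistic=wald_stat,
            pvalue=wald_p,
            method="wald",
            wald_statistic=wald_stat,
            wald_pvalue=wald_p,
        )
    probit = fit_probit(data.s, data.Z)
    sel = data.s == 1
    ols = fit_ols(data, use_selected_only=True)
    resid = data.y[sel] - data.X.loc[sel].to_numpy() @ ols.coef.to_numpy()
    n1 = int(sel.sum())
    sigma2_mle = float(resid @ resid) / n1
    ll0 = float(probit.loglik) - 0.5 * n1 * (math.log(2 * math.pi * sigma2_mle) + 1.0)
    lr = 2.0 * (fit.loglik - ll0)
    if lr < 0:
        if lr < -1e-6 * max(1.0, abs(ll0)):
            logger.warning("negative LR statistic %.3g; restricted fit may dominate", lr)
        lr = max(lr, 0.0)
    return RhoZeroTest(
        statistic=float(lr),
        pvalue=float(stats.chi2.sf(lr, 1)),
        method="lr",
        wald_statistic=wald_stat,
        wald_pvalue=wald_p,
    )


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(U <= h, V <= k) at correlation rho.

    Owen (1956): Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - c,
    with T Owen's T function, a_h = (k - rho h)/(h sqrt(1-rho^2)) and c = 1/2
    iff h k < 0 (zeros resolved toward +0).  Exact to the accuracy of
    scipy.special.owens_t (~1e-14); validated against the Genz integrator.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)
    r1 = math.sqrt(1.0 - rho * rho)
    hs = np.where(h == 0.0, 1e-300, h)
    ks = np.where(k == 0.0, 1e-300, k)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ah = np.clip((ks - rho * hs) / (hs * r1), -1e8, 1e8)
        ak = np.clip((hs - rho * ks) / (ks * r1), -1e8, 1e8)
    c = np.where(hs * ks < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hs, ah) - owens_t(ks, ak) - c
    return np.clip(out, 0.0, 1.0)


def heckman_probit_fiml(
    data: ModelData,
    margin_var: str | None = None,
    fix_rho: float | None = None,
) -> tuple[HeckmanFit, "pd.Series | None"]:
    """Bivariate probit with selection for a binary outcome.

    Unselected rows contribute log Phi(-z'gamma); selected rows contribute
    log Phi2(q x'beta... explicitly: log Phi2(x'beta, z'gamma; rho) when y = 1
    and log[Phi(z'gamma) - Phi2(x'beta, z'gamma; rho)] when y = 0.  If
    ``margin_var`` names a binary outcome covariate, the average marginal
    effect on P(y = 1) = Phi(x'beta) is computed over ALL rows (selected and
    unselected profiles), since the target is the population probability.
    """
    sel = data.s == 1
    y = data.y[sel]
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ParameterError("binary-outcome variant requires y in {0, 1} on selected rows")
    X = data.X.to_numpy(dtype=float)
    Z = data.Z.to_numpy(dtype=float)
    Xs = X[sel]
    Zs = Z[sel]
    Z0 = Z[~sel]
    y1 = y == 1.0
    nb, ng = Xs.shape[1], Zs.shape[1]

    def nll(theta):
        b = theta[:nb]
        g = theta[nb : nb + ng]
        rho = fix_rho if fix_rho is not None else math.tanh(theta[-1])
        xb = Xs @ b
        zg = Zs @ g
        p11 = bvn_cdf(xb, zg, rho)
        p01 = np.clip(ndtr(zg) - p11, 1e-300, None)
        ll = float(np.sum(log_ndtr(-(Z0 @ g))))
        ll += float(np.sum(np.log(np.clip(p11[y1], 1e-300, None))))
        ll += float(np.sum(np.log(p01[~y1])))
        return -ll

    probit_y = fit_probit(y.astype(int), data.X.loc[sel])
    probit_s = fit_probit(data.s, data.Z)
    x0 = np.concatenate([probit_y.coef.to_numpy(), probit_s.coef.to_numpy()])
    if fix_rho is None:
        x0 = np.append(x0, 0.0)
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
    theta = res.x
    rho = fix_rho if fix_rho is not None else math.tanh(theta[-1])
    H = _num_hessian(nll, theta, step=1e-4)
    try:
        cov_t = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_t = np.linalg.pinv(H)
    jac = np.ones(len(theta))
    if fix_rho is None:
        jac[-1] = 1.0 - rho**2
    cov_nat = cov_t * np.outer(jac, jac)
    se_all = np.sqrt(np.clip(np.diag(cov_nat), 0.0, np.inf))
    names = [f"beta:{c}" for c in data.X.columns] + [f"gamma:{c}" for c in data.Z.columns]
    se_vals = list(se_all[: nb + ng])
    se_rho = float(se_all[-1]) if fix_rho is None else 0.0
    se = pd.Series(
        se_vals + [se_rho, math.nan, math.nan],
        index=names + ["rho", "sigma", "lambda"],
    )
    fit = HeckmanFit(
        beta=pd.Series(theta[:nb], index=data.X.columns),
        gamma=pd.Series(theta[nb : nb + ng], index=data.Z.columns),
        rho=float(rho),
        sigma=1.0,
        lambda_coef=float(rho),
        se=se,
        loglik=-float(res.fun),
        converged=converged,
        method="probit_fiml",
        n_selected=int(sel.sum()),
        n_total=len(data.s),
        se_atanh_rho=float(np.sqrt(max(cov_t[-1, -1], 0.0))) if fix_rho is None else math.nan,
    )
    margin = None
    if margin_var is not None:
        if margin_var not in data.X.columns:
            raise ParameterError(f"margin_var '{margin_var}' is not an outcome covariate")
        j = list(data.X.columns).index(margin_var)
        b = theta[:nb]
        X1, X0v = X.copy(), X.copy()
        X1[:, j], X0v[:, j] = 1.0, 0.0
        u1, u0 = X1 @ b, X0v @ b
        ame = float(np.mean(ndtr(u1) - ndtr(u0)))
        grad = (stats.norm.pdf(u1)[:, None] * X1 - stats.norm.pdf(u0)[:, None] * X0v).mean(axis=0)
        var = float(grad @ cov_nat[:nb, :nb] @ grad)
        se_m = math.sqrt(max(var, 0.0))
        margin = pd.Series(
            {
                "value": ame,
                "se": se_m,
                "ci_low": ame - Z975 * se_m,
                "ci_high": ame + Z975 * se_m,
            },
            name=margin_var,
        )
    return fit, margin
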