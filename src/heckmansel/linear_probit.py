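"""OLS and probit building blocks reused by every selection estimator.

The fits delegate to statsmodels; this module owns the design-bundle
container, the average-marginal-effect computation and the numerically stable
inverse Mills ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import log_ndtr

from .exceptions import (
    ConvergenceError,
    EmptyDataError,
    ParameterError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ModelData:
    """The (y, X, s, Z) design bundle for any selection-model fit.

    ``y`` is the outcome (NaN where unobserved), ``s`` the 0/1 selection
    indicator, ``X`` the outcome design and ``Z`` the selection design.  The
    outcome covariates must be a subset of the selection covariates; a
    selection covariate *excluded* from the outcome equation (the exclusion
    restriction) is recommended, and its absence is logged as a warning.
    """

    y: np.ndarray
    X: pd.DataFrame
    s: np.ndarray
    Z: pd.DataFrame

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.s = np.asarray(self.s, dtype=np.int64)
        n = len(self.y)
        if not (len(self.X) == len(self.s) == len(self.Z) == n):
            raise ParameterError("y, X, s, Z must have equal row counts")
        extra = [c for c in self.X.columns if c not in self.Z.columns]
        if extra:
            raise ParameterError(
                f"X columns must be a subset of Z columns; extra in X: {extra}"
            )
        excluded = [c for c in self.Z.columns if c not in self.X.columns]
        if not excluded:
            logger.warning(
                "no exclusion restriction: every selection covariate also enters "
                "the outcome equation; identification rests on the nonlinearity "
                "of the inverse Mills ratio alone"
            )
        observed = ~np.isnan(self.y)
        if not np.array_equal(observed, self.s == 1):
            raise ParameterError("y must be present exactly where s == 1")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        x_cols: list[str],
        z_cols: list[str],
        select: str | None = None,
        add_const: bool = True,
    ) -> "ModelData":
        y = frame[outcome].to_numpy(dtype=float)
        s = (
            frame[select].to_numpy(dtype=np.int64)
            if select is not None
            else (~np.isnan(y)).astype(np.int64)
        )
        X = frame[list(x_cols)].astype(float).copy()
        Z = frame[list(z_cols)].astype(float).copy()
        if add_const:
            X.insert(0, "const", 1.0)
            Z.insert(0, "const", 1.0)
        return cls(y=y, X=X, s=s, Z=Z)

    @property
    def n_selected(self) -> int:
        return int((self.s == 1).sum())


@dataclass
class FitResult:
    """Coefficients with Wald 95% intervals from one OLS or probit fit."""

    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_used: int
    converged: bool
    loglik: float | None = None
    cov: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        bad = self.ci_low >= self.ci_high
        if bool(bad.any()):
            raise ParameterError(
                f"ci_low must be < ci_high elementwise; violated for {list(self.ci_low.index[bad])}"
            )


@dataclass
class MarginalEffect:
    """Average marginal effect of one covariate on P(s = 1) in a probit."""

    var: str
    kind: str  # "binary" or "continuous"
    value: float
    se: float
    ci_low: float
    ci_high: float


def _check_rank(M: np.ndarray, names: list[str]) -> None:
    if M.shape[0] < M.shape[1]:
        raise SingularDesignError(
            f"fewer rows ({M.shape[0]}) than columns ({M.shape[1]})"
        )
    scale = np.linalg.norm(M, axis=0)
    scale[scale == 0] = 1.0
    r = np.abs(np.diag(np.linalg.qr(M / scale, mode="r")))
    tol = M.shape[0] * np.finfo(float).eps
    suspect = [names[j] for j in range(len(names)) if r[j] < tol * max(1.0, r.max())]
    if suspect:
        raise SingularDesignError(f"rank-deficient design; collinear columns: {suspect}")


def fit_ols(data: ModelData, use_selected_only: bool = False) -> FitResult:
    """Closed-form least squares with conventional homoskedastic SEs.

    With ``use_selected_only`` this is the complete-case analysis: only rows
    with an observed outcome enter.  Otherwise all rows are used and the
    outcome must be fully observed.
    """
    if use_selected_only:
        rows = data.s == 1
    else:
        rows = np.ones(len(data.y), dtype=bool)
        if np.isnan(data.y).any():
            raise EmptyDataError(
                "outcome has missing values; use use_selected_only=True for a "
                "complete-case fit"
            )
    if rows.sum() == 0:
        raise EmptyDataError("no usable rows for OLS")
    X = data.X.loc[rows]
    y = data.y[rows]
    _check_rank(X.to_numpy(), list(X.columns))
    res = sm.OLS(y, X).fit()
    coef = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return FitResult(
        coef=coef,
        se=se,
        ci_low=coef - Z975 * se,
        ci_high=coef + Z975 * se,
        n_used=int(rows.sum()),
        converged=True,
        loglik=None,
        cov=cov,
    )


def _separating_column(s: np.ndarray, Z: pd.DataFrame) -> str | None:
    for c in Z.columns:
        v = Z[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            continue
        v1, v0 = v[s == 1], v[s == 0]
        if v1.min() > v0.max() or v1.max() < v0.min():
            return c
    return None


def fit_probit(s: np.ndarray, Z: pd.DataFrame) -> FitResult:
    """Maximum-likelihood probit of a 0/1 indicator on a named design."""
    s = np.asarray(s, dtype=np.int64)
    if s.min() == s.max():
        raise EmptyDataError(
            f"degenerate outcome: selection indicator is constant at {int(s[0])}"
        )
    _check_rank(Z.to_numpy(dtype=float), list(Z.columns))
    sep = _separating_column(s, Z)
    if sep is not None:
        raise ConvergenceError(
            f"perfect separation: column '{sep}' separates the 0/1 outcome; "
            "probit ML does not exist"
        )
    model = sm.Probit(s, Z)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except Exception as exc:  # statsmodels raises on separation/singularity
        raise ConvergenceError(f"probit fit failed: {exc}") from exc
    grad = model.score(res.params)
    converged = bool(res.mle_retvals.get("converged", False)) and (
        float(np.max(np.abs(grad))) < 1e-6 * max(1.0, len(s))
    )
    coef = pd.Series(res.params, index=Z.columns)
    se = pd.Series(res.bse, index=Z.columns)
    cov = pd.DataFrame(res.cov_params(), index=Z.columns, columns=Z.columns)
    return FitResult(
        coef=coef,
        se=se,
        ci_low=coef - Z975 * se,
        ci_high=coef + Z975 * se,
        n_used=len(s),
        converged=converged,
        loglik=float(res.llf),
        cov=cov,
    )


def probit_margins(fit: FitResult, Z: pd.DataFrame, var_name: str) -> MarginalEffect:
    """Average marginal effect of ``var_name`` on the probit success probability.

    Continuous columns: mean over rows of phi(z'g) * g_var.  Binary 0/1
    columns: mean over rows of Phi(z'g | var=1) - Phi(z'g | var=0).  The SE is
    by the delta method from the coefficient covariance.
    """
    if var_name not in fit.coef.index:
        raise ParameterError(
            f"unknown column '{var_name}'; fitted columns: {list(fit.coef.index)}"
        )
    if fit.cov is None:
        raise ParameterError("fit carries no coefficient covariance")
    g = fit.coef.to_numpy()
    names = list(fit.coef.index)
    j = names.index(var_name)
    Zm = Z[names].to_numpy(dtype=float)
    vals = np.unique(Zm[:, j])
    binary = np.isin(vals, (0.0, 1.0)).all()
    if binary:
        Z1, Z0 = Zm.copy(), Zm.copy()
        Z1[:, j], Z0[:, j] = 1.0, 0.0
        u1, u0 = Z1 @ g, Z0 @ g
        ame = float(np.mean(stats.norm.cdf(u1) - stats.norm.cdf(u0)))
        grad = (
            stats.norm.pdf(u1)[:, None] * Z1 - stats.norm.pdf(u0)[:, None] * Z0
        ).mean(axis=0)
        kind = "binary"
    else:
        u = Zm @ g
        phi = stats.norm.pdf(u)
        ame = float(np.mean(phi) * g[j])
        # d/dg_l mean(phi(u) g_j) = mean(-u phi z_l) g_j + delta_{lj} mean(phi)
        grad = (-u * phi)[:, None] * Zm
        grad = grad.mean(axis=0) * g[j]
        grad[j] += float(np.mean(phi))
        kind = "continuous"
    var = float(grad @ fit.cov.to_numpy() @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    return MarginalEffect(
        var=var_name,
        kind=kind,
        value=ame,
        se=se,
        ci_low=ame - Z975 * se,
        ci_high=ame + Z975 * se,
    )


def inverse_mills(u):
    """Inverse Mills ratio lambda(u) = phi(u) / Phi(u), stable on all finite reals.

    Computed as exp(log phi(u) - log Phi(u)); for u -> -inf this approaches
    -u without overflow or catastrophic cancellation.
    """
    arr = np.asarray(u, dtype=float)
    out = np.exp(stats.norm.logpdf(arr) - log_ndtr(arr))
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out
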