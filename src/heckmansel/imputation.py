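"""Comparison methods for missing outcomes: mean imputation, PIDA and MICE.

* ``mean_impute`` — replace every missing outcome by the overall observed mean.
* ``pida_impute`` — pattern imputation with delta adjustment: deterministic
  replacement by the observed mean shifted by a chosen multiple of the
  observed SD, or by treatment-group observed means.  Used as a sensitivity
  analysis for departures from MAR.
* ``mice_impute`` — multiple imputation: Bayesian normal-linear regression of
  the outcome on complete predictors, one proper draw per imputation.  With a
  single incomplete variable the chained-equations cycle has exactly one step.
* ``rubin_pool`` — the standard combining rules for a scalar estimand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyDataError, ParameterError, SingularDesignError


@dataclass(frozen=True)
class PidaSpec:
    """How to fill the missing outcomes.

    ``shift``: fill value = observed mean + shift_sd * observed SD (shift_sd of
    -0.5 / +0.5 reproduce the half-SD-below / half-SD-above scenarios).
    ``group_mean``: fill with the observed mean of the subject's own group.
    """

    strategy: str = "shift"            # "shift" | "group_mean"
    shift_sd: float = 0.0
    group_col: str = "treat"

    def __post_init__(self) -> None:
        if self.strategy not in ("shift", "group_mean"):
            raise ParameterError(f"unknown PIDA strategy '{self.strategy}'")
        if not math.isfinite(self.shift_sd):
            raise ParameterError("shift_sd must be finite")


@dataclass
class PooledEstimate:
    """Rubin-pooled scalar estimate with within/between variance decomposition."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int

    def __post_init__(self) -> None:
        target = self.within_var + (1.0 + 1.0 / self.m) * self.between_var
        if abs(self.total_var - target) > 1e-10 * max(1.0, abs(target)):
            raise ParameterError("total_var must equal within + (1 + 1/m) * between")
        if self.between_var < 0:
            raise ParameterError("between_var must be >= 0")


def _observed(frame: pd.DataFrame, outcome: str) -> np.ndarray:
    y = frame[outcome].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    if obs.sum() == 0:
        raise EmptyDataError(f"no observed values in column '{outcome}'")
    return obs


def mean_impute(frame: pd.DataFrame, outcome: str = "bw_obs") -> pd.DataFrame:
    """Fill every missing outcome with the overall observed mean."""
    obs = _observed(frame, outcome)
    out = frame.copy()
    y = out[outcome].to_numpy(dtype=float)
    out[outcome] = np.where(obs, y, float(y[obs].mean()))
    return out


def pida_impute(
    frame: pd.DataFrame, spec: PidaSpec, outcome: str = "bw_obs"
) -> pd.DataFrame:
    """Deterministic pattern imputation with delta adjustment."""
    obs = _observed(frame, outcome)
    out = frame.copy()
    y = out[outcome].to_numpy(dtype=float)
    if spec.strategy == "shift":
        fill = float(y[obs].mean()) + spec.shift_sd * float(y[obs].std(ddof=1))
        out[outcome] = np.where(obs, y, fill)
        return out
    if spec.group_col not in out.columns:
        raise ParameterError(f"group column '{spec.group_col}' not in data")
    g = out[spec.group_col].to_numpy()
    filled = y.copy()
    for level in np.unique(g):
        in_g = g == level
        if not (obs & in_g).any():
            raise EmptyDataError(
                f"group {spec.group_col}={level} has no observed outcome values"
            )
        filled[in_g & ~obs] = float(y[obs & in_g].mean())
    out[outcome] = filled
    return out


def mice_impute(
    frame: pd.DataFrame,
    predictors: list[str],
    m: int,
    seed: int,
    outcome: str = "bw_obs",
) -> list[pd.DataFrame]:
    """Proper multiple imputation of a single incomplete outcome.

    For each of the m imputations, draw sigma^2 from the scaled inverse
    chi-square posterior of the observed-data regression (outcome on an
    intercept plus ``predictors``), draw coefficients from their conditional
    normal posterior, and fill each missing outcome with its linear prediction
    plus N(0, sigma) noise.  Deterministic given the seed.
    """
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    for c in predictors:
        if frame[c].isna().any():
            raise ParameterError(
                f"predictor column '{c}' has missing values; only the outcome may be missing"
            )
    obs = _observed(frame, outcome)
    y = frame[outcome].to_numpy(dtype=float)
    Xall = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in predictors]
    )
    Xo, yo = Xall[obs], y[obs]
    n_obs, k = Xo.shape
    XtX = Xo.T @ Xo
    if np.linalg.matrix_rank(XtX) < k:
        raise SingularDesignError(
            f"singular predictor matrix for imputation (predictors: {predictors})"
        )
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    rss = float(resid @ resid)
    nu = n_obs - k
    chol = np.linalg.cholesky(XtX_inv)
    Xm = Xall[~obs]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    completed: list[pd.DataFrame] = []
    for _ in range(m):
        if rss <= 0 or nu <= 0:
            sigma2 = 0.0
        else:
            sigma2 = rss / rng.chisquare(nu)
        beta_draw = beta_hat + math.sqrt(sigma2) * (chol @ rng.standard_normal(k))
        fill = Xm @ beta_draw + math.sqrt(sigma2) * rng.standard_normal(len(Xm))
        out = frame.copy()
        col = y.copy()
        col[~obs] = fill
        out[outcome] = col
        completed.append(out)
    return completed


def completed_to_long(completed: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack m completed datasets into one long frame with an ``imp`` column."""
    return pd.concat(
        [d.assign(imp=i) for i, d in enumerate(completed)], ignore_index=True
    )


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-imputation scalar estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ParameterError(f"pooling requires m >= 2 imputations, got {m}")
    if len(u) != m or not (np.isfinite(q).all() and np.isfinite(u).all()):
        raise ParameterError("estimates and variances must be finite and equal length")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        r = (1.0 + 1.0 / m) * between
        df = (m - 1) * (1.0 + within / r) ** 2
        tcrit = float(stats.t.ppf(0.975, df))
    else:
        df = math.inf
        tcrit = float(stats.norm.ppf(0.975))
    half = tcrit * math.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        within_var=within,
        between_var=between,
        total_var=total,
        df=df,
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )
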