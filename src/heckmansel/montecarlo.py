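"""Monte-Carlo replication engine: scenarios x estimators x replicates.

Each replicate draws a fresh cohort, applies the scenario's missingness
mechanism, runs every requested estimator of the treatment effect on birth
weight, and records the estimate with its 95% CI.  Summaries report mean, SD,
bias, RMSE and CI coverage against the configured true effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imputation
from .dgp import Cohort, SimParams, apply_mar, apply_mnar, calibrate_intercept, generate_complete
from .exceptions import EmptyDataError, ParameterError
from .heckman import heckman_fiml, heckman_two_step
from .linear_probit import ModelData, fit_ols

SCENARIOS = ("complete", "mar", "mnar")

X_COLS = ["treat"]
Z_COLS = ["treat", "distance"]


def model_data_from_cohort(frame: pd.DataFrame) -> ModelData:
    """Build the standard (y, X, s, Z) bundle from the cohort CSV schema."""
    return ModelData.from_frame(
        frame, outcome="bw_obs", select="selected", x_cols=X_COLS, z_cols=Z_COLS
    )


def _treat_record(fit) -> dict:
    return {
        "est": float(fit.coef["treat"]),
        "se": float(fit.se["treat"]),
        "ci_low": float(fit.ci_low["treat"]),
        "ci_high": float(fit.ci_high["treat"]),
        "converged": bool(fit.converged),
    }


def _est_ols_full(frame, params, seed, mice_m):
    data = ModelData.from_frame(frame, outcome="bw_true", x_cols=X_COLS, z_cols=Z_COLS)
    return _treat_record(fit_ols(data))


def _est_cca(frame, params, seed, mice_m):
    data = model_data_from_cohort(frame)
    return _treat_record(fit_ols(data, use_selected_only=True))


def _ols_on_filled(filled: pd.DataFrame):
    data = ModelData.from_frame(filled, outcome="bw_obs", x_cols=X_COLS, z_cols=Z_COLS)
    return fit_ols(data)


def _est_mean_imp(frame, params, seed, mice_m):
    return _treat_record(_ols_on_filled(imputation.mean_impute(frame)))


def _est_pida_group(frame, params, seed, mice_m):
    spec = imputation.PidaSpec(strategy="group_mean", group_col="treat")
    return _treat_record(_ols_on_filled(imputation.pida_impute(frame, spec)))


def _est_pida_minus(frame, params, seed, mice_m):
    spec = imputation.PidaSpec(strategy="shift", shift_sd=-0.5)
    return _treat_record(_ols_on_filled(imputation.pida_impute(frame, spec)))


def _est_pida_plus(frame, params, seed, mice_m):
    spec = imputation.PidaSpec(strategy="shift", shift_sd=+0.5)
    return _treat_record(_ols_on_filled(imputation.pida_impute(frame, spec)))


def _est_mice(frame, params, seed, mice_m):
    completed = imputation.mice_impute(
        frame, predictors=["treat", "distance"], m=mice_m, seed=seed
    )
    ests, vars_ = [], []
    for d in completed:
        fit = _ols_on_filled(d)
        ests.append(float(fit.coef["treat"]))
        vars_.append(float(fit.se["treat"]) ** 2)
    pooled = imputation.rubin_pool(ests, vars_)
    return {
        "est": pooled.estimate,
        "se": math.sqrt(pooled.total_var),
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "converged": True,
    }


def _heckman_record(fit) -> dict:
    est = float(fit.beta["treat"])
    se = float(fit.se["beta:treat"])
    return {
        "est": est,
        "se": se,
        "ci_low": est - 1.959963984540054 * se,
        "ci_high": est + 1.959963984540054 * se,
        "converged": bool(fit.converged),
    }


def _est_heckman_2s(frame, params, seed, mice_m):
    return _heckman_record(heckman_two_step(model_data_from_cohort(frame)))


def _est_heckman_fiml(frame, params, seed, mice_m):
    return _heckman_record(heckman_fiml(model_data_from_cohort(frame)))


ESTIMATORS = {
    "ols_full": _est_ols_full,
    "cca": _est_cca,
    "mean_imp": _est_mean_imp,
    "mice": _est_mice,
    "pida_group": _est_pida_group,
    "pida_minus": _est_pida_minus,
    "pida_plus": _est_pida_plus,
    "heckman_2s": _est_heckman_2s,
    "heckman_fiml": _est_heckman_fiml,
}


@dataclass
class McScenario:
    """One simulation condition: missingness regime, DGP parameters, estimators."""

    name: str
    params: SimParams
    estimators: list[str]
    reps: int = 200
    base_seed: int = 0
    mice_m: int = 25

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ParameterError(f"scenario must be one of {SCENARIOS}, got '{self.name}'")
        if self.reps < 1:
            raise ParameterError(f"reps must be >= 1, got {self.reps}")
        unknown = [e for e in self.estimators if e not in ESTIMATORS]
        if unknown:
            raise ParameterError(
                f"unknown estimators {unknown}; registered: {sorted(ESTIMATORS)}"
            )


@dataclass
class McSummary:
    """Per-estimator distribution of the treatment-effect estimate."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for _, row in self.table.iterrows():
            n = row["n_converged"]
            if n >= 2:
                target = row["bias"] ** 2 + row["sd_est"] ** 2 * (n - 1) / n
                if abs(row["rmse"] ** 2 - target) > 1e-6 * max(1.0, target):
                    raise ParameterError("rmse^2 must equal bias^2 + sd^2*(n-1)/n")
            if not 0.0 <= row["ci_coverage"] <= 1.0:
                raise ParameterError("ci_coverage must lie in [0, 1]")


def _rep_seed(base_seed: int, rep: int, purpose: int) -> int:
    """Counter-based derivation: independent 31-bit seed per (replicate, purpose)."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(rep), purpose))
    return int(ss.generate_state(1)[0] % (2**31))


def run_mc(scenario: McScenario) -> tuple[McSummary, pd.DataFrame]:
    """Run the replication study; returns the summary and the per-replicate table."""
    params = scenario.params
    if scenario.name == "mnar":
        params = calibrate_intercept(params)
    rows = []
    failures: dict[str, int] = {e: 0 for e in scenario.estimators}
    first_error: dict[str, str] = {}
    for rep in range(scenario.reps):
        gen_seed = _rep_seed(scenario.base_seed, rep, 0)
        miss_seed = _rep_seed(scenario.base_seed, rep, 1)
        est_seed = _rep_seed(scenario.base_seed, rep, 2)
        cohort = generate_complete(params, seed=gen_seed)
        if scenario.name == "mar":
            cohort = apply_mar(cohort, params.mar_rate, seed=miss_seed)
        elif scenario.name == "mnar":
            cohort = apply_mnar(cohort, params, seed=miss_seed)
        for est_name in scenario.estimators:
            rec = {
                "rep": rep,
                "scenario": scenario.name,
                "estimator": est_name,
                "est": np.nan,
                "se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "converged": False,
            }
            try:
                out = ESTIMATORS[est_name](cohort.frame, params, est_seed, scenario.mice_m)
                rec.update(out)
            except Exception as exc:
                failures[est_name] += 1
                first_error.setdefault(est_name, repr(exc))
            rows.append(rec)
    for est_name, nfail in failures.items():
        if nfail > 0.2 * scenario.reps:
            raise RuntimeError(
                f"estimator '{est_name}' failed on {nfail}/{scenario.reps} replicates "
                f"(> 20%); first error: {first_error.get(est_name)}"
            )
    table = pd.DataFrame(rows)
    summary = summarize(table, params.beta_treat)
    return summary, table


def summarize(table: pd.DataFrame, beta_treat: float) -> McSummary:
    """Reduce a per-replicate table to per-estimator bias/RMSE/coverage rows."""
    out = []
    for est_name, grp in table.groupby("estimator", sort=False):
        ok = grp[grp["converged"] & grp["est"].notna()]
        n = len(ok)
        if n == 0:
            out.append(
                {
                    "estimator": est_name,
                    "mean_est": np.nan,
                    "sd_est": np.nan,
                    "bias": np.nan,
                    "rmse": np.nan,
                    "ci_coverage": 0.0,
                    "n_converged": 0,
                }
            )
            continue
        est = ok["est"].to_numpy()
        mean_est = float(est.mean())
        sd_est = float(est.std(ddof=1)) if n > 1 else 0.0
        bias = mean_est - beta_treat
        rmse = float(np.sqrt(np.mean((est - beta_treat) ** 2)))
        cover = float(
            ((ok["ci_low"] <= beta_treat) & (beta_treat <= ok["ci_high"])).mean()
        )
        out.append(
            {
                "estimator": est_name,
                "mean_est": mean_est,
                "sd_est": sd_est,
                "bias": bias,
                "rmse": rmse,
                "ci_coverage": cover,
                "n_converged": n,
            }
        )
    return McSummary(table=pd.DataFrame(out).set_index("estimator"))


def summarize_panels(
    table: pd.DataFrame, beta_treat: float, out_path=None
):
    """One histogram panel per estimator x scenario, reference line at the true effect.

    Returns (figure, summary) where summary is the McSummary of the table.
    Also annotates the figure with the estimate-SD of each panel so the
    efficiency cost of the selection correction (its wider spread relative to
    complete-data OLS) is visible at a glance.
    """
    if len(table) == 0:
        raise EmptyDataError("empty per-replicate table")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = (
        table[["estimator", "scenario"]].drop_duplicates().itertuples(index=False)
    )
    pairs = [(p.estimator, p.scenario) for p in pairs]
    ncol = min(3, len(pairs))
    nrow = (len(pairs) + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False
    )
    for ax, (est_name, scen) in zip(axes.ravel(), pairs):
        sub = table[
            (table["estimator"] == est_name)
            & (table["scenario"] == scen)
            & table["converged"]
        ]
        vals = sub["est"].dropna().to_numpy()
        if len(vals):
            ax.hist(vals, bins=30, color="steelblue", alpha=0.8)
            ax.set_title(
                f"{est_name} / {scen}\nSD = {np.std(vals, ddof=1):.1f} g"
                if len(vals) > 1
                else f"{est_name} / {scen}"
            )
        ax.axvline(beta_treat, color="firebrick", linestyle="--")
        ax.set_xlabel("treatment estimate (g)")
    for ax in axes.ravel()[len(pairs):]:
        ax.set_visible(False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    summary = summarize(table, beta_treat)
    return fig, summary
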