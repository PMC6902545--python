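"""Synthetic birth-cohort generator.

Emulates a surveillance cohort with a continuous outcome (birth weight in
grams), a binary exposure (antenatal supplementation), an exclusion-restriction
covariate (household distance to the nearest facility, km), and a latent
confounder of observation (maternal health knowledge, standard-normal units).
Birth weight decomposes as

    bw = bw_mean + beta_treat * treat + knowledge_effect * knowledge + e,

with ``e`` normal with SD ``sqrt(bw_sd**2 - knowledge_effect**2)`` so that the
*total* SD of birth weight is ``bw_sd``.  Three observation regimes are
supported: complete data, missing-at-random (i.i.d. Bernoulli masking of the
outcome), and endogenous selection (missing-not-at-random), where the outcome
is observed iff a latent propensity

    s* = sel_alpha0 + sel_alpha_t * treat + sel_alpha_k * knowledge
         - sel_alpha_d * distance + eps,        eps ~ N(0, 1),

exceeds zero.  The selection noise ``eps`` is independent of the outcome noise
``e``; all cross-equation correlation flows through the latent knowledge, so
the composite errors of the two equations are exactly bivariate normal and the
classical sample-selection model is correctly specified.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .exceptions import CalibrationError, ParameterError

COHORT_COLUMNS = ("id", "treat", "distance", "knowledge", "bw_true", "selected", "bw_obs")

# Named RNG sub-streams derived from one master seed, so toggling a component
# (e.g. switching MAR for MNAR) does not perturb the draws of the others.
_STREAMS = {
    "treatment": 0,
    "distance": 1,
    "knowledge": 2,
    "outcome": 3,
    "selection": 4,
    "mar": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimParams:
    """All generator knobs; defaults are the study conditions of the simulation.

    Units: grams for the outcome-side parameters, km for distance, probit-index
    units (per SD of the standard-normal selection noise) for the ``sel_*``
    loadings.
    """

    n: int = 10_000
    beta_treat: float = 50.0          # g, causal effect of supplementation
    bw_mean: float = 3000.0           # g, untreated knowledge-average mean
    bw_sd: float = 500.0              # g, total SD of birth weight
    knowledge_effect: float = 100.0   # g per SD of latent health knowledge
    p_treat: float = 0.5              # supplementation probability
    mar_rate: float = 0.40            # fraction missing under MAR
    sel_alpha0: float = 0.0           # selection intercept (calibrated)
    sel_alpha_t: float = 1.0          # selection loading on treatment (>0: treated observed more)
    sel_alpha_k: float = 1.0          # selection loading on knowledge (sign fixed positive)
    sel_alpha_d: float = 0.25         # selection loading on distance, per km (entered negatively)
    dist_max: float = 10.0            # km, upper bound of the uniform distance
    target_obs_rate: float = 0.60     # observed fraction targeted under MNAR
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError(f"n must be >= 1, got {self.n}")
        if not self.knowledge_effect >= 0:
            raise ParameterError(
                f"knowledge_effect must be >= 0, got {self.knowledge_effect}"
            )
        if not self.bw_sd > self.knowledge_effect:
            raise ParameterError(
                "bw_sd must exceed knowledge_effect so the idiosyncratic SD "
                f"sqrt(bw_sd^2 - knowledge_effect^2) is real and positive; "
                f"got bw_sd={self.bw_sd}, knowledge_effect={self.knowledge_effect}"
            )
        if not 0.0 < self.mar_rate < 1.0:
            raise ParameterError(f"mar_rate must lie in (0, 1), got {self.mar_rate}")
        if not 0.0 < self.target_obs_rate < 1.0:
            raise ParameterError(
                f"target_obs_rate must lie in (0, 1), got {self.target_obs_rate}"
            )
        if not 0.0 <= self.p_treat <= 1.0:
            raise ParameterError(f"p_treat must lie in [0, 1], got {self.p_treat}")
        if self.sel_alpha_k < 0:
            raise ParameterError(
                "sel_alpha_k must be >= 0 (selection increases with knowledge), "
                f"got {self.sel_alpha_k}"
            )
        if self.sel_alpha_d < 0:
            raise ParameterError(
                "sel_alpha_d must be >= 0 (selection decreases with distance; the "
                f"loading enters negatively), got {self.sel_alpha_d}"
            )
        if not self.dist_max > 0:
            raise ParameterError(f"dist_max must be > 0, got {self.dist_max}")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    @property
    def idio_sd(self) -> float:
        """SD of the idiosyncratic outcome noise (g)."""
        return math.sqrt(self.bw_sd**2 - self.knowledge_effect**2)


@dataclass
class Cohort:
    """Per-subject simulated records, including latent fields kept for validation.

    ``knowledge`` is retained *only* so tests can verify the generator; no
    estimator in this package ever reads it.  ``bw_obs`` is NaN exactly where
    ``selected == 0``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ParameterError(f"cohort frame lacks columns: {missing}")
        masked = self.frame["bw_obs"].isna().to_numpy()
        unselected = (self.frame["selected"].to_numpy() == 0)
        if not np.array_equal(masked, unselected):
            raise ParameterError("bw_obs must be present iff selected == 1")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def observed_fraction(self) -> float:
        return float(self.frame["selected"].mean())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        frame = pd.read_csv(path)
        return cls(frame=frame[list(COHORT_COLUMNS)].copy())


def generate_complete(params: SimParams, seed: int | None = None) -> Cohort:
    """Draw a fully observed cohort; deterministic given the seed.

    Uses independent named sub-streams for treatment, distance, knowledge and
    outcome noise, all derived from one master seed (``params.seed`` unless
    overridden).
    """
    params.validate()
    master = params.seed if seed is None else int(seed)
    n = params.n
    treat = (_rng(master, "treatment").random(n) < params.p_treat).astype(np.int64)
    distance = _rng(master, "distance").uniform(0.0, params.dist_max, n)
    knowledge = _rng(master, "knowledge").standard_normal(n)
    e = _rng(master, "outcome").standard_normal(n) * params.idio_sd
    bw_true = (
        params.bw_mean
        + params.beta_treat * treat
        + params.knowledge_effect * knowledge
        + e
    )
    frame = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "treat": treat,
            "distance": distance,
            "knowledge": knowledge,
            "bw_true": bw_true,
            "selected": np.ones(n, dtype=np.int64),
            "bw_obs": bw_true.copy(),
        }
    )
    return Cohort(frame=frame)


def _require_complete(cohort: Cohort, op: str) -> None:
    if not bool((cohort.frame["selected"] == 1).all()):
        raise ParameterError(f"{op} requires a fully observed cohort")


def apply_mar(cohort: Cohort, mar_rate: float, seed: int) -> Cohort:
    """Mask the outcome independently with probability ``mar_rate`` (MAR)."""
    if not 0.0 < mar_rate < 1.0:
        raise ParameterError(f"mar_rate must lie in (0, 1), got {mar_rate}")
    _require_complete(cohort, "apply_mar")
    frame = cohort.frame.copy()
    u = _rng(int(seed), "mar").random(len(frame))
    selected = (u >= mar_rate).astype(np.int64)
    frame["selected"] = selected
    frame["bw_obs"] = np.where(selected == 1, frame["bw_true"], np.nan)
    return Cohort(frame=frame)


def apply_mnar(cohort: Cohort, params: SimParams, seed: int) -> Cohort:
    """Mask the outcome by thresholding the latent selection propensity (MNAR).

    selected = 1 iff  sel_alpha0 + sel_alpha_t*treat + sel_alpha_k*knowledge
    - sel_alpha_d*distance + eps > 0, with eps standard normal and independent
    of the outcome's idiosyncratic noise.
    """
    params.validate()
    _require_complete(cohort, "apply_mnar")
    frame = cohort.frame.copy()
    eps = _rng(int(seed), "selection").standard_normal(len(frame))
    s_star = (
        params.sel_alpha0
        + params.sel_alpha_t * frame["treat"].to_numpy()
        + params.sel_alpha_k * frame["knowledge"].to_numpy()
        - params.sel_alpha_d * frame["distance"].to_numpy()
        + eps
    )
    selected = (s_star > 0).astype(np.int64)
    frame["selected"] = selected
    frame["bw_obs"] = np.where(selected == 1, frame["bw_true"], np.nan)
    return Cohort(frame=frame)


def expected_obs_rate(params: SimParams, sel_alpha0: float | None = None) -> float:
    """Closed-form P(s* > 0) under the generator, by quadrature over distance.

    Marginalizing knowledge and the selection noise gives, per subject profile,
    Phi((a0 + a_t*t - a_d*d) / sqrt(1 + a_k^2)); the population rate averages
    this over t ~ Bernoulli(p_treat) and d ~ Uniform(0, dist_max) with 64-node
    Gauss-Legendre quadrature.
    """
    a0 = params.sel_alpha0 if sel_alpha0 is None else float(sel_alpha0)
    scale = math.sqrt(1.0 + params.sel_alpha_k**2)
    nodes, weights = np.polynomial.legendre.leggauss(64)
    d = 0.5 * params.dist_max * (nodes + 1.0)  # map [-1,1] -> [0, dist_max]
    w = weights / 2.0  # uniform density times Jacobian
    rate = 0.0
    for t, pt in ((0, 1.0 - params.p_treat), (1, params.p_treat)):
        if pt == 0.0:
            continue
        idx = (a0 + params.sel_alpha_t * t - params.sel_alpha_d * d) / scale
        rate += pt * float(np.sum(w * ndtr(idx)))
    return rate


def calibrate_intercept(params: SimParams) -> SimParams:
    """Set ``sel_alpha0`` by root-finding so P(s* > 0) = target_obs_rate."""
    params.validate()
    lo, hi = -40.0, 40.0
    r_lo = expected_obs_rate(params, lo)
    r_hi = expected_obs_rate(params, hi)
    target = params.target_obs_rate
    if not r_lo < target < r_hi:
        raise CalibrationError(
            f"target_obs_rate={target} is outside the achievable range "
            f"({r_lo:.6g}, {r_hi:.6g}) for the given selection loadings"
        )
    root = optimize.brentq(
        lambda a0: expected_obs_rate(params, a0) - target, lo, hi, xtol=1e-10
    )
    return params.replace(sel_alpha0=float(root))
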