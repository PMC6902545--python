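"""OLS/probit building blocks, marginal effects and the inverse Mills ratio."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from heckmansel import (
    ModelData,
    SimParams,
    fit_ols,
    fit_probit,
    generate_complete,
    inverse_mills,
    probit_margins,
)
from heckmansel.exceptions import (
    ConvergenceError,
    EmptyDataError,
    ParameterError,
    SingularDesignError,
)
from oracles import mills_highprec


def _data(y, X, s=None, Z=None):
    s = np.ones(len(y), dtype=int) if s is None else s
    Z = X if Z is None else Z
    return ModelData(y=y, X=X, s=s, Z=Z)


class TestFitOls:
    def test_exact_line(self):
        X = pd.DataFrame({"const": 1.0, "x": [1.0, 2.0, 3.0]})
        fit = fit_ols(_data(np.array([2.0, 4.0, 6.0]), X))
        assert abs(fit.coef["x"] - 2.0) < 1e-12
        assert abs(fit.coef["const"]) < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 2)), columns=["a", "b"])
        y = rng.standard_normal(6)
        fit = fit_ols(_data(y, X))
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(fit.coef.to_numpy() - ref)) < 1e-10

    def test_recovers_treatment_effect_on_complete_cohort(self):
        frame = generate_complete(SimParams(), seed=51).frame
        X = pd.DataFrame({"const": 1.0, "treat": frame["treat"].astype(float)})
        fit = fit_ols(_data(frame["bw_true"].to_numpy(), X))
        assert abs(fit.coef["treat"] - 50.0) < 3 * fit.se["treat"]

    def test_residuals_orthogonal_to_design(self, rng):
        n = 500
        X = pd.DataFrame(
            {"const": 1.0, "a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        y = rng.standard_normal(n)
        fit = fit_ols(_data(y, X))
        resid = y - X.to_numpy() @ fit.coef.to_numpy()
        assert np.max(np.abs(X.to_numpy().T @ resid)) < 1e-8 * n

    def test_collinear_column_named(self):
        X = pd.DataFrame({"const": 1.0, "x": [1.0, 2.0, 3.0], "x2": [2.0, 4.0, 6.0]})
        with pytest.raises(SingularDesignError, match="x"):
            fit_ols(_data(np.zeros(3), X))

    def test_no_usable_rows(self):
        X = pd.DataFrame({"const": [1.0, 1.0]})
        with pytest.raises(EmptyDataError):
            fit_ols(
                ModelData(
                    y=np.array([np.nan, np.nan]),
                    X=X,
                    s=np.array([0, 0]),
                    Z=X,
                ),
                use_selected_only=True,
            )


class TestFitProbit:
    def test_intercept_only_balanced(self):
        s = np.repeat([0, 1], 50)
        Z = pd.DataFrame({"const": np.ones(100)})
        fit = fit_probit(s, Z)
        assert abs(fit.coef["const"]) < 1e-6
        assert fit.converged

    def test_intercept_only_inverse_cdf(self):
        s = np.r_[np.zeros(16), np.ones(84)]
        Z = pd.DataFrame({"const": np.ones(100)})
        fit = fit_probit(s, Z)
        assert abs(fit.coef["const"] - norm.ppf(0.84)) < 1e-6

    def test_saturated_binary_reproduces_cell_rates(self):
        # cell success rates 0.5 (x=0) and 0.84 (x=1)
        x = np.repeat([0.0, 1.0], 100)
        s = np.r_[np.repeat([0, 1], 50), np.zeros(16), np.ones(84)].astype(int)
        Z = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_probit(s, Z)
        assert abs(fit.coef["const"]) < 1e-6
        assert abs(fit.coef["x"] - norm.ppf(0.84)) < 1e-6

    def test_perfect_separation_identified(self):
        x = np.linspace(-1, 1, 40)
        s = (x > 0).astype(int)
        Z = pd.DataFrame({"const": 1.0, "x": x})
        with pytest.raises(ConvergenceError, match="x"):
            fit_probit(s, Z)

    def test_degenerate_outcome(self):
        Z = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(EmptyDataError):
            fit_probit(np.ones(10, dtype=int), Z)

    def test_loglik_dominates_null_start(self, rng):
        n = 400
        Z = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        s = (rng.standard_normal(n) < 0.3 + 0.8 * Z["x"]).astype(int)
        fit = fit_probit(s, Z)
        ll_zero = float(np.sum(norm.logcdf((2 * s - 1) * 0.0)))
        assert fit.loglik >= ll_zero


class TestProbitMargins:
    @pytest.fixture()
    def cell_fit(self):
        x = np.repeat([0.0, 1.0], 100)
        s = np.r_[np.repeat([0, 1], 50), np.zeros(16), np.ones(84)].astype(int)
        Z = pd.DataFrame({"const": 1.0, "x": x})
        return fit_probit(s, Z), Z

    def test_binary_ame_is_cell_rate_difference(self, cell_fit):
        fit, Z = cell_fit
        me = probit_margins(fit, Z, "x")
        assert me.kind == "binary"
        assert abs(me.value - 0.34) < 1e-6
        assert -1 < me.value < 1

    def test_zero_coefficient_zero_effect(self):
        Z = pd.DataFrame({"const": np.ones(100), "x": np.r_[np.zeros(50), np.ones(50)]})
        s = np.tile([0, 1], 50)  # x unrelated to s
        fit = fit_probit(s, Z)
        fit.coef["x"] = 0.0
        me = probit_margins(fit, Z, "x")
        assert abs(me.value) < 1e-12

    def test_continuous_ame_matches_finite_difference(self, rng):
        n = 600
        Z = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        s = (rng.standard_normal(n) < 0.2 + 0.7 * Z["x"]).astype(int)
        fit = fit_probit(s, Z)
        me = probit_margins(fit, Z, "x")
        g = fit.coef.to_numpy()
        h = 1e-6

        def mean_p(shift):
            Zs = Z.copy()
            Zs["x"] = Zs["x"] + shift
            return float(norm.cdf(Zs.to_numpy() @ g).mean())

        fd = (mean_p(h) - mean_p(-h)) / (2 * h)
        assert abs(me.value - fd) < 1e-6

    def test_matches_statsmodels_margeff(self, rng):
        n = 500
        Z = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(n)})
        s = (rng.standard_normal(n) < 0.1 + 0.5 * Z["x"]).astype(int)
        fit = fit_probit(s, Z)
        me = probit_margins(fit, Z, "x")
        sm_res = sm.Probit(s, Z).fit(disp=0)
        sm_me = sm_res.get_margeff(at="overall")
        assert abs(me.value - float(sm_me.margeff[0])) < 1e-8
        assert abs(me.se - float(sm_me.margeff_se[0])) < 1e-6

    def test_unknown_column(self, cell_fit):
        fit, Z = cell_fit
        with pytest.raises(ParameterError):
            probit_margins(fit, Z, "nope")


class TestInverseMills:
    def test_at_zero(self):
        assert abs(inverse_mills(0.0) - math.sqrt(2 / math.pi)) < 1e-9

    @pytest.mark.parametrize("u", [-37.0, -30.0, -10.0, -1.0, 0.0, 1.0, 5.0, 37.0])
    def test_matches_high_precision_closed_form(self, u):
        ref = mills_highprec(u)
        got = inverse_mills(u)
        assert abs(got - ref) <= 1e-10 * max(1.0, abs(ref))

    def test_deep_tail_asymptote(self):
        val = inverse_mills(-37.0)
        assert math.isfinite(val)
        assert abs(val - 37.0) / 37.0 < 1e-3

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(min_value=-37.0, max_value=37.0))
    def test_positive_and_above_negated_argument(self, u):
        lam = inverse_mills(u)
        assert lam > 0.0
        assert lam > -u

    def test_strictly_decreasing_on_grid(self):
        grid = np.linspace(-37, 37, 5001)
        vals = inverse_mills(grid)
        assert np.all(np.diff(vals) < 0)


class TestModelData:
    def test_x_must_be_subset_of_z(self):
        X = pd.DataFrame({"const": [1.0, 1.0], "w": [0.0, 1.0]})
        Z = pd.DataFrame({"const": [1.0, 1.0]})
        with pytest.raises(ParameterError, match="subset"):
            ModelData(y=np.array([1.0, 2.0]), X=X, s=np.array([1, 1]), Z=Z)

    def test_missing_exclusion_restriction_warns(self, caplog):
        X = pd.DataFrame({"const": [1.0, 1.0, 1.0]})
        with caplog.at_level("WARNING", logger="heckmansel.linear_probit"):
            ModelData(y=np.array([1.0, 2.0, 3.0]), X=X, s=np.array([1, 1, 1]), Z=X)
        assert any("exclusion" in r.message for r in caplog.records)

    def test_presence_mask_must_match_selection(self):
        X = pd.DataFrame({"const": [1.0, 1.0]})
        with pytest.raises(ParameterError, match="present exactly"):
            ModelData(y=np.array([1.0, np.nan]), X=X, s=np.array([1, 1]), Z=X)
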