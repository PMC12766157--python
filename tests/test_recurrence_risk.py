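"""Post-recurrence survival, deconvolution, and MR risk algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrisk import (build_t2_survival, compose_cumulative, conditional_risk,
                   deconvolve_t1, mr_risk_curve, sensitivity_over_r)
from mrisk.recurrence_risk import (DeconvolutionResult, RecurrenceRiskCurve,
                                   convolve_survival, format_percent)

GRID = np.arange(0.0, 181.0, 1.0)
GRID_HALF = np.arange(0.0, 180.51, 0.5)


def _weibull_sf(t, median, shape):
    lam = np.log(2.0) ** (1.0 / shape) / median
    return np.exp(-((lam * np.asarray(t, float)) ** shape))


class TestBuildT2Survival:
    def test_r_one_is_identity(self):
        s = np.exp(-GRID / 30.0)
        model = build_t2_survival(GRID, s, 1.0)
        assert np.allclose(model.s2, s)

    def test_exponential_rate_scales_with_r(self):
        lam = 1 / 40.0
        s = np.exp(-lam * GRID)
        model = build_t2_survival(GRID, s, 1.33)
        assert np.allclose(model.s2, np.exp(-1.33 * lam * GRID))
        # median shrinks by 1/1.33
        med_idx = np.argmin(np.abs(model.s2 - 0.5))
        assert GRID[med_idx] == pytest.approx(np.log(2) / (1.33 * lam), abs=1.0)

    def test_r_is_reciprocal_of_published_hr(self):
        r = 1.0 / 0.75
        assert round(r, 2) == 1.33

    def test_nonpositive_r_fatal(self):
        with pytest.raises(ValueError, match="positive"):
            build_t2_survival(GRID, np.exp(-GRID / 30.0), 0.0)


class TestDeconvolution:
    def test_instant_death_t2_returns_s_star(self):
        # S2 is a step to 0: T2 ≡ 0, so S1 must equal S* exactly
        s_star = _weibull_sf(GRID, 40.0, 1.2)
        step = np.where(GRID_HALF <= 0, 1.0, 0.0)
        model = build_t2_survival(GRID_HALF, step, 1.0)
        res = deconvolve_t1(s_star, model, grid=GRID)
        assert np.max(np.abs(res.s1 - s_star)) < 1e-10
        assert res.residual < 1e-10

    def test_hypoexponential_closed_form(self):
        """T1 ~ Exp(1/20), T2 ~ Exp(1/10): recover e^{−t/20} to ≤ 0.01."""
        l1, l2 = 1 / 20.0, 1 / 10.0
        s_star = (l2 * np.exp(-l1 * GRID) - l1 * np.exp(-l2 * GRID)) / (l2 - l1)
        model = build_t2_survival(GRID_HALF, np.exp(-l2 * GRID_HALF), 1.0)
        res = deconvolve_t1(s_star, model, grid=GRID)
        assert np.max(np.abs(res.s1 - np.exp(-l1 * GRID))) <= 0.01
        assert not res.unstable

    def test_convolution_round_trip_20_random_draws(self):
        """Re-convolving the recovered S1 reproduces S* (residual ≤ 0.005)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            gam1, med1 = rng.uniform(0.8, 1.8), rng.uniform(15, 60)
            gam2, med2 = rng.uniform(1.0, 1.8), rng.uniform(10, 40)
            r = rng.uniform(1.0, 1.7)
            s2_base = 1.0 / (1.0 + (GRID_HALF / med2) ** gam2)  # log-logistic
            model = build_t2_survival(GRID_HALF, s2_base, r)
            s1_true = _weibull_sf(GRID, med1, gam1)
            s2_mid = model.s2_at(GRID[:-1] + 0.5)
            s_star = convolve_survival(s1_true, s2_mid)
            res = deconvolve_t1(s_star, model, grid=GRID)
            assert res.residual <= 0.005
            assert np.max(np.abs(res.s1 - s1_true)) <= 0.01

    def test_weibull_loglogistic_round_trip_tight(self):
        model = build_t2_survival(
            GRID_HALF, 1.0 / (1.0 + (GRID_HALF / 28.0) ** 1.4), 1.33)
        s1_true = _weibull_sf(GRID, 30.0, 1.3)
        s_star = convolve_survival(s1_true, model.s2_at(GRID[:-1] + 0.5))
        res = deconvolve_t1(s_star, model, grid=GRID)
        assert res.residual <= 0.005


def _curve(c=0.8, median=30.0, shape=1.2, r=1.33):
    return RecurrenceRiskCurve(stratum="x", r=r, grid=GRID,
                               s1=_weibull_sf(GRID, median, shape), c=c)


class TestRiskAlgebra:
    def test_cumulative_risk_limits(self):
        curve = _curve(c=0.8)
        assert curve.at(0.0) == 0.0
        # S1 ≈ 0 at the horizon → P → 1 − c
        assert curve.at(180.0) == pytest.approx(0.2, abs=0.002)
        assert np.all(np.diff(curve.cumulative) >= -1e-12)

    def test_pointwise_arithmetic(self):
        dec = DeconvolutionResult(grid=GRID, s1=np.full(len(GRID), 0.8),
                                  residual=0.0, unstable=False)
        dec.s1[0] = 1.0
        curve = mr_risk_curve(0.9, dec, r=1.33)
        assert curve.at(60.0) == pytest.approx(0.1 * 0.2)  # (1−c)(1−S1)

    def test_conditional_flat_interval_is_zero(self):
        curve = _curve()
        q = conditional_risk(curve, 178.0, 180.0)
        assert q == pytest.approx(0.0, abs=1e-4)

    def test_conditional_arithmetic(self):
        # P(5y) = 0.10, P(10y) = 0.19 → conditional = 0.10
        class P:
            grid = np.array([0.0, 60.0, 120.0])
            def at(self, t):
                return {0.0: 0.0, 60.0: 0.10, 120.0: 0.19}[t]
        assert conditional_risk(P(), 60.0, 120.0) == pytest.approx(0.10)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=0.95), min_size=1,
                    max_size=6))
    def test_compose_then_condition_is_identity(self, qs):
        cum = [compose_cumulative(qs[:k + 1]) for k in range(len(qs))]
        prev = 0.0
        for k, q in enumerate(qs):
            back = (cum[k] - prev) / (1.0 - prev)
            # machine precision up to the conditioning of the division
            assert back == pytest.approx(q, abs=1e-13 / (1.0 - prev))
            prev = cum[k]

    def test_compose_all_zero(self):
        assert compose_cumulative([0.0, 0.0, 0.0]) == 0.0


class TestPrintedConditionalTables:
    """Recomposing published 5-year conditional risks into cumulative risk."""

    @pytest.mark.parametrize("conds, printed_pct", [
        ((0.070, 0.040, 0.018), 12.3),   # stage I–III, 15–74, 2007–2017
        ((0.027, 0.027, 0.021), 7.3),    # stage I, 15–44, 2007–2017
        ((0.011, 0.012, 0.010), 3.3),    # stage I, 65–74, 2007–2017
        ((0.361, 0.202, 0.083), 53.2),   # stage III, 65–74, 2007–2017
    ])
    def test_fifteen_year_recomposition(self, conds, printed_pct):
        cum = compose_cumulative(conds)
        assert float(format_percent(cum)) == printed_pct


class TestSensitivity:
    def test_monotone_in_r_and_shrinking_with_horizon(self):
        s_star = _weibull_sf(GRID, 45.0, 1.3)
        s_iv = 1.0 / (1.0 + (GRID_HALF / 30.0) ** 1.2)
        sens = sensitivity_over_r(s_star, GRID_HALF, s_iv, c=0.7,
                                  r_grid=(1.00, 1.33, 1.50, 1.70),
                                  r_default=1.33, grid=GRID)
        # larger r → shorter T2 → later implied recurrence → lower early risk
        p5 = sens["P_60m"].to_numpy()
        assert np.all(np.diff(p5) < 0)
        # spread across r shrinks as the horizon grows
        spread = [sens[f"P_{t}m"].max() - sens[f"P_{t}m"].min()
                  for t in (60, 120, 180)]
        assert spread[0] > spread[1] >= spread[2]
        # the default-r row is its own reference
        row = sens[sens["r"] == 1.33].iloc[0]
        assert row["diff_60m"] == 0.0 and row["diff_180m"] == 0.0

    def test_risk_bounded_by_one_minus_c_for_all_r(self):
        s_star = _weibull_sf(GRID, 45.0, 1.3)
        s_iv = 1.0 / (1.0 + (GRID_HALF / 30.0) ** 1.2)
        c = 0.7
        for r in (1.00, 1.33, 1.50, 1.70):
            model = build_t2_survival(GRID_HALF, s_iv, r)
            res = deconvolve_t1(s_star, model, grid=GRID)
            curve = mr_risk_curve(c, res, r=r)
            assert np.all(np.diff(curve.cumulative) >= -1e-12)
            assert np.all(curve.cumulative <= 1.0 - c + 1e-12)


class TestFormatting:
    def test_percent_rounds_half_up(self):
        assert format_percent(0.1235) == "12.4"
        assert format_percent(0.12345, 2) == "12.35"
        assert format_percent(0.005) == "0.5"
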