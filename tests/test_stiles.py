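"""Quadratic-trend fit and the residual-outlier rupture rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisisrepair import (
    ConfigurationError,
    Course,
    InvalidInputError,
    StilesConfig,
    detect_stiles,
    fit_quadratic_course,
)

from oracles import stiles_condition_oracle


def fit_oracle_ols(values, residual_df="n-3"):
    """Independent normal-equations fit via statsmodels OLS."""
    import statsmodels.api as sm

    n = len(values)
    x = np.arange(1, n + 1) - (n + 1) / 2.0
    X = sm.add_constant(np.column_stack([x, x * x]))
    res = sm.OLS(np.asarray(values, float), X).fit()
    ssr = float(res.ssr)
    denom = n - 3 if residual_df == "n-3" else n
    return res.params[0], res.params[1], res.params[2], np.sqrt(ssr / denom)


class TestFit:
    def test_constant_course(self):
        fit = fit_quadratic_course(Course.from_values("c", [50.0] * 10))
        assert fit.midtreatment_intercept == pytest.approx(50.0)
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.curve == pytest.approx(0.0, abs=1e-10)
        assert fit.rmse == 0.0

    def test_exact_linear_data(self):
        n = 11
        mid = (n + 1) / 2
        vals = [3 + 2 * (s - mid) for s in range(1, n + 1)]
        fit = fit_quadratic_course(Course.from_values("c", vals))
        assert fit.midtreatment_intercept == pytest.approx(3.0, abs=1e-8)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.curve == pytest.approx(0.0, abs=1e-8)
        assert fit.rmse == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-50, 50),
        b=st.floats(-5, 5),
        c=st.floats(-1, 1),
        n=st.integers(4, 40),
    )
    def test_exact_quadratic_recovery(self, a, b, c, n):
        mid = (n + 1) / 2
        vals = [a + b * (s - mid) + c * (s - mid) ** 2 for s in range(1, n + 1)]
        fit = fit_quadratic_course(Course.from_values("q", vals))
        assert fit.midtreatment_intercept == pytest.approx(a, abs=1e-6)
        assert fit.slope == pytest.approx(b, abs=1e-7)
        assert fit.curve == pytest.approx(c, abs=1e-8)
        assert fit.rmse == 0.0

    @pytest.mark.parametrize("residual_df", ["n-3", "n"])
    def test_noisy_fit_matches_independent_ols(self, residual_df):
        rng = np.random.default_rng(42)
        vals = (100 + rng.normal(0, 20, 30)).tolist()
        fit = fit_quadratic_course(Course.from_values("c", vals), residual_df)
        b0, b1, b2, rmse = fit_oracle_ols(vals, residual_df)
        assert fit.midtreatment_intercept == pytest.approx(b0, abs=1e-8)
        assert fit.slope == pytest.approx(b1, abs=1e-8)
        assert fit.curve == pytest.approx(b2, abs=1e-8)
        assert fit.rmse == pytest.approx(rmse, abs=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_quadratic_course(Course.from_values("c", [1, 2, 3]))


class TestDetect:
    def test_strictly_increasing_course_has_no_ruptures(self):
        c = Course.from_values("c", list(range(40, 62, 2)))
        res = detect_stiles(c, fit_quadratic_course(c), StilesConfig.modified())
        assert res.rupture_sessions == ()
        assert not res.excluded

    def test_negative_slope_excluded_under_original(self):
        vals = [100 - 3 * s for s in range(12)]
        vals[6] -= 40  # a clear trough that would otherwise be a rupture
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        res = detect_stiles(c, fit, StilesConfig.original(absolute_floor=90.0))
        assert res.excluded
        assert res.exclusion_reason == "negative linear trend"
        modified = detect_stiles(c, fit, StilesConfig.modified())
        assert not modified.excluded

    def test_flat_course_with_single_trough(self):
        vals = [60.0] * 11
        vals[5] = 10.0  # session 6
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        res = detect_stiles(c, fit, StilesConfig.original(absolute_floor=50.0))
        assert res.rupture_sessions == (6,)
        fitted = [fit.predict(s, 11) for s in c.sessions]
        oracle, excl = stiles_condition_oracle(
            vals, fitted, fit.rmse, fit.slope, absolute_floor=50.0
        )
        assert not excl
        assert list(res.rupture_sessions) == oracle

    def test_missing_floor_is_configuration_error(self):
        c = Course.from_values("c", [60, 10, 60, 60, 60])
        fit = fit_quadratic_course(c)
        cfg = StilesConfig(require_floor=True)
        with pytest.raises(ConfigurationError):
            detect_stiles(c, fit, cfg)

    @settings(max_examples=150, deadline=None)
    @given(vals=st.lists(st.integers(0, 80).map(float), min_size=4, max_size=20))
    def test_scan_matches_condition_oracle(self, vals):
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        fitted = [fit.predict(s, len(vals)) for s in c.sessions]
        for cfg in (
            StilesConfig.original(absolute_floor=40.0),
            StilesConfig.modified(),
        ):
            res = detect_stiles(c, fit, cfg)
            oracle, excluded = stiles_condition_oracle(
                vals,
                fitted,
                fit.rmse,
                fit.slope,
                rmse_multiplier=cfg.rmse_multiplier,
                absolute_floor=cfg.absolute_floor,
                exclude_first_last=cfg.exclude_first_last,
                exclude_negative_slope=cfg.exclude_negative_slope,
                require_below_previous=cfg.require_below_previous,
            )
            assert res.excluded == excluded
            assert list(res.rupture_sessions) == oracle

    @settings(max_examples=100, deadline=None)
    @given(
        vals=st.lists(st.integers(0, 80).map(float), min_size=4, max_size=25),
        mults=st.tuples(st.floats(0.5, 2), st.floats(0.1, 2)),
    )
    def test_raising_multiplier_never_adds_ruptures(self, vals, mults):
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        lo, hi = min(mults), max(mults)
        low = detect_stiles(c, fit, StilesConfig.modified(rmse_multiplier=lo))
        high = detect_stiles(c, fit, StilesConfig.modified(rmse_multiplier=hi))
        assert set(high.rupture_sessions) <= set(low.rupture_sessions)

    @settings(max_examples=100, deadline=None)
    @given(vals=st.lists(st.integers(0, 80).map(float), min_size=4, max_size=25))
    def test_first_and_last_sessions_never_rupture_under_original(self, vals):
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        res = detect_stiles(c, fit, StilesConfig.original(absolute_floor=100.0))
        if not res.excluded:
            assert 1 not in res.rupture_sessions
            assert len(vals) not in res.rupture_sessions

    @settings(max_examples=100, deadline=None)
    @given(vals=st.lists(st.integers(50, 80).map(float), min_size=4, max_size=25))
    def test_floor_suppresses_ruptures_in_high_courses(self, vals):
        # every value above the floor: no ruptures regardless of shape
        c = Course.from_values("c", vals)
        fit = fit_quadratic_course(c)
        res = detect_stiles(c, fit, StilesConfig.original(absolute_floor=40.0))
        if not res.excluded:
            assert res.rupture_sessions == ()
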