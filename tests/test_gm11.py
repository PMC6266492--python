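"""GM(1,1): AGO, background values, least-squares fit, forecasts, grading."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecofoot import (
    DomainError,
    GreySeries,
    accuracy_report,
    ago,
    background_sequence,
    fit_gm11,
    forecast,
    generate_exact_gm_series,
    iago,
)

# the study's five-year demand and supply per-capita series (hm²/person)
EF_SERIES = GreySeries.from_arrays(
    range(2013, 2018), [1.5270, 1.4782, 2.3897, 1.9143, 1.2611]
)
EC_SERIES = GreySeries.from_arrays(
    range(2013, 2018), [0.3478, 0.3795, 0.4084, 0.3902, 0.3595]
)


class TestAgo:
    def test_cumulative_sum(self):
        np.testing.assert_allclose(
            ago(EF_SERIES.values),
            [1.5270, 3.0052, 5.3949, 7.3092, 8.5703],
        )

    def test_singleton(self):
        np.testing.assert_array_equal(ago([3.5]), [3.5])

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            ago([])

    @given(st.lists(st.floats(min_value=0.01, max_value=1e3),
                    min_size=1, max_size=20))
    def test_iago_round_trip(self, values):
        np.testing.assert_allclose(iago(ago(values)), values, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=1e3),
                    min_size=2, max_size=20))
    def test_strictly_increasing_for_positive_input(self, values):
        assert np.all(np.diff(ago(values)) > 0)


class TestBackgroundSequence:
    def test_half_sums(self):
        np.testing.assert_allclose(
            background_sequence(ago(EF_SERIES.values)),
            [2.2661, 4.20005, 6.35205, 7.93975],
        )

    def test_weight_one_returns_later_values(self):
        cum = ago(EF_SERIES.values)
        np.testing.assert_array_equal(
            background_sequence(cum, weight=1.0), cum[1:]
        )

    def test_midpoint(self):
        np.testing.assert_array_equal(
            background_sequence([1.0, 3.0], weight=0.5), [2.0]
        )

    def test_weight_out_of_range(self):
        with pytest.raises(DomainError):
            background_sequence([1.0, 2.0], weight=1.5)


class TestFit:
    def test_demand_series_coefficients(self):
        fit = fit_gm11(EF_SERIES)
        assert fit.a == pytest.approx(0.0537948, rel=1e-3)
        assert fit.asymptote == pytest.approx(37.922, rel=1e-3)
        assert fit.amplitude == pytest.approx(-36.395, rel=1e-3)

    def test_supply_series_coefficients(self):
        fit = fit_gm11(EC_SERIES)
        assert fit.a == pytest.approx(0.0197318, rel=1e-3)
        assert fit.asymptote == pytest.approx(20.6091, rel=1e-3)
        assert fit.amplitude == pytest.approx(-20.2613, rel=1e-3)

    def test_initial_condition_anchoring(self):
        fit = fit_gm11(EF_SERIES)
        assert fit.fitted_cumulative[0] == pytest.approx(
            fit.initial_value, abs=1e-12
        )
        assert fit.restored[0] == fit.initial_value

    def test_restored_is_differenced_cumulative(self):
        fit = fit_gm11(EF_SERIES)
        np.testing.assert_allclose(
            fit.restored[1:], np.diff(fit.fitted_cumulative), rtol=1e-12
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(DomainError):
            fit_gm11(GreySeries.from_arrays([1, 2, 3], [1.0, 2.0, 3.0]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DomainError):
            fit_gm11(GreySeries.from_arrays(range(4), [1.0, 0.0, 1.0, 1.0]))

    def test_mean_relative_error_matches_closed_form(self):
        """MRE equals a brute-force evaluation of the time response."""
        fit = fit_gm11(EF_SERIES)
        a, u, x1 = fit.a, fit.u, EF_SERIES.values[0]
        errs = []
        for k in range(2, 6):
            x1hat_k = (x1 - u / a) * math.exp(-a * (k - 1)) + u / a
            x1hat_km1 = (x1 - u / a) * math.exp(-a * (k - 2)) + u / a
            restored = x1hat_k - x1hat_km1
            obs = EF_SERIES.values[k - 1]
            errs.append(abs(obs - restored) / obs)
        assert fit.mean_relative_error == pytest.approx(
            sum(errs) / len(errs), rel=1e-12
        )

    def test_oracle_equivalence_with_generic_minimizer(self):
        """Normal equations agree with a generic least-squares minimizer."""
        from scipy.optimize import least_squares

        for series in (EF_SERIES, EC_SERIES):
            x = np.asarray(series.values)
            z = background_sequence(ago(x))
            sol = least_squares(
                lambda p: x[1:] + p[0] * z - p[1],
                x0=[0.0, float(x.mean())],
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            fit = fit_gm11(series)
            assert fit.a == pytest.approx(sol.x[0], rel=1e-8)
            assert fit.u == pytest.approx(sol.x[1], rel=1e-8)


@given(
    a=st.floats(min_value=-0.5, max_value=0.5),
    u=st.floats(min_value=0.1, max_value=100.0),
    n=st.integers(min_value=4, max_value=20),
)
def test_exact_parameter_recovery(a, u, n):
    """Series built from the discrete grey recursion return (a, u) exactly."""
    try:
        series = generate_exact_gm_series(a, u, initial_value=u, n=n)
    except DomainError:
        return  # parameters drive the series nonpositive; nothing to fit
    fit = fit_gm11(series)
    assert fit.a == pytest.approx(a, abs=1e-10, rel=1e-10)
    assert fit.u == pytest.approx(u, abs=1e-10, rel=1e-10)


@given(
    c=st.floats(min_value=0.01, max_value=100.0),
)
def test_scale_equivariance(c):
    """fit(c·x).a == fit(x).a and fit(c·x).u == c·fit(x).u."""
    base = fit_gm11(EF_SERIES)
    scaled = fit_gm11(
        GreySeries.from_arrays(
            EF_SERIES.labels, [c * v for v in EF_SERIES.values]
        )
    )
    assert scaled.a == pytest.approx(base.a, rel=1e-9)
    assert scaled.u == pytest.approx(c * base.u, rel=1e-9)


class TestForecast:
    def test_demand_one_step(self):
        fit = fit_gm11(EF_SERIES)
        assert forecast(fit, 1)[0] == pytest.approx(1.5371, abs=1e-4)

    def test_supply_one_step(self):
        fit = fit_gm11(EC_SERIES)
        assert forecast(fit, 1)[0] == pytest.approx(0.3658, abs=1e-4)

    def test_geometric_decay_when_a_positive(self):
        fit = fit_gm11(EF_SERIES)
        values = forecast(fit, 6)
        ratios = values[1:] / values[:-1]
        np.testing.assert_allclose(ratios, math.exp(-fit.a), rtol=1e-10)
        assert np.all(np.diff(values) < 0)

    def test_invalid_steps(self):
        with pytest.raises(DomainError):
            forecast(fit_gm11(EF_SERIES), 0)

    def test_degenerate_constant_branch(self):
        series = generate_exact_gm_series(0.0, 2.0, initial_value=2.0, n=5)
        np.testing.assert_array_equal(series.values, [2.0] * 5)
        fit = fit_gm11(series)
        assert fit.degenerate
        np.testing.assert_allclose(forecast(fit, 3), [2.0, 2.0, 2.0])


class TestAccuracyReport:
    def test_exact_series_scores_top_grade(self):
        # (a, u) are recovered exactly; the restored values differ from the
        # discrete recursion only by the continuous-time discretisation gap,
        # so the mean relative error is far below the top-grade bound
        fit = fit_gm11(generate_exact_gm_series(0.1, 1.0, 1.5, 6))
        rep = accuracy_report(fit)
        assert rep.mean_relative_error < 1e-3
        assert rep.grade == "excellent"

    def test_constant_series_scores_zero_error(self):
        fit = fit_gm11(generate_exact_gm_series(0.0, 2.0, 2.0, 5))
        rep = accuracy_report(fit)
        assert rep.mean_relative_error == pytest.approx(0.0, abs=1e-12)
        assert rep.grade == "excellent"

    def test_boundary_is_inclusive(self):
        """An MRE exactly at a threshold earns the better grade."""
        fit = fit_gm11(EF_SERIES)
        for bound, name in [(0.01, "excellent"), (0.03, "good")]:
            rep = accuracy_report(fit, thresholds=((bound, name),))
            expected = name if fit.mean_relative_error <= bound \
                else "unqualified"
            assert rep.grade == expected
        rep = accuracy_report(
            fit, thresholds=((fit.mean_relative_error, "boundary"),)
        )
        assert rep.grade == "boundary"

    def test_supply_fit_grade(self):
        rep = accuracy_report(fit_gm11(EC_SERIES))
        # one-step mean relative error just under 4% -> qualified
        assert rep.grade == "qualified"
        assert len(rep.relative_errors) == 4
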