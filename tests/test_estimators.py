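import numpy as np
import pandas as pd
import pytest

from conftest import exact_update_frame, make_frame
from sensbias.cohort import CohortConfig
from sensbias.estimators import (
    BiasEstimates,
    FitError,
    IncompleteSeriesError,
    LinearFit,
    decompose,
    enhancement_bias,
    fit_sensitivity,
    fit_sensitivity_mixed,
    sensitivity_bias_theoretical,
    total_bias,
)
from sensbias.model import SensitivityCurve, avg_pair_bias

ANCHORS = np.arange(20, 81)
CURVE = SensitivityCurve(b=0.65, c=-0.15)


@pytest.fixture(scope="module")
def exact_frame():
    return exact_update_frame(CURVE, CURVE, ANCHORS)


def make_fit(slope, intercept, scope="all", n=100):
    return LinearFit(slope=slope, intercept=intercept, p_slope=0.5, n=n, feedback_scope=scope)


class TestFitSensitivity:
    def test_noiseless_recovery(self, exact_frame):
        fit = fit_sensitivity(exact_frame)
        assert fit.slope == pytest.approx(-0.15, abs=1e-9)
        assert fit.intercept == pytest.approx(0.65, abs=1e-9)
        assert fit.n == len(exact_frame)

    def test_noiseless_recovery_scoped(self, exact_frame):
        for scope in ("positive", "negative"):
            fit = fit_sensitivity(exact_frame, scope)
            assert fit.slope == pytest.approx(-0.15, abs=1e-9)
            assert fit.feedback_scope == scope

    def test_zero_sensitivity(self):
        df = exact_update_frame(SensitivityCurve(b=0.0), SensitivityCurve(b=0.0), ANCHORS)
        fit = fit_sensitivity(df)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_scope_partition(self, small_frame):
        n_all = fit_sensitivity(small_frame).n
        n_p = fit_sensitivity(small_frame, "positive").n
        n_n = fit_sensitivity(small_frame, "negative").n
        assert n_p + n_n == n_all

    def test_noisy_recovery_mean_over_seeds(self):
        # parameter-recovery oracle at reduced scale; the full-size version
        # lives in the acceptance suite
        slopes = [
            fit_sensitivity(
                make_frame(
                    CohortConfig(n_participants=400, seed=s, c_p=-0.12, c_n=-0.12,
                                 group_offsets={})
                )
            ).slope
            for s in range(8)
        ]
        assert np.mean(slopes) == pytest.approx(-0.12, abs=0.03)

    def test_too_few_rows(self, exact_frame):
        with pytest.raises(FitError):
            fit_sensitivity(exact_frame.iloc[:2])

    def test_zero_predictor_variance(self):
        df = exact_update_frame(CURVE, CURVE, [50, 50, 50]).query("t == 1")
        with pytest.raises(FitError):
            fit_sensitivity(df)

    def test_p_value_two_sided_range(self, small_frame):
        fit = fit_sensitivity(small_frame)
        assert 0.0 <= fit.p_slope <= 1.0


class TestFitSensitivityMixed:
    def test_degenerate_random_effect_equals_ols(self):
        # residuals sum to zero within every participant: the ML estimate of
        # the between-participant variance sits at the boundary, so the
        # fixed-effect slope must coincide with OLS
        rng = np.random.default_rng(0)
        rows = []
        for pid in range(1, 41):
            a = rng.uniform(20, 80, size=4)
            resid = rng.normal(0, 0.05, size=4)
            resid -= resid.mean()
            y = 0.65 - 0.15 * a / 100.0 + resid
            for t in range(1, 5):
                rows.append(dict(participant_id=pid, t=t, a_t=a[t - 1],
                                 f_t=a[t - 1] + 13, a_next=a[t - 1] + y[t - 1] * 13,
                                 delta_t=13.0, sign=1))
        df = pd.DataFrame(rows)
        ols = fit_sensitivity(df)
        mixed = fit_sensitivity_mixed(df)
        assert mixed.slope == pytest.approx(ols.slope, abs=1e-6)
        assert mixed.p_slope is None

    def test_recovery_with_participant_intercepts(self):
        frame = make_frame(
            CohortConfig(n_participants=800, seed=4, c_p=-0.12, c_n=-0.12,
                         participant_b_sd=0.1, group_offsets={})
        )
        fit = fit_sensitivity_mixed(frame)
        assert fit.slope == pytest.approx(-0.12, abs=0.04)

    def test_close_to_ols_on_trust_coupled_data(self):
        frame = make_frame(
            CohortConfig(n_participants=600, seed=9, c_p=0.0, c_n=0.0,
                         trust_slope_coupling=0.2, group_offsets={})
        )
        assert abs(fit_sensitivity_mixed(frame).slope - fit_sensitivity(frame).slope) <= 0.02

    def test_applicability_error_under_three_steps(self, exact_frame):
        with pytest.raises(FitError):
            fit_sensitivity_mixed(exact_frame[exact_frame["t"] <= 2])


class TestTotalBias:
    def test_single_participant_arithmetic(self):
        rows = []
        a_vals = [50.0, 50.13, 50.26, 50.39]
        deltas = [12, 14, 12, 14]
        for t in range(1, 5):
            a = a_vals[t - 1]
            a_next = a + 0.13
            rows.append(dict(participant_id=1, t=t, a_t=a, f_t=a + deltas[t - 1],
                             a_next=a_next, delta_t=deltas[t - 1], sign=1))
        df = pd.DataFrame(rows)
        # a5 - a1 = 0.52, half-sum of intensities = 26 -> 2.0 percent
        assert total_bias(df) == pytest.approx(2.0)

    def test_zero_when_everyone_returns(self):
        df = exact_update_frame(SensitivityCurve(b=0.6), SensitivityCurve(b=0.6), ANCHORS)
        assert total_bias(df) == pytest.approx(0.0, abs=1e-9)

    def test_incomplete_series_error_names_participants(self, exact_frame):
        chopped = exact_frame[~((exact_frame["participant_id"] == 3) & (exact_frame["t"] == 4))]
        with pytest.raises(IncompleteSeriesError, match="3"):
            total_bias(chopped)

    def test_close_to_theory_on_noiseless_symmetric_frame(self, exact_frame):
        fp = fit_sensitivity(exact_frame, "positive")
        fn = fit_sensitivity(exact_frame, "negative")
        B = total_bias(exact_frame)
        S_prime = sensitivity_bias_theoretical(exact_frame, fp, fn)
        assert B == pytest.approx(S_prime, rel=0.15)

    def test_theory_gap_shrinks_linearly_in_delta(self):
        def rel_gap(delta):
            df = exact_update_frame(CURVE, CURVE, ANCHORS, delta=delta)
            fp = fit_sensitivity(df, "positive")
            fn = fit_sensitivity(df, "negative")
            B = total_bias(df)
            return abs(B - sensitivity_bias_theoretical(df, fp, fn)) / B

        assert rel_gap(13.0) / rel_gap(6.5) == pytest.approx(2.0, rel=0.25)


class TestEnhancementBias:
    def test_equal_fits_zero(self, exact_frame):
        fit = make_fit(-0.1, 0.6)
        assert enhancement_bias(exact_frame, fit, fit) == 0.0

    def test_crossing_at_mean(self):
        df = pd.DataFrame(
            dict(participant_id=[1], t=[1], a_t=[50.0], f_t=[63.0], a_next=[56.0],
                 delta_t=[13.0], sign=[1])
        )
        # (0.2 * 0.5) + (-0.1) = 0
        assert enhancement_bias(df, make_fit(0.2, 0.1), make_fit(0.0, 0.2)) == pytest.approx(0.0)

    def test_uniform_gap_recovered_from_generator(self):
        frame = make_frame(
            CohortConfig(n_participants=600, seed=13, b_p=0.675, b_n=0.625,
                         c_p=-0.12, c_n=-0.12, group_offsets={})
        )
        fp = fit_sensitivity(frame, "positive")
        fn = fit_sensitivity(frame, "negative")
        assert enhancement_bias(frame, fp, fn) == pytest.approx(5.0, abs=1.5)


class TestSensitivityBiasTheoretical:
    def test_single_triple_value(self):
        df = pd.DataFrame(
            dict(participant_id=[1], t=[1], a_t=[50.0], f_t=[63.0], a_next=[56.0],
                 delta_t=[13.0], sign=[1])
        )
        # c_m = -0.1, b_m = 0.55: 0.1 * 0.5 * 13 = 0.65
        fit_p = make_fit(-0.1, 0.55)
        fit_n = make_fit(-0.1, 0.55)
        assert sensitivity_bias_theoretical(df, fit_p, fit_n) == pytest.approx(0.65)

    def test_zero_slope_zero(self, exact_frame):
        assert sensitivity_bias_theoretical(exact_frame, make_fit(0, 0.5), make_fit(0, 0.7)) == 0.0

    def test_matches_model_core_pair_bias(self, exact_frame):
        # cross-module oracle: per-triple mean of avg_pair_bias * 100/delta
        fit_p = make_fit(-0.2, 0.7)
        fit_n = make_fit(-0.1, 0.6)
        curve_p = SensitivityCurve(b=0.7, c=-0.2)
        curve_n = SensitivityCurve(b=0.6, c=-0.1)
        expected = np.mean(
            [
                avg_pair_bias(row.a_t, curve_p, curve_n, row.delta_t).raw_change
                * 100.0 / row.delta_t
                for row in exact_frame.itertuples()
            ]
        )
        got = sensitivity_bias_theoretical(exact_frame, fit_p, fit_n)
        assert got == pytest.approx(expected, rel=1e-9)


class TestDecompose:
    def test_constant_equal_curves_all_zero(self):
        df = exact_update_frame(SensitivityCurve(b=0.6), SensitivityCurve(b=0.6), ANCHORS)
        est = decompose(df)
        for value in (est.B, est.E, est.S_measured, est.S_theoretical):
            assert value == pytest.approx(0.0, abs=1e-9)

    def test_identity_holds_exactly(self, small_frame):
        from sensbias.data import SelectionCriteria, subset

        complete = subset(small_frame, SelectionCriteria(require_complete_series=True))
        est = decompose(complete)
        assert est.S_measured == est.B - est.E
        assert est.units_note == "percent of delta"

    def test_symmetric_noiseless(self, exact_frame):
        est = decompose(exact_frame)
        assert est.E == pytest.approx(0.0, abs=1e-9)
        assert est.S_measured == pytest.approx(est.S_theoretical, rel=0.15)
        assert est.S_measured > 0 and est.S_theoretical > 0

    def test_trust_gradient_direction(self):
        frame = make_frame(
            CohortConfig(n_participants=1200, seed=17, c_p=0.0, c_n=0.0, b_p=0.65,
                         b_n=0.65, trust_slope_coupling=0.3, response_noise_sd=0.1,
                         group_offsets={})
        )
        from sensbias.data import SelectionCriteria, subset

        values = []
        for trust in [(0, 6), (7, 10), (9, 10)]:
            sub = subset(frame, SelectionCriteria(trust_range=trust,
                                                  require_complete_series=True))
            values.append(decompose(sub).S_theoretical)
        assert values[0] < values[1] < values[2]
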