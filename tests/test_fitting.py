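"""Curve containers, goodness statistics, and the four fitting routes."""

import io
import math

import numpy as np
import pytest

from umasurv import (
    MixtureParams,
    SurvivalCurve,
    UMAParams,
    fit_lq,
    fit_mt,
    fit_uma,
    fit_uma_mixture,
    goodness_stats,
    uma_survival,
)
from umasurv.fitting import FitResult, FittingError


def exact_curve(params, doses):
    return SurvivalCurve.from_model(params, doses)


class TestSurvivalCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            SurvivalCurve((1.0, 1.0), ((0.5,), (0.4,)))  # non-increasing doses
        with pytest.raises(ValueError):
            SurvivalCurve((0.0, 2.0), ((1.0,), (1.5,)))  # survival > 1
        with pytest.raises(ValueError):
            SurvivalCurve((0.0, 2.0), ((0.9,), (0.5,)))  # zero dose not normalised

    def test_zero_dose_anchor_auto_inserted(self):
        c = SurvivalCurve.from_points([(2.0, (0.5, 0.6)), (4.0, (0.2,))])
        assert c.doses[0] == 0.0
        assert c.means[0] == 1.0
        assert math.isnan(c.sds[0])

    def test_means_and_sample_sds(self):
        c = SurvivalCurve.from_points([(2.0, (0.4, 0.5, 0.6))])
        assert c.means[1] == pytest.approx(0.5)
        assert c.sds[1] == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1))

    def test_csv_replicate_dialect_roundtrip(self):
        c = SurvivalCurve.from_points([(2.0, (0.4, 0.5)), (5.0, (0.1,))])
        text = c.to_csv()
        c2 = SurvivalCurve.from_csv(io.StringIO(text))
        assert c2.doses == c.doses
        assert c2.replicates == c.replicates

    def test_csv_mean_sd_dialect_preserves_moments(self):
        text = "dose_gy,mean,sd\n0,1.0,\n2,0.5,0.05\n5,0.1,0.02\n"
        c = SurvivalCurve.from_csv(io.StringIO(text))
        assert c.means[1] == pytest.approx(0.5)
        assert c.sds[1] == pytest.approx(0.05)
        assert c.sds[2] == pytest.approx(0.02)

    def test_csv_requires_dose_column(self):
        with pytest.raises(ValueError, match="dose_gy"):
            SurvivalCurve.from_csv(io.StringIO("gy,rep1\n1,0.5\n"))


class TestGoodnessStats:
    def test_perfect_fit(self):
        c = SurvivalCurve.from_points([(2.0, (0.5,)), (5.0, (0.1,))])
        st = goodness_stats(c, c.means)
        assert st.r2 == 1.0 and st.rss == 0.0 and st.r == 0.0

    def test_three_point_hand_arithmetic(self):
        # S = (1, 0.5, 0.1) vs fitted (1, 0.4, 0.12):
        # RSS = 0.01 + 0.0004 = 0.0104; r = (0 + 0.2 + 0.2)/3
        c = SurvivalCurve.from_points([(0.0, (1.0,)), (2.0, (0.5,)), (5.0, (0.1,))])
        st = goodness_stats(c, [1.0, 0.4, 0.12])
        assert st.rss == pytest.approx(0.0104, rel=1e-12)
        assert st.r == pytest.approx(0.4 / 3, rel=1e-12)
        mean = (1.0 + 0.5 + 0.1) / 3
        sss = (1 - mean) ** 2 + (0.5 - mean) ** 2 + (0.1 - mean) ** 2
        assert st.sss == pytest.approx(sss, rel=1e-12)
        assert st.r2 == pytest.approx(1 - 0.0104 / sss, rel=1e-12)

    def test_relative_experimental_error_over_points_with_sd(self):
        c = SurvivalCurve.from_points(
            [(0.0, (1.0,)), (2.0, (0.45, 0.55)), (5.0, (0.1,))]
        )
        st = goodness_stats(c, c.means)
        sd = np.std([0.45, 0.55], ddof=1)
        assert st.e == pytest.approx(sd / 0.5)  # only the replicated point counts

    def test_r2_undefined_when_all_means_equal(self):
        c = SurvivalCurve((1.0, 2.0), ((0.5,), (0.5,)))
        assert math.isnan(goodness_stats(c, [0.5, 0.5]).r2)

    def test_good_fit_criterion(self):
        c = SurvivalCurve.from_points([(2.0, (0.45, 0.55)), (5.0, (0.09, 0.11))])
        st = goodness_stats(c, c.means)
        assert st.is_good  # r = 0 < e, R2 = 1


class TestFitUMA:
    @pytest.mark.parametrize(
        "d0,n",
        [(1.5, 5.0), (0.5, 0.2), (2.55, 0.2), (7.0, 60.0), (3.0, 1.7), (1.0, 11.7)],
    )
    def test_exact_recovery_on_noiseless_data(self, d0, n):
        curve = exact_curve(UMAParams(d0, n), np.arange(0.0, 13.0))
        fit = fit_uma(curve)
        assert fit.params.d0 == pytest.approx(d0, rel=1e-6)
        assert fit.params.n == pytest.approx(n, rel=1e-6)
        assert fit.stats.r < 1e-8
        assert fit.stats.r2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_exponential_data(self):
        curve = exact_curve(UMAParams(2.8, 1.0), np.arange(0.0, 13.0))
        fit = fit_uma(curve)
        assert fit.params.n == pytest.approx(1.0, abs=1e-3)
        assert fit.params.d0 == pytest.approx(2.8, abs=1e-3)

    def test_linearisation_identity_on_exact_data(self):
        # y = ln(n/S + 1 - n) = D/D0 at every point of exact model data
        d0, n = 2.2, 2.8
        doses = np.arange(0.0, 13.0)
        s = np.array([uma_survival(UMAParams(d0, n), d) for d in doses])
        y = np.log(n / s + 1 - n)
        assert np.allclose(y, doses / d0, rtol=1e-10, atol=1e-12)

    def test_reported_stats_self_consistent(self):
        curve = SurvivalCurve.from_points(
            [(1.0, (0.8, 0.9)), (3.0, (0.4, 0.5)), (6.0, (0.1, 0.12)), (9.0, (0.02, 0.03))]
        )
        fit = fit_uma(curve)
        st = goodness_stats(curve, fit.fitted)
        assert fit.stats.r2 == pytest.approx(st.r2, rel=1e-12)
        assert fit.stats.r == pytest.approx(st.r, rel=1e-12)
        assert fit.stats.e == pytest.approx(st.e, rel=1e-12)

    def test_deterministic(self):
        curve = SurvivalCurve.from_points(
            [(1.0, (0.85,)), (3.0, (0.45,)), (6.0, (0.11,)), (9.0, (0.025,))]
        )
        a, b = fit_uma(curve), fit_uma(curve)
        assert a.params == b.params

    def test_too_few_points_rejected(self):
        with pytest.raises(FittingError):
            fit_uma(SurvivalCurve.from_points([(2.0, (0.5,))]))

    def test_parameter_recovery_median_error(self, recovery_errors):
        """Generate -> fit round trip on noisy triplicate curves: median
        relative error of both parameters below 10%."""
        err_d0, err_n = recovery_errors
        assert np.median(err_d0) < 0.10
        assert np.median(err_n) < 0.10


class TestFitMixture:
    def test_exact_two_population_recovery(self):
        truth = MixtureParams(((0.5, UMAParams(2.80, 1.0)), (0.5, UMAParams(2.70, 58.0))))
        curve = exact_curve(truth, np.arange(0.0, 26.0, 2.0))
        fit = fit_uma_mixture(curve, k=2)
        # sorted by descending D0: the resistant (higher-D0) component first
        (w1, p1), (w2, p2) = fit.params.components
        assert p1.d0 >= p2.d0
        assert p1.d0 == pytest.approx(2.80, rel=0.05)
        assert p1.n == pytest.approx(1.0, rel=0.05)
        assert p2.d0 == pytest.approx(2.70, rel=0.05)
        assert p2.n == pytest.approx(58.0, rel=0.05)
        assert fit.stats.r < 1e-4

    def test_k1_reduces_to_single_fit(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 13.0))
        single = fit_uma(curve)
        k1 = fit_uma_mixture(curve, k=1)
        assert k1.params.d0 == pytest.approx(single.params.d0, rel=1e-12)

    def test_mixture_fit_survival_is_one_at_zero(self):
        truth = MixtureParams(((0.5, UMAParams(3.0, 1.0)), (0.5, UMAParams(1.2, 10.0))))
        curve = exact_curve(truth, np.arange(0.0, 16.0, 1.5))
        fit = fit_uma_mixture(curve, k=2)
        assert uma_survival(fit.params, 0.0) == 1.0

    def test_needs_enough_points(self):
        with pytest.raises(FittingError):
            fit_uma_mixture(
                SurvivalCurve.from_points([(2.0, (0.5,)), (4.0, (0.2,))]), k=2
            )


class TestFitLQ:
    def test_roundtrip_alpha_beta(self):
        alpha, beta = 0.13, 0.06
        doses = np.arange(0.0, 9.0)
        pts = [(d, (math.exp(-alpha * d - beta * d * d),)) for d in doses]
        fit = fit_lq(SurvivalCurve.from_points(pts))
        assert fit.params.alpha == pytest.approx(alpha, rel=1e-8)
        assert fit.params.beta == pytest.approx(beta, rel=1e-8)

    def test_underdetermined_rejected(self):
        with pytest.raises(FittingError):
            fit_lq(SurvivalCurve.from_points([(2.0, (0.5,))]))

    def test_dose_range_sensitivity_on_shouldered_data(self):
        """Restricting the LQ regression range changes alpha/beta materially
        on curved (UMA) data; wider range -> larger fitted ratio."""
        curve = exact_curve(UMAParams(2.20, 2.8), np.arange(0.0, 15.0))
        ab_low = fit_lq(curve, dose_range=(0.0, 10.0)).params.alpha_beta_ratio
        ab_high = fit_lq(curve, dose_range=(0.0, 14.0)).params.alpha_beta_ratio
        assert ab_high > ab_low * 1.05

    def test_stats_cover_all_points_including_outside_range(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 15.0))
        fit = fit_lq(curve, dose_range=(0.0, 6.0))
        assert len(fit.fitted) == curve.n_points
        # the low-dose-only LQ fit underestimates high-dose survival
        assert fit.fitted[-1] < curve.means[-1]

    def test_lq_and_uma_agree_in_range_diverge_at_high_dose(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 15.0))
        lq = fit_lq(curve, dose_range=(0.0, 6.0))
        uma = fit_uma(curve)
        in_range = np.asarray(curve.doses) <= 6.0
        rel = np.abs(np.asarray(lq.fitted) - np.asarray(uma.fitted)) / np.asarray(
            uma.fitted
        )
        assert np.all(rel[in_range] < 0.15)
        # the low-dose LQ fit bends away on the straight portion:
        # more than an order of magnitude below the UMA curve at 14 Gy
        assert lq.fitted[-1] < 0.1 * uma.fitted[-1]


class TestFitMT:
    def test_roundtrip_on_exact_high_dose_data(self):
        d0, n = 1.35, 5.4
        pts = [(d, (n * math.exp(-d / d0),)) for d in (4.0, 6.0, 8.0, 10.0)]
        fit = fit_mt(SurvivalCurve.from_points(pts), min_dose=3.0)
        assert fit.params.d0 == pytest.approx(d0, rel=1e-10)
        assert fit.params.n == pytest.approx(n, rel=1e-10)

    def test_pure_exponential_gives_n_one(self):
        curve = exact_curve(UMAParams(2.0, 1.0), np.arange(0.0, 13.0))
        fit = fit_mt(curve)
        assert fit.params.n == pytest.approx(1.0, rel=1e-10)

    def test_overestimates_low_dose_survival_on_shouldered_curve(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 13.0))
        fit = fit_mt(curve)
        i = curve.doses.index(1.0)
        assert fit.fitted[i] > curve.means[i]

    def test_needs_two_high_dose_points(self):
        with pytest.raises(FittingError):
            fit_mt(SurvivalCurve.from_points([(2.0, (0.5,)), (4.0, (0.2,))]), min_dose=3.0)


class TestFitResultSerialisation:
    def test_json_roundtrip_uma(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 13.0))
        fit = fit_uma(curve)
        back = FitResult.from_json(fit.to_json())
        assert back == fit

    def test_json_roundtrip_lq_and_mixture(self):
        curve = exact_curve(UMAParams(1.5, 5.0), np.arange(0.0, 13.0))
        for fit in (fit_lq(curve), fit_mt(curve)):
            assert FitResult.from_json(fit.to_json()) == fit
        truth = MixtureParams(((0.5, UMAParams(3.0, 1.0)), (0.5, UMAParams(1.2, 10.0))))
        mcurve = exact_curve(truth, np.arange(0.0, 16.0, 1.5))
        mfit = fit_uma_mixture(mcurve, k=2)
        assert FitResult.from_json(mfit.to_json()) == mfit
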