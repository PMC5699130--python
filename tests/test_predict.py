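"""Posterior post-processing: curves, hazard ratios, event-time prediction."""

import numpy as np
import pytest
from scipy import optimize

import cfjoint as cj
from cfjoint.basis import SplineSpec
from cfjoint.mcmc import PosteriorDraws
from cfjoint.params import EVENT_COVARIATES, LONG_COVARIATES


def curve_draws(betas, bs=None, spline=None, extra=None):
    """Hand-assemble PosteriorDraws with given curve coefficients."""
    spline = spline if spline is not None else SplineSpec(knots=())
    betas = np.asarray(betas, float)
    n_draws = betas.shape[0]
    names = [f"beta{i}" for i in range(4)]
    cols = [betas]
    if spline.n_knots:
        names += [f"b{m + 1}" for m in range(spline.n_knots)]
        cols.append(np.asarray(bs, float))
    if extra:
        for k, v in extra.items():
            names.append(k)
            cols.append(np.asarray(v, float)[:, None])
    params = np.concatenate(cols, axis=1)[None]  # single chain
    return PosteriorDraws(
        params=params, names=names, U=None, patient_ids=None,
        variant="joint-semiparametric", spline=spline,
    )


class TestPopulationCurve:
    def test_zero_coefficients_give_zero_curve(self):
        d = curve_draws(np.zeros((3, 4)))
        est = cj.population_curve(d, np.linspace(6, 45, 20))
        np.testing.assert_allclose(est.mean, 0.0)
        np.testing.assert_allclose(est.lower, 0.0)

    def test_single_draw_band_has_zero_width(self):
        d = curve_draws([[1.0, 0.5, -0.02, 0.0]])
        est = cj.population_curve(d, [10.0, 20.0])
        np.testing.assert_allclose(est.upper - est.lower, 0.0)

    def test_rate_curve_matches_finite_difference_of_level(self):
        rng = np.random.default_rng(1)
        spline = SplineSpec(knots=(12.0, 20.0, 30.0))
        d = curve_draws(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)) * 0.01, spline)
        grid = np.linspace(7, 44, 300)
        level = cj.population_curve(d, grid)
        rate = cj.population_curve(d, grid, rate=True)
        h = 1e-4
        up = cj.population_curve(d, grid + h)
        dn = cj.population_curve(d, grid - h)
        fd = (up.mean - dn.mean) / (2 * h)
        np.testing.assert_allclose(rate.mean, fd, atol=1e-3)

    def test_extrapolation_warns(self):
        d = curve_draws(np.zeros((2, 4)))
        with pytest.warns(UserWarning, match="extrapolation"):
            cj.population_curve(d, [3.0, 10.0])


class TestSubjectTrajectory:
    def test_zero_effects_patient_matches_population_plus_covariates(
        self, small_joint_draws, small_registry
    ):
        pid = int(small_registry.patient_ids[0])
        ages = np.linspace(8, 14, 5)
        est = cj.subject_trajectory(small_joint_draws, small_registry, pid, ages)
        # recompute for one draw by hand
        d = small_joint_draws
        i = 3
        coef = np.array(
            [d.get(f"beta{j}")[i] for j in range(4)]
            + [d.get(f"b{m + 1}")[i] for m in range(d.spline.n_knots)]
        )
        from cfjoint.basis import build_basis

        x = small_registry.long_covariate_path(pid, ages)
        alpha1 = np.array([d.get(f"alpha1_{c}")[i] for c in LONG_COVARIATES])
        U = d.U_flat()[i, 0]
        expect = build_basis(ages, d.spline) @ coef + x @ alpha1 + U[0] + U[1] * ages
        got = (
            cj.subject_trajectory(
                small_joint_draws, small_registry, pid, ages, keep_draws=True
            ).per_draw[i]
        )
        np.testing.assert_allclose(got, expect, rtol=1e-10)
        assert est.mean.shape == ages.shape

    def test_unknown_patient_rejected(self, small_joint_draws, small_registry):
        from cfjoint.registry import UnknownPatientError

        with pytest.raises(UnknownPatientError):
            cj.subject_trajectory(small_joint_draws, small_registry, "nope")


class TestSteepestDecline:
    def test_monotone_decreasing_rate_puts_minimum_at_upper_bound(self):
        # f' = beta1 + 2 beta2 age with beta2 < 0: minimized at age 45
        d = curve_draws([[0.0, 1.0, -0.5, 0.0]] * 3)
        res = cj.age_of_steepest_decline(d)
        assert res["mean"] == pytest.approx(45.0)
        assert res["sd"] == 0.0

    def test_quadratic_rate_vertex_found_within_grid_resolution(self):
        # f = beta1 a + beta2 a^2 + beta3 a^3 -> f' quadratic with vertex at
        # -beta2 / (3 beta3); choose vertex at age 20
        beta3 = 0.01
        beta2 = -3 * beta3 * 20
        d = curve_draws([[0.0, 0.0, beta2, beta3]])
        res = cj.age_of_steepest_decline(d, grid_step=0.1)
        assert res["mean"] == pytest.approx(20.0, abs=0.1)


class TestHazardRatios:
    def test_reported_per_sd_transforms(self):
        assert cj.hazard_ratio_per_sd(-0.0086, 326.8) == pytest.approx(0.856, abs=5e-4)
        assert cj.hazard_ratio_per_sd(-0.3532, 2.602) == pytest.approx(0.566, abs=5e-4)

    def test_zero_association_gives_unit_ratio(self):
        for var in (0.5, 10.0, 300.0):
            assert cj.hazard_ratio_per_sd(0.0, var) == 1.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            cj.hazard_ratio_per_sd(-0.1, 0.0)

    def test_monotone_in_theta_and_variance(self):
        thetas = np.linspace(-1, 1, 21)
        hrs = cj.hazard_ratio_per_sd(thetas, 4.0)
        assert np.all(np.diff(hrs) > 0)
        variances = np.linspace(0.5, 8, 15)
        hrs_v = cj.hazard_ratio_per_sd(-0.3, variances)
        assert np.all(np.diff(hrs_v) < 0)

    def test_summaries_from_draws(self, small_joint_draws):
        out = cj.hazard_ratio_summaries(small_joint_draws)
        for key, stat in out.items():
            assert stat["hpd"][0] <= stat["mean"] <= stat["hpd"][1], key
            assert stat["point"] > 0


class TestInterceptSlopeCorrelation:
    def test_registry_sigma_reproduces_reported_value_at_age_six(self):
        re = cj.reference_params().re_dist
        assert cj.intercept_slope_correlation_at_age(re, 6.0) == pytest.approx(
            -0.60, abs=0.01
        )

    def test_uncorrelated_effects_at_age_zero(self):
        re = cj.RandomEffectsDist(sigma0_sq=100.0, sigma1_sq=2.0, sigma01=0.0)
        assert cj.intercept_slope_correlation_at_age(re, 0.0) == 0.0

    def test_zero_crossing_age_matches_monte_carlo(self, rng):
        re = cj.reference_params().re_dist
        age0 = -re.sigma01 / re.sigma1_sq  # numerator root, ~9.90
        assert cj.intercept_slope_correlation_at_age(re, age0) == pytest.approx(0.0, abs=1e-12)
        U = rng.multivariate_normal([0, 0], re.Sigma, size=1_000_000)
        emp = np.corrcoef(U[:, 0] + age0 * U[:, 1], U[:, 1])[0, 1]
        assert emp == pytest.approx(0.0, abs=0.005)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            cj.intercept_slope_correlation_at_age(np.array([[1.0, 5.0], [5.0, 1.0]]), 6.0)


class TestConditionalMedianEventTime:
    def _draws_with_event_params(self, k, alpha2_icpt, theta=None, n_pat=1):
        names = ["k"] + [f"alpha2_{c}" for c in EVENT_COVARIATES]
        row = [k, alpha2_icpt] + [0.0] * (len(EVENT_COVARIATES) - 1)
        U = None
        if theta is not None:
            names += ["theta0", "theta1"]
            row += list(theta)
            U = np.zeros((1, 1, n_pat, 2))
        params = np.array([[row]])
        return PosteriorDraws(
            params=params, names=names, U=U,
            patient_ids=np.array([1]), variant="joint-semiparametric",
            spline=SplineSpec(knots=()),
        )

    def _registry_single(self, time=1.0, status=0):
        from conftest import toy_event_frame, toy_long_frame

        long = toy_long_frame([(1, 10.0, 0.0), (1, 11.0, 0.0)])
        events = toy_event_frame([(1, time, status)])
        return cj.Registry(long=long, events=events)

    def test_exponential_median_from_time_origin(self):
        reg = self._registry_single(time=1.0)
        d = self._draws_with_event_params(k=1.0, alpha2_icpt=0.0, theta=(0.0, 0.0))
        est = cj.conditional_median_event_time(d, reg, 1, censor_time=0.0)
        assert est.medians[0] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_weibull_conditional_median_matches_numeric_root(self):
        reg = self._registry_single(time=1.0)
        d = self._draws_with_event_params(k=2.0, alpha2_icpt=0.0, theta=(0.0, 0.0))
        est = cj.conditional_median_event_time(d, reg, 1)
        target = optimize.brentq(
            lambda t: np.exp(-(t**2)) / np.exp(-1.0) - 0.5, 1.0, 10.0
        )
        assert est.medians[0] == pytest.approx(target, rel=1e-10)
        assert est.medians[0] == pytest.approx(np.sqrt(1 + np.log(2)), rel=1e-12)

    def test_prediction_never_precedes_censoring(self, small_joint_draws, small_registry):
        censored = small_registry.events.query("status == 0")["patient_id"]
        pid = censored.iloc[0]
        est = cj.conditional_median_event_time(small_joint_draws, small_registry, pid)
        assert np.all(est.medians >= est.censor_time)

    def test_monotone_in_censor_time_and_eta(self):
        reg = self._registry_single(time=1.0)
        meds_c = []
        for c in (0.5, 1.0, 2.0, 4.0):
            d = self._draws_with_event_params(k=2.0, alpha2_icpt=0.0, theta=(0.0, 0.0))
            meds_c.append(
                cj.conditional_median_event_time(d, reg, 1, censor_time=c).medians[0]
            )
        assert np.all(np.diff(meds_c) > 0)
        meds_eta = []
        for icpt in (-2.0, -1.0, 0.0, 1.0):
            d = self._draws_with_event_params(k=2.0, alpha2_icpt=icpt, theta=(0.0, 0.0))
            meds_eta.append(
                cj.conditional_median_event_time(d, reg, 1, censor_time=1.0).medians[0]
            )
        assert np.all(np.diff(meds_eta) < 0)

    def test_observed_event_patient_rejected(self, small_joint_draws, small_registry):
        with_event = small_registry.events.query("status == 1")["patient_id"]
        with pytest.raises(ValueError, match="censored patients only"):
            cj.conditional_median_event_time(
                small_joint_draws, small_registry, with_event.iloc[0]
            )
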