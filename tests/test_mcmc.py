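"""MCMC machinery: HPD intervals, summaries, and sampler correctness."""

import warnings

import numpy as np
import pytest
from scipy import stats

import cfjoint as cj
from cfjoint.mcmc import PosteriorDraws


def brute_force_hpd(x, mass):
    x = np.sort(np.asarray(x, float))
    n = x.size
    m = int(np.ceil(mass * n))
    best = None
    for j in range(n - m + 1):
        w = x[j + m - 1] - x[j]
        if best is None or w < best[0] - 1e-15:
            best = (w, x[j], x[j + m - 1])
    return best[1], best[2]


class TestHPDInterval:
    def test_constant_sample(self):
        assert cj.hpd_interval([3.3] * 10) == (3.3, 3.3)

    def test_uniform_ranks_tie_broken_low(self):
        assert cj.hpd_interval(np.arange(1, 101), 0.95) == (1.0, 95.0)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("mass", [0.5, 0.9, 0.95])
    def test_matches_brute_force_window_search(self, seed, mass):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.5, size=201)
        assert cj.hpd_interval(x, mass) == pytest.approx(brute_force_hpd(x, mass))

    def test_normal_sample_matches_analytic_quantiles(self, rng):
        x = rng.standard_normal(100_000)
        lo, hi = cj.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_never_wider_than_equal_tailed(self, rng):
        x = rng.lognormal(0, 0.8, 4001)
        lo, hi = cj.hpd_interval(x, 0.9)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert hi - lo <= qhi - qlo + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cj.hpd_interval([1.0])


def _manual_draws(params, names):
    return PosteriorDraws(
        params=params,
        names=names,
        U=None,
        patient_ids=None,
        variant="separate-event",
        spline=None,
    )


class TestSummarize:
    def test_degenerate_draws_have_zero_width(self):
        params = np.full((2, 40, 1), 7.25)
        rep = cj.summarize(_manual_draws(params, ["k"]))
        row = rep.table.loc["k"]
        assert row["mean"] == 7.25
        assert row["hpd_high"] - row["hpd_low"] == 0.0

    def test_row_count_and_mean_recomputation(self, small_joint_draws):
        rep = cj.summarize(small_joint_draws)
        assert len(rep.table) == len(small_joint_draws.names)
        th = small_joint_draws.get("theta1")
        assert rep.table.loc["theta1", "mean"] == pytest.approx(th.mean(), rel=1e-12)

    def test_single_chain_warns_and_reports_nan_rhat(self):
        rng = np.random.default_rng(0)
        params = rng.normal(size=(1, 60, 1))
        with pytest.warns(UserWarning, match="single chain"):
            rep = cj.summarize(_manual_draws(params, ["k"]))
        assert np.isnan(rep.table.loc["k", "rhat"])


class TestConfigValidation:
    def test_burnin_must_be_below_iterations(self):
        with pytest.raises(ValueError):
            cj.MCMCConfig(n_iterations=100, n_burnin=100)

    def test_unknown_variant_rejected(self, toy_registry):
        with pytest.raises(ValueError):
            cj.run_mcmc(toy_registry, variant="bogus")


@pytest.fixture(scope="module")
def gls_data():
    """Small cohort with known variance components for the closed-form check."""
    p = cj.reference_params()
    raw = cj.simulate_cohort(cj.CohortConfig(n_patients=30, seed=13, params=p))
    return raw.to_registry(), p


class TestSamplerCorrectness:
    def test_identical_seed_reproduces_draws(self, small_registry):
        cfg = cj.MCMCConfig(n_chains=2, n_iterations=120, n_burnin=40, seed=77)
        a = cj.run_mcmc(small_registry, "joint-semiparametric", config=cfg)
        b = cj.run_mcmc(small_registry, "joint-semiparametric", config=cfg)
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.U, b.U)

    def test_posterior_mean_matches_generalized_least_squares(self, gls_data):
        """With fixed variance components and no event submodel the Gibbs
        sampler targets a Gaussian posterior whose mean has a closed form."""
        reg, p = gls_data
        fixed = {"sigma_eps2": p.longitudinal.sigma_eps2, "Sigma": p.re_dist.Sigma}
        cfg = cj.MCMCConfig(n_chains=2, n_iterations=2000, n_burnin=500, seed=3)
        draws = cj.run_mcmc(
            reg, "separate-longitudinal", spline=p.spline, config=cfg, fixed=fixed
        )
        X, y, ages = reg.long_design(p.spline)
        pidx = reg.patient_index()
        n_pat = reg.n_patients
        prior_prec = 1e-6  # N(0, 1e6) prior on every coefficient
        A = np.zeros((X.shape[1], X.shape[1]))
        rhs = np.zeros(X.shape[1])
        for i in range(n_pat):
            sel = pidx == i
            Z = np.column_stack([np.ones(sel.sum()), ages[sel]])
            V = Z @ p.re_dist.Sigma @ Z.T + p.longitudinal.sigma_eps2 * np.eye(sel.sum())
            Vi = np.linalg.inv(V)
            A += X[sel].T @ Vi @ X[sel]
            rhs += X[sel].T @ Vi @ y[sel]
        expected = np.linalg.solve(A + prior_prec * np.eye(X.shape[1]), rhs)
        rep = cj.summarize(draws).table
        for j, name in enumerate(draws.names[: X.shape[1]]):
            if name.startswith("b"):  # spline coefs carry the shrinkage prior
                continue
            row = rep.loc[name]
            mcse = np.std(draws.get(name)) / np.sqrt(max(row["ess"], 4.0))
            assert abs(row["mean"] - expected[j]) < 3.5 * mcse + 1e-8, name

    def test_zero_association_factorizes_to_separate_longitudinal(self, gls_data):
        """Fixing theta0 = theta1 = 0 must leave the longitudinal posterior
        identical to the separate longitudinal fit (within MC error)."""
        reg, p = gls_data
        cfg = cj.MCMCConfig(n_chains=2, n_iterations=1200, n_burnin=400, seed=8)
        joint = cj.run_mcmc(
            reg,
            "joint-semiparametric",
            spline=p.spline,
            config=cfg,
            fixed={"theta0": 0.0, "theta1": 0.0},
        )
        sep = cj.run_mcmc(reg, "separate-longitudinal", spline=p.spline, config=cfg)
        for name in ("beta1", "alpha1_baseline_fev1", "sigma_eps2", "sigma0_sq", "sigma1_sq"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                import arviz as az

                mcse = np.hypot(
                    np.std(joint.get(name)) / np.sqrt(max(float(az.ess(joint.get_chains(name))), 4)),
                    np.std(sep.get(name)) / np.sqrt(max(float(az.ess(sep.get_chains(name))), 4)),
                )
            assert abs(joint.mean(name) - sep.mean(name)) < 4 * mcse, name

    def test_draws_contain_no_nonfinite_values(self, small_joint_draws):
        assert np.all(np.isfinite(small_joint_draws.params))
        assert np.all(np.isfinite(small_joint_draws.U))

    def test_recovers_weibull_shape_on_event_only_fit(self, rng):
        """Event-only fit on pure Weibull data recovers the true shape."""
        n = 400
        k_true = 2.0
        import pandas as pd

        from conftest import toy_event_frame, toy_long_frame

        t = rng.weibull(k_true, n) * 2.0  # scale 2 -> eta = -k log 2
        t = np.clip(t, 1e-3, None)
        cens = np.minimum(t, 6.0)
        status = (t <= 6.0).astype(int)
        long = toy_long_frame([(i + 1, 10.0, 90.0) for i in range(n)])
        events = toy_event_frame(list(zip(range(1, n + 1), cens, status)))
        reg = cj.Registry(long=long, events=events)
        cfg = cj.MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=500, seed=4)
        draws = cj.run_mcmc(reg, "separate-event", config=cfg)
        lo, hi = cj.hpd_interval(draws.get("k"), 0.99)
        assert lo < k_true < hi


class TestFrailty:
    def test_frailty_variant_samples_and_records_heterogeneity(self, small_registry):
        """Adding the event-level frailty U3 ~ N(0, sigma3^2) yields finite
        draws of sigma3_sq and one frailty trajectory per patient."""
        cfg = cj.MCMCConfig(n_chains=1, n_iterations=250, n_burnin=100, seed=6)
        d = cj.run_mcmc(small_registry, "joint-semiparametric", config=cfg, frailty=True)
        assert d.has("sigma3_sq")
        assert np.all(d.get("sigma3_sq") > 0)
        assert d.U3.shape == (1, 150, small_registry.n_patients)

    def test_frailty_simulation_spreads_event_risk(self):
        p = cj.reference_params()
        p.re_dist.sigma3_sq = 0.25
        raw = cj.simulate_cohort(
            cj.CohortConfig(n_patients=400, seed=3, params=p, frailty=True)
        )
        assert raw.truth["U3"].std() == pytest.approx(0.5, abs=0.1)


class TestHPDProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=120),
        st.floats(0.05, 0.99),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_interval_contains_requested_mass_and_matches_oracle(self, xs, mass):
        lo, hi = cj.hpd_interval(xs, mass)
        x = np.asarray(xs)
        m = int(np.ceil(mass * x.size))
        assert np.sum((x >= lo) & (x <= hi)) >= m
        assert (lo, hi) == pytest.approx(brute_force_hpd(x, mass))
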