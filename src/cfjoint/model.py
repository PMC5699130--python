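"""Likelihood and posterior density of the joint model.

Longitudinal submodel (per visit j of patient i, age in years):

    FEV1_ij = f(age_ij) + x1_ij' alpha1 + U0_i + U1_i * age_ij + eps_ij,
    eps_ij ~ N(0, sigma_eps^2),

with f the cubic truncated-power spline.  Event submodel (t = years since
baseline entry):

    h_i(t) = k t^(k-1) exp(eta_i),
    eta_i  = x2_i' alpha2 + theta0 U0_i + theta1 U1_i (+ U3_i),

so the event time is Weibull given the random effects; the two submodels are
conditionally independent given (U0, U1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .basis import build_basis
from .params import JointParams, PriorSpec, SubjectEffects
from .registry import Registry

_LOG2PI = np.log(2.0 * np.pi)


def longitudinal_mean(
    params: JointParams, age, covariates, u: SubjectEffects | tuple = (0.0, 0.0)
):
    """Noise-free longitudinal mean: f(age) + x' alpha1 + U0 + U1 * age.

    ``age`` may be scalar or array; ``covariates`` one row or a matching
    stack of rows in ``LONG_COVARIATES`` order.
    """
    age = np.asarray(age, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.shape[-1] != params.longitudinal.alpha1.shape[0]:
        raise ValueError(
            f"covariate vector has {x.shape[-1]} entries, expected "
            f"{params.longitudinal.alpha1.shape[0]}"
        )
    B = build_basis(age, params.spline)
    fixed = B @ np.concatenate([params.longitudinal.beta, params.longitudinal.b])
    cov = x @ params.longitudinal.alpha1
    if isinstance(u, SubjectEffects):
        u0, u1 = u.U0, u.U1
    else:
        u0, u1 = u
    return fixed + cov + np.asarray(u0, float) + np.asarray(u1, float) * age


def hazard(t, k: float, eta):
    """Weibull hazard ``k t^(k-1) exp(eta)``; increases in t iff k > 1."""
    t = np.asarray(t, dtype=float)
    if not k > 0:
        raise ValueError("k must be positive")
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    return k * t ** (k - 1.0) * np.exp(eta)


def cumulative_hazard(t, k: float, eta):
    """Integrated hazard ``t^k exp(eta)``; survival = exp(-cumulative_hazard)."""
    t = np.asarray(t, dtype=float)
    if not k > 0:
        raise ValueError("k must be positive")
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return t**k * np.exp(eta)


def event_loglik(time, status, k: float, eta):
    """Censored Weibull log-likelihood contribution(s).

    ``status * log h(T) - H(T)``; a censored record contributes only the
    survival term.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    eta = np.asarray(eta, dtype=float)
    logh = np.log(k) + (k - 1.0) * np.log(time) + eta
    return status * logh - cumulative_hazard(time, k, eta)


def _gaussian_loglik(y, mean, var):
    r = np.asarray(y, float) - mean
    return -0.5 * (_LOG2PI + np.log(var)) * r.size - 0.5 * np.sum(r * r) / var


def log_prior(params: JointParams, prior: PriorSpec) -> float:
    """Log prior density of all parameters (see PriorSpec)."""
    lon, ev, re = params.longitudinal, params.event, params.re_dist
    lp = 0.0
    coef_sd = np.sqrt(prior.coef_var)
    flat = np.concatenate([lon.beta, lon.alpha1, ev.alpha2, [ev.theta0, ev.theta1]])
    lp += np.sum(stats.norm.logpdf(flat, 0.0, coef_sd))
    if lon.b.size:
        if lon.sigma_b2 is None:
            lp += np.sum(stats.norm.logpdf(lon.b, 0.0, coef_sd))
        else:
            lp += np.sum(stats.norm.logpdf(lon.b, 0.0, np.sqrt(lon.sigma_b2)))
            lp += stats.invgamma.logpdf(lon.sigma_b2, prior.spline_a, scale=prior.spline_b)
    lp += stats.invgamma.logpdf(lon.sigma_eps2, prior.var_a, scale=prior.var_b)
    # Wishart prior on the precision matrix, expressed as a density on Sigma
    # (Jacobian of Sigma -> Sigma^-1 for symmetric 2x2 is |Sigma|^-3).
    Sigma = re.Sigma
    prec = np.linalg.inv(Sigma)
    lp += stats.wishart.logpdf(prec, df=prior.wishart_df, scale=prior.wishart_scale)
    lp += -3.0 * np.linalg.slogdet(Sigma)[1]
    if re.sigma3_sq > 0:
        lp += stats.invgamma.logpdf(re.sigma3_sq, prior.var_a, scale=prior.var_b)
    lp += stats.gamma.logpdf(ev.k, prior.k_shape, scale=1.0 / prior.k_rate)
    return float(lp)


def event_linear_predictor(
    params: JointParams, X2: np.ndarray, effects: SubjectEffects
) -> np.ndarray:
    ev = params.event
    eta = X2 @ ev.alpha2 + ev.theta0 * effects.U0 + ev.theta1 * effects.U1
    if effects.U3 is not None:
        eta = eta + effects.U3
    return eta


def joint_log_posterior(
    params: JointParams,
    effects: SubjectEffects,
    registry: Registry | None,
    prior: PriorSpec | None = None,
) -> float:
    """Unnormalized log posterior of the full joint model.

    Sums the Gaussian longitudinal log-likelihood, the censored Weibull
    log-likelihood, the bivariate-normal random-effects density (plus the
    frailty normal when present), and the log prior.  Returns ``-inf`` for
    an invalid covariance so samplers can reject rather than crash;
    ``registry=None`` (or an empty cohort) returns the log prior alone.
    """
    prior = prior if prior is not None else PriorSpec()
    try:
        lp = log_prior(params, prior)
    except ValueError:
        return -np.inf
    Sigma = params.re_dist.Sigma
    sign, _ = np.linalg.slogdet(Sigma)
    if sign <= 0 or Sigma[0, 0] <= 0 or np.linalg.det(Sigma) <= 0:
        return -np.inf
    if registry is None or registry.n_patients == 0:
        return lp
    if effects.n != registry.n_patients:
        raise ValueError("one (U0, U1) pair required per patient")

    X, y, ages = registry.long_design(params.spline)
    pidx = registry.patient_index()
    mean = X @ params.longitudinal.coef + effects.U0[pidx] + effects.U1[pidx] * ages
    lp += _gaussian_loglik(y, mean, params.longitudinal.sigma_eps2)

    X2, time, status = registry.event_design()
    eta = event_linear_predictor(params, X2, effects)
    lp += float(np.sum(event_loglik(time, status, params.event.k, eta)))

    U = np.column_stack([effects.U0, effects.U1])
    lp += float(np.sum(stats.multivariate_normal.logpdf(U, mean=np.zeros(2), cov=Sigma)))
    if effects.U3 is not None:
        if params.re_dist.sigma3_sq <= 0:
            return -np.inf
        lp += float(
            np.sum(stats.norm.logpdf(effects.U3, 0.0, np.sqrt(params.re_dist.sigma3_sq)))
        )
    return float(lp)
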