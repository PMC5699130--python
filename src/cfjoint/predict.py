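"""Scientific post-processing of posterior draws.

Turns MCMC output into the quantities of clinical interest: population and
per-patient FEV1 trajectories (level and rate of decline), the age of most
rapid decline, hazard ratios per SD of the random effects, the implied
correlation between trajectory level at a given age and slope, and
individualized conditional median exacerbation times for censored patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import AGE_RANGE, build_basis, build_basis_derivative
from .mcmc import PosteriorDraws, hpd_interval
from .params import LONG_COVARIATES
from .registry import Registry, UnknownPatientError


@dataclass
class TrajectoryEstimate:
    """Pointwise posterior summary of a smooth (noise-free) FEV1 curve."""

    ages: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: str  # "population" or a patient id
    kind: str  # "level" (% predicted) or "rate" (% predicted / year)
    per_draw: np.ndarray | None = None  # (n_draws, n_ages)


@dataclass
class EventTimePosterior:
    """Posterior of the conditional median exacerbation time for a censored
    patient.  Times are years since baseline; ``*_age`` adds baseline age."""

    patient_id: object
    censor_time: float
    baseline_age: float
    medians: np.ndarray  # per-draw conditional median event times
    summary_median: float
    hpd: tuple[float, float]

    @property
    def medians_age(self) -> np.ndarray:
        return self.baseline_age + self.medians

    @property
    def summary_median_age(self) -> float:
        return self.baseline_age + self.summary_median


def _curve_coefs(draws: PosteriorDraws) -> np.ndarray:
    """(n_draws, 4 + K) stacked [beta, b] coefficients."""
    K = draws.spline.n_knots
    cols = [draws.get(f"beta{i}") for i in range(4)]
    cols += [draws.get(f"b{m + 1}") for m in range(K)]
    return np.column_stack(cols)


def _check_grid(ages: np.ndarray) -> None:
    lo, hi = AGE_RANGE
    if np.any(ages < lo) or np.any(ages > hi):
        warnings.warn(
            f"age grid extends outside the modeled range {AGE_RANGE}; "
            "curve values there are extrapolations",
            stacklevel=3,
        )


def population_curve(
    draws: PosteriorDraws,
    ages,
    rate: bool = False,
    mass: float = 0.95,
    keep_draws: bool = False,
) -> TrajectoryEstimate:
    """Posterior of the population mean curve f(age) or its derivative.

    With ``rate=True`` the curve is f'(age), the population rate of FEV1
    change in % predicted per year.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    _check_grid(ages)
    basis_fn = build_basis_derivative if rate else build_basis
    B = basis_fn(ages, draws.spline)  # (n_ages, 4+K)
    C = _curve_coefs(draws)  # (n_draws, 4+K)
    curves = C @ B.T  # (n_draws, n_ages)
    return _summarize_curves(curves, ages, "population", "rate" if rate else "level", mass, keep_draws)


def _summarize_curves(curves, ages, level, kind, mass, keep_draws) -> TrajectoryEstimate:
    if curves.shape[0] == 1:
        lo = hi = curves[0]
    else:
        bounds = np.apply_along_axis(lambda c: hpd_interval(c, mass), 0, curves)
        lo, hi = bounds[0], bounds[1]
    return TrajectoryEstimate(
        ages=ages,
        mean=curves.mean(axis=0),
        lower=lo,
        upper=hi,
        level=level,
        kind=kind,
        per_draw=curves if keep_draws else None,
    )


def subject_trajectory(
    draws: PosteriorDraws,
    registry: Registry,
    patient_id,
    ages=None,
    rate: bool = False,
    mass: float = 0.95,
    keep_draws: bool = False,
) -> TrajectoryEstimate:
    """Posterior of one patient's smooth FEV1 trajectory (or its rate).

    Adds the patient's covariate contribution and sampled random effects
    ``U0 + U1 * age`` to the population curve; time-varying covariates are
    carried forward from the last observed visit.
    """
    ids = list(draws.patient_ids)
    if patient_id not in ids:
        raise UnknownPatientError(f"patient {patient_id!r} not in the fitted cohort")
    pi = ids.index(patient_id)
    sub = registry.long[registry.long["patient_id"] == patient_id]
    if ages is None:
        ages = np.linspace(sub["age"].min(), sub["age"].max(), 50)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    _check_grid(ages)

    basis_fn = build_basis_derivative if rate else build_basis
    B = basis_fn(ages, draws.spline)
    C = _curve_coefs(draws)
    curves = C @ B.T
    U = draws.U_flat()[:, pi, :]  # (n_draws, 2)
    if rate:
        curves = curves + U[:, 1][:, None]
    else:
        x = registry.long_covariate_path(patient_id, ages)  # (n_ages, n_cov)
        alpha1 = np.column_stack([draws.get(f"alpha1_{c}") for c in LONG_COVARIATES])
        curves = curves + alpha1 @ x.T
        curves = curves + U[:, 0][:, None] + U[:, 1][:, None] * ages[None, :]
    return _summarize_curves(curves, ages, str(patient_id), "rate" if rate else "level", mass, keep_draws)


def age_of_steepest_decline(
    draws: PosteriorDraws, grid_step: float = 0.1, age_range: tuple[float, float] = AGE_RANGE
) -> dict:
    """Per-draw minimizer of the population rate curve f'(age).

    Grid search at ``grid_step`` (years) resolution; returns mean (SD) and
    median (IQR) across draws plus the per-draw minimizers.
    """
    lo, hi = age_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    B = build_basis_derivative(grid, draws.spline)
    C = _curve_coefs(draws)
    rates = C @ B.T
    minimizers = grid[np.argmin(rates, axis=1)]
    q25, q50, q75 = np.percentile(minimizers, [25, 50, 75])
    return {
        "mean": float(minimizers.mean()),
        "sd": float(minimizers.std()),
        "median": float(q50),
        "iqr": (float(q25), float(q75)),
        "per_draw": minimizers,
    }


def hazard_ratio_per_sd(theta, var):
    """Hazard ratio per one SD of a random effect: ``exp(theta * sqrt(var))``.

    Puts the intercept (% predicted) and slope (%/year) associations on a
    comparable scale.  Vectorized over draws.
    """
    theta = np.asarray(theta, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variance must be positive")
    out = np.exp(theta * np.sqrt(var))
    return float(out) if out.ndim == 0 else out


def hazard_ratio_summaries(draws: PosteriorDraws, mass: float = 0.95) -> dict:
    """Posterior summaries of the four association hazard ratios.

    Returns per-unit HRs ``exp(theta0)``, ``exp(theta1)`` and per-SD HRs
    ``exp(theta0 * sigma0)``, ``exp(theta1 * sigma1)``; each entry holds the
    posterior mean and HPD over draws plus the plug-in value at the
    posterior means of the parameters (the conventional reported number).
    """
    out = {}
    specs = {
        "hr_intercept_per_unit": (draws.get("theta0"), None),
        "hr_slope_per_unit": (draws.get("theta1"), None),
        "hr_intercept_per_sd": (draws.get("theta0"), draws.get("sigma0_sq")),
        "hr_slope_per_sd": (draws.get("theta1"), draws.get("sigma1_sq")),
    }
    for name, (th, var) in specs.items():
        per_draw = np.exp(th) if var is None else hazard_ratio_per_sd(th, var)
        if var is None:
            point = float(np.exp(th.mean()))
        else:
            point = hazard_ratio_per_sd(th.mean(), var.mean())
        lo, hi = hpd_interval(per_draw, mass)
        out[name] = {
            "point": point,
            "mean": float(per_draw.mean()),
            "hpd": (lo, hi),
        }
    return out


def intercept_slope_correlation_at_age(Sigma, age: float) -> float:
    """Correlation between the trajectory level at ``age`` and the slope.

    ``Corr(U0 + age * U1, U1) = (sigma01 + age * sigma1^2) /
    (sqrt(sigma0^2 + age^2 sigma1^2 + 2 age sigma01) * sigma1)``.
    At age 6 this quantifies the "ceiling effect": patients starting higher
    tend to decline faster when it is negative.
    """
    if hasattr(Sigma, "Sigma"):
        Sigma = Sigma.Sigma
    Sigma = np.asarray(Sigma, dtype=float)
    if np.linalg.det(Sigma) <= 0 or Sigma[0, 0] <= 0:
        raise ValueError("Sigma must be positive definite")
    s0, s1, s01 = Sigma[0, 0], Sigma[1, 1], Sigma[0, 1]
    num = s01 + age * s1
    den = np.sqrt(s0 + age**2 * s1 + 2.0 * age * s01) * np.sqrt(s1)
    return float(num / den)


def conditional_median_event_time(
    draws: PosteriorDraws,
    registry: Registry,
    patient_id,
    censor_time: float | None = None,
    mass: float = 0.95,
) -> EventTimePosterior:
    """Posterior of the conditional median exacerbation time of a censored
    patient.

    Given survival to the censoring time c, the conditional median under the
    Weibull solves ``S(t)/S(c) = 1/2``:

        t_med = (c^k + ln 2 * exp(-eta))^(1/k),

    evaluated per MCMC draw with that draw's ``eta = x2' alpha2 + theta0 U0
    + theta1 U1``.  Always >= c (exacerbation cannot predate censoring).
    """
    ev = registry.events.loc[patient_id]
    if int(ev["status"]) == 1:
        raise ValueError(
            f"patient {patient_id!r} has an observed exacerbation; conditional "
            "prediction is defined for censored patients only"
        )
    c = float(ev["time"]) if censor_time is None else float(censor_time)
    if c < 0:
        raise ValueError("censor_time must be >= 0")
    ids = list(draws.patient_ids)
    if patient_id not in ids:
        raise UnknownPatientError(f"patient {patient_id!r} not in the fitted cohort")
    pi = ids.index(patient_id)

    X2, _, _ = registry.event_design()
    row = X2[list(registry.events.index).index(patient_id)]
    from .params import EVENT_COVARIATES

    alpha2 = np.column_stack([draws.get(f"alpha2_{c_}") for c_ in EVENT_COVARIATES])
    eta = alpha2 @ row
    if draws.has("theta0"):
        U = draws.U_flat()[:, pi, :]
        eta = eta + draws.get("theta0") * U[:, 0] + draws.get("theta1") * U[:, 1]
    k = draws.get("k")
    medians = (c**k + np.log(2.0) * np.exp(-eta)) ** (1.0 / k)
    if medians.size > 1:
        lo, hi = hpd_interval(medians, mass)
    else:
        lo = hi = float(medians[0])
    return EventTimePosterior(
        patient_id=patient_id,
        censor_time=c,
        baseline_age=float(ev["baseline_age"]),
        medians=medians,
        summary_median=float(np.median(medians)),
        hpd=(lo, hi),
    )
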