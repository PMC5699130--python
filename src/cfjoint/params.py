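"""Parameter containers for the shared-parameter joint model.

The model couples a Gaussian linear mixed submodel for longitudinal FEV1
(% predicted) with a Weibull proportional-hazards submodel for time to first
pulmonary exacerbation.  Per-patient random intercepts and slopes
``(U0, U1) ~ N(0, Sigma)`` enter the longitudinal mean as ``U0 + U1 * age``
and the log hazard as ``theta0 * U0 + theta1 * U1`` (optionally plus an
independent frailty ``U3 ~ N(0, sigma3^2)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import SplineSpec

#: Covariates of the longitudinal submodel, in design order.  ``baseline_fev1``
#: is the first retained FEV1 measurement; birth-cohort contrasts use the
#: youngest cohort (born after 1994) as reference; the last four flags are
#: time-varying infection/comorbidity indicators.
LONG_COVARIATES = (
    "baseline_fev1",
    "male",
    "cohort_lt1981",
    "cohort_1981_1988",
    "cohort_1989_1994",
    "low_ses",
    "cfrd",
    "mrsa",
    "b_cepacia",
    "pa",
)

#: Covariates of the Weibull event submodel (all fixed at baseline).
EVENT_COVARIATES = (
    "intercept",
    "baseline_age",
    "baseline_fev1",
    "male",
    "cohort_lt1981",
    "cohort_1981_1988",
    "cohort_1989_1994",
    "low_ses",
)

#: Birth-cohort categories; the last is the reference level.
BIRTH_COHORTS = ("lt1981", "1981_1988", "1989_1994", "gt1994")


@dataclass
class LongitudinalParams:
    """Fixed effects and residual variance of the FEV1 submodel."""

    beta: np.ndarray  # global cubic coefficients (beta0..beta3)
    b: np.ndarray  # spline coefficients, one per knot
    alpha1: np.ndarray  # covariate effects, order LONG_COVARIATES
    sigma_eps2: float  # measurement-error variance (FEV1^2 units)
    sigma_b2: float | None = None  # spline shrinkage variance (None = vague)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must have length 4")
        if self.alpha1.shape != (len(LONG_COVARIATES),):
            raise ValueError(
                f"alpha1 must have length {len(LONG_COVARIATES)} (got {self.alpha1.shape})"
            )
        if not self.sigma_eps2 > 0:
            raise ValueError("sigma_eps2 must be positive")

    @property
    def coef(self) -> np.ndarray:
        """Stacked coefficient vector ``[beta, b, alpha1]`` (design order)."""
        return np.concatenate([self.beta, self.b, self.alpha1])


@dataclass
class RandomEffectsDist:
    """Bivariate normal law of (U0, U1), plus an optional frailty variance."""

    sigma0_sq: float  # between-patient intercept variance
    sigma1_sq: float  # between-patient slope variance
    sigma01: float  # intercept-slope covariance
    sigma3_sq: float = 0.0  # frailty variance (0 = frailty off)

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0 or self.sigma1_sq <= 0:
            raise ValueError("random-effect variances must be positive")
        if self.sigma01**2 >= self.sigma0_sq * self.sigma1_sq:
            raise ValueError("Sigma is not positive definite")
        if self.sigma3_sq < 0:
            raise ValueError("sigma3_sq must be >= 0")

    @property
    def Sigma(self) -> np.ndarray:
        return np.array(
            [[self.sigma0_sq, self.sigma01], [self.sigma01, self.sigma1_sq]]
        )

    @classmethod
    def from_Sigma(cls, Sigma: np.ndarray, sigma3_sq: float = 0.0) -> "RandomEffectsDist":
        Sigma = np.asarray(Sigma, dtype=float)
        return cls(
            sigma0_sq=float(Sigma[0, 0]),
            sigma1_sq=float(Sigma[1, 1]),
            sigma01=float(Sigma[0, 1]),
            sigma3_sq=sigma3_sq,
        )


@dataclass
class SubjectEffects:
    """Per-patient latent effects: intercepts U0, slopes U1, optional frailty."""

    U0: np.ndarray
    U1: np.ndarray
    U3: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.U0 = np.atleast_1d(np.asarray(self.U0, dtype=float))
        self.U1 = np.atleast_1d(np.asarray(self.U1, dtype=float))
        if self.U0.shape != self.U1.shape:
            raise ValueError("U0 and U1 must have the same shape")
        if self.U3 is not None:
            self.U3 = np.atleast_1d(np.asarray(self.U3, dtype=float))
            if self.U3.shape != self.U0.shape:
                raise ValueError("U3 must match U0 in shape")

    @property
    def n(self) -> int:
        return self.U0.shape[0]

    @classmethod
    def zeros(cls, n: int, frailty: bool = False) -> "SubjectEffects":
        return cls(
            U0=np.zeros(n),
            U1=np.zeros(n),
            U3=np.zeros(n) if frailty else None,
        )


@dataclass
class EventParams:
    """Weibull shape, baseline-covariate effects and association parameters."""

    k: float  # Weibull shape (>1: hazard increasing in time)
    alpha2: np.ndarray  # coefficients, order EVENT_COVARIATES
    theta0: float  # log-HR per unit of U0 (1 % predicted)
    theta1: float  # log-HR per unit of U1 (1 % predicted / year)

    def __post_init__(self) -> None:
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        if not self.k > 0:
            raise ValueError("Weibull shape k must be positive")
        if self.alpha2.shape != (len(EVENT_COVARIATES),):
            raise ValueError(
                f"alpha2 must have length {len(EVENT_COVARIATES)} (got {self.alpha2.shape})"
            )


@dataclass
class JointParams:
    """All parameters of the joint model."""

    longitudinal: LongitudinalParams
    re_dist: RandomEffectsDist
    event: EventParams
    spline: SplineSpec

    def __post_init__(self) -> None:
        if self.longitudinal.b.shape != (self.spline.n_knots,):
            raise ValueError(
                f"spline coefficient vector b has length {self.longitudinal.b.shape[0]} "
                f"but the spline spec has {self.spline.n_knots} knots"
            )

    def to_flat_series(self) -> pd.Series:
        """Flatten to one named scalar per row, for reporting."""
        lon, ev, re = self.longitudinal, self.event, self.re_dist
        vals: dict[str, float] = {}
        for i, v in enumerate(lon.beta):
            vals[f"beta{i}"] = v
        for i, v in enumerate(lon.b):
            vals[f"b{i + 1}"] = v
        for name, v in zip(LONG_COVARIATES, lon.alpha1):
            vals[f"alpha1_{name}"] = v
        vals["sigma_eps2"] = lon.sigma_eps2
        if lon.sigma_b2 is not None:
            vals["sigma_b2"] = lon.sigma_b2
        vals["sigma0_sq"] = re.sigma0_sq
        vals["sigma1_sq"] = re.sigma1_sq
        vals["sigma01"] = re.sigma01
        if re.sigma3_sq > 0:
            vals["sigma3_sq"] = re.sigma3_sq
        vals["k"] = ev.k
        for name, v in zip(EVENT_COVARIATES, ev.alpha2):
            vals[f"alpha2_{name}"] = v
        vals["theta0"] = ev.theta0
        vals["theta1"] = ev.theta1
        return pd.Series(vals, name="value")

    def replace(self, **kwargs) -> "JointParams":
        return replace(self, **kwargs)


@dataclass
class PriorSpec:
    """Prior hyperparameters (vague, WinBUGS-style defaults).

    Regression coefficients and association parameters get independent
    ``N(0, coef_var)`` priors; variances get ``InvGamma(var_a, var_b)``;
    the random-effects precision gets ``Wishart(I_2, wishart_df)``; the
    Weibull shape gets ``Gamma(k_shape, k_rate)``.  Spline coefficients
    ``b_m ~ N(0, sigma_b2)`` with an inverse-gamma hyperprior on
    ``sigma_b2`` -- this shrinkage IS the spline penalization.
    """

    coef_var: float = 1.0e6
    var_a: float = 0.01
    var_b: float = 0.01
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    k_shape: float = 1.0
    k_rate: float = 0.001
    spline_a: float = 0.01
    spline_b: float = 0.01

    def __post_init__(self) -> None:
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        if self.coef_var <= 0 or self.var_a <= 0 or self.var_b <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= dimension (2)")
        if self.k_shape <= 0 or self.k_rate <= 0:
            raise ValueError("Weibull shape prior hyperparameters must be positive")


def reference_params(n_knots: int = 6) -> JointParams:
    """Default parameter values emulating US CF registry joint-model estimates.

    These are posterior-mean-scale values representative of published
    registry analyses of FEV1 decline and first pulmonary exacerbation in
    2003-2011 US cohorts: measurement-error SD ~7.7 % predicted, between
    patient intercept SD ~18, slope SD ~1.6 %/yr, strong negative
    intercept-slope covariance (the "ceiling effect"), Weibull shape ~2.6
    (sharply increasing exacerbation hazard), and negative association of
    both trajectory level and rate of change with the hazard.  Knot
    locations are evenly spaced over adolescence/adulthood; with the
    default spline coefficients the population curve declines fastest
    around age 17.

    Used as the default truth of the synthetic-cohort generator and as the
    worked-example input set.
    """
    if n_knots not in (0, 6):
        raise ValueError("reference parameters are defined for 0 or 6 knots")
    spline = SplineSpec(knots=(10.0, 15.0, 20.0, 25.0, 30.0, 35.0)[: n_knots or 0])
    lon = LongitudinalParams(
        beta=np.array([16.89, 3.121, -0.1367, -0.0016]),
        b=np.array([0.0073, 0.0103, -0.0206, 0.0029, 0.0015, 0.0008])[: n_knots or 0],
        alpha1=np.array(
            [0.6834, -0.1650, 12.39, 4.936, 0.0608, -0.5984, -0.3695, -0.8114, -0.7705, -0.5673]
        ),
        sigma_eps2=59.24,
    )
    re = RandomEffectsDist(sigma0_sq=326.8, sigma1_sq=2.602, sigma01=-25.76)
    ev = EventParams(
        k=2.564,
        alpha2=np.array([-3.568, 0.0023, -0.0198, -0.2940, -0.5348, -0.2348, 0.1261, 0.1059]),
        theta0=-0.0086,
        theta1=-0.3532,
    )
    return JointParams(longitudinal=lon, re_dist=re, event=ev, spline=spline)
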