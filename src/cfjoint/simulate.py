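"""Synthetic CF-registry cohorts drawn from the joint generative model.

The generator emulates the structure of 2003-2011 US CF registry extracts:
patients enter at varying ages (median ~10.8 y), attend quarterly clinic
visits, have FEV1 generated from the spline mixed submodel around their
latent (U0, U1), and experience a first pulmonary exacerbation at a Weibull
time whose log hazard includes theta0*U0 + theta1*U1.  Longitudinal records
stop at the first event; administrative censoring reflects staggered entry
into a finite study window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import longitudinal_mean
from .params import BIRTH_COHORTS, JointParams, SubjectEffects, reference_params
from .registry import EmptyCohortError, Registry

AGE_MIN, AGE_MAX = 6.0, 45.0


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Prevalences follow reported 2003-2011 US registry cohort summaries
    (56% male, 35% lower SES, birth-cohort mix 13.5/15.3/27.9/43.3%,
    20.7% Pa and 2.5% B. cepacia at baseline, entry FEV1 ~ N(92.3, 19.6^2),
    median entry age 10.8 y).  Baseline MRSA/CFRD prevalence and the
    time-varying onset rates are not reported at baseline and are set to
    plausible CF-clinic values.  The administrative horizon is drawn
    uniformly on ``horizon_range`` to mimic staggered entry into a ~9-year
    registry window; visits arrive as a Poisson process at ``visit_rate``
    (quarterly clinic convention).
    """

    n_patients: int = 300
    visit_rate: float = 4.0  # visits per year
    entry_age_log_mu: float = float(np.log(4.8))  # entry age = 6 + LogNormal
    entry_age_log_sigma: float = 0.92
    entry_age_max: float = 40.0
    horizon_range: tuple[float, float] = (5.0, 9.0)  # administrative censoring, years
    p_male: float = 0.56
    p_low_ses: float = 0.35
    cohort_probs: tuple[float, ...] = (0.135, 0.153, 0.279, 0.433)
    p_baseline: dict = field(
        default_factory=lambda: {"cfrd": 0.10, "mrsa": 0.15, "b_cepacia": 0.025, "pa": 0.207}
    )
    onset_rate: dict = field(
        default_factory=lambda: {"cfrd": 0.02, "mrsa": 0.03, "b_cepacia": 0.003, "pa": 0.05}
    )
    baseline_fev1_mean: float = 92.3
    baseline_fev1_sd: float = 19.6
    params: JointParams = field(default_factory=reference_params)
    frailty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        probs = [self.p_male, self.p_low_ses, *self.p_baseline.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("prevalences must lie in [0, 1]")
        if abs(sum(self.cohort_probs) - 1.0) > 1e-9:
            raise ValueError("cohort_probs must sum to 1")
        if not self.horizon_range[1] >= self.horizon_range[0] > 0:
            raise ValueError("horizon must be positive")
        if self.frailty and self.params.re_dist.sigma3_sq <= 0:
            raise ValueError("frailty requested but sigma3_sq is 0")


@dataclass
class RawRegistry:
    """Simulated registry tables plus the latent truth (never fed to fits)."""

    long: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame | None = None  # per-patient U0, U1 (and U3, eta)
    true_params: JointParams | None = None

    def to_registry(self) -> Registry:
        return Registry(long=self.long.copy(), events=self.events.copy())


def weibull_time_from_uniform(u, eta, k: float):
    """Inverse-transform a Uniform(0,1) draw to a Weibull event time.

    Solves ``S(T) = exp(-T^k e^eta) = u``, i.e. ``T = (-log u / e^eta)^(1/k)``.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    u = np.asarray(u, dtype=float)
    return (-np.log(u) / np.exp(np.asarray(eta, float))) ** (1.0 / k)


def simulate_event_time(eta, k: float, rng: np.random.Generator):
    """Draw Weibull event time(s) with linear predictor ``eta`` and shape k."""
    eta = np.asarray(eta, dtype=float)
    u = rng.uniform(size=eta.shape if eta.shape else None)
    return weibull_time_from_uniform(u, eta, k)


def simulate_cohort(cfg: CohortConfig, rng: np.random.Generator | None = None) -> RawRegistry:
    """Generate a synthetic registry under the joint generative model.

    Per patient: draw entry age and covariates; draw (U0, U1) ~ N(0, Sigma)
    (plus frailty if enabled); simulate the exacerbation time from the
    Weibull hazard; censor administratively at the horizon or age 45; lay
    down Poisson-process visit ages up to the follow-up end; generate FEV1
    at each visit from the longitudinal mean plus N(0, sigma_eps^2) noise.
    Seed-reproducible via ``cfg.seed`` (or an explicit generator).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = cfg.params
    N = cfg.n_patients

    entry = AGE_MIN + rng.lognormal(cfg.entry_age_log_mu, cfg.entry_age_log_sigma, N)
    entry = np.minimum(entry, cfg.entry_age_max)
    male = (rng.random(N) < cfg.p_male).astype(int)
    low_ses = (rng.random(N) < cfg.p_low_ses).astype(int)
    cohort = rng.choice(len(BIRTH_COHORTS), size=N, p=np.asarray(cfg.cohort_probs))
    cohort_lab = np.asarray(BIRTH_COHORTS)[cohort]
    base_fev1 = rng.normal(cfg.baseline_fev1_mean, cfg.baseline_fev1_sd, N)

    Sigma = p.re_dist.Sigma
    U = rng.multivariate_normal(np.zeros(2), Sigma, size=N, method="eigh")
    U3 = (
        rng.normal(0.0, np.sqrt(p.re_dist.sigma3_sq), N)
        if cfg.frailty
        else np.zeros(N)
    )

    # event linear predictor (baseline covariates only)
    a2 = p.event.alpha2
    eta = (
        a2[0]
        + a2[1] * entry
        + a2[2] * base_fev1
        + a2[3] * male
        + a2[4] * (cohort == 0)
        + a2[5] * (cohort == 1)
        + a2[6] * (cohort == 2)
        + a2[7] * low_ses
        + p.event.theta0 * U[:, 0]
        + p.event.theta1 * U[:, 1]
        + U3
    )
    T_event = simulate_event_time(eta, p.event.k, rng)
    horizon = rng.uniform(*cfg.horizon_range, size=N)
    T_cens = np.minimum(horizon, AGE_MAX - entry)
    follow = np.minimum(T_event, T_cens)
    status = (T_event <= T_cens).astype(int)

    # infection / comorbidity onset ages (monotone 0 -> 1 processes)
    tv_names = ("cfrd", "mrsa", "b_cepacia", "pa")
    onset = {}
    for name in tv_names:
        at_base = rng.random(N) < cfg.p_baseline[name]
        later = entry + rng.exponential(1.0 / max(cfg.onset_rate[name], 1e-12), N)
        onset[name] = np.where(at_base, -np.inf, later)

    rows: list[dict] = []
    sd_eps = np.sqrt(p.longitudinal.sigma_eps2)
    for i in range(N):
        n_extra = rng.poisson(cfg.visit_rate * follow[i])
        offsets = np.sort(rng.uniform(0.0, follow[i], n_extra))
        visit_ages = entry[i] + np.concatenate([[0.0], offsets])
        tv = {name: (visit_ages >= onset[name][i]).astype(int) for name in tv_names}
        x = np.column_stack(
            [
                np.full_like(visit_ages, base_fev1[i]),
                np.full_like(visit_ages, male[i]),
                np.full_like(visit_ages, float(cohort[i] == 0)),
                np.full_like(visit_ages, float(cohort[i] == 1)),
                np.full_like(visit_ages, float(cohort[i] == 2)),
                np.full_like(visit_ages, low_ses[i]),
                tv["cfrd"],
                tv["mrsa"],
                tv["b_cepacia"],
                tv["pa"],
            ]
        )
        mu = longitudinal_mean(p, visit_ages, x, (U[i, 0], U[i, 1]))
        fev1 = mu + rng.normal(0.0, sd_eps, visit_ages.size)
        for j, a in enumerate(visit_ages):
            rows.append(
                {
                    "patient_id": i + 1,
                    "age": a,
                    "fev1": fev1[j],
                    "male": male[i],
                    "birth_cohort": cohort_lab[i],
                    "low_ses": low_ses[i],
                    "cfrd": tv["cfrd"][j],
                    "mrsa": tv["mrsa"][j],
                    "b_cepacia": tv["b_cepacia"][j],
                    "pa": tv["pa"][j],
                }
            )
    long = pd.DataFrame(rows)
    events = pd.DataFrame(
        {
            "patient_id": np.arange(1, N + 1),
            "time": follow,
            "status": status,
            "baseline_age": entry,
            "baseline_fev1": base_fev1,
            "male": male,
            "birth_cohort": cohort_lab,
            "low_ses": low_ses,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": np.arange(1, N + 1),
            "U0": U[:, 0],
            "U1": U[:, 1],
            "U3": U3,
            "eta": eta,
            "event_time_latent": T_event,
        }
    )
    return RawRegistry(long=long, events=events, truth=truth, true_params=p)


def apply_cohort_filters(
    raw: RawRegistry,
    min_visits: int = 10,
    age_range: tuple[float, float] = (AGE_MIN, AGE_MAX),
    min_visits_before_truncation: bool = False,
) -> tuple[RawRegistry, pd.DataFrame]:
    """Apply the registry inclusion rules; return (filtered, exclusion log).

    Rules, in order: (1) drop visits outside the closed age window;
    (2) truncate each patient's longitudinal records at the first recorded
    exacerbation; (3) drop patients with fewer than ``min_visits`` retained
    FEV1 measurements.  Baseline age/FEV1 are (re)set from the first
    retained visit.  This order is idempotent; set
    ``min_visits_before_truncation=True`` to count visits before event
    truncation instead (not idempotent for patients with early events).

    The exclusion log has one row per dropped visit or patient with columns
    ``patient_id, level, reason, n``.
    """
    long = raw.long.sort_values(["patient_id", "age"], kind="mergesort").copy()
    events = raw.events.copy()
    log_rows: list[dict] = []
    lo, hi = age_range

    def _log(pid, level, reason, n=1):
        log_rows.append({"patient_id": pid, "level": level, "reason": reason, "n": n})

    # 1. age window (closed bounds)
    out = (long["age"] < lo) | (long["age"] > hi)
    for pid, n in long.loc[out, "patient_id"].value_counts().items():
        _log(pid, "visit", "age_outside_window", int(n))
    long = long[~out]

    steps = ["truncate", "min_visits"]
    if min_visits_before_truncation:
        steps = ["min_visits", "truncate"]

    for step in steps:
        if step == "min_visits":
            counts = long.groupby("patient_id").size()
            bad = counts[counts < min_visits].index
            no_visits = set(events["patient_id"]) - set(counts.index)
            for pid in list(bad) + sorted(no_visits):
                _log(pid, "patient", "fewer_than_min_visits")
            long = long[~long["patient_id"].isin(set(bad) | no_visits)]
            events = events[events["patient_id"].isin(long["patient_id"].unique())]
        else:
            # baseline from first retained visit, then truncate at first event
            first = long.groupby("patient_id")["age"].min()
            ev = events.set_index("patient_id")
            event_age = first + ev["time"]
            cut = long["patient_id"].map(event_age)
            is_event = long["patient_id"].map(ev["status"]).astype(bool)
            late = is_event & (long["age"] > cut + 1e-9)
            for pid, n in long.loc[late, "patient_id"].value_counts().items():
                _log(pid, "visit", "after_first_exacerbation", int(n))
            long = long[~late]

    if len(long) == 0:
        raise EmptyCohortError("no records remain after cohort filters")

    # reset baseline covariates from the first retained visit
    first_rows = long.groupby("patient_id").first()
    events = events[events["patient_id"].isin(first_rows.index)].copy()
    events["baseline_age"] = events["patient_id"].map(first_rows["age"])
    events["baseline_fev1"] = events["patient_id"].map(first_rows["fev1"])

    truth = None
    if raw.truth is not None:
        truth = raw.truth[raw.truth["patient_id"].isin(first_rows.index)].copy()
    excl = pd.DataFrame(log_rows, columns=["patient_id", "level", "reason", "n"])
    filtered = RawRegistry(
        long=long.reset_index(drop=True),
        events=events.reset_index(drop=True),
        truth=truth,
        true_params=raw.true_params,
    )
    if filtered.long.isna().any().any():
        warnings.warn("filtered longitudinal table contains missing values")
    return filtered, excl
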