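"""Model comparison via the deviance information criterion (DIC).

Deviance is conditioned on the per-patient random effects (the plug-in,
WinBUGS-style convention): D = -2 log L(submodel | parameters, U).  For each
submodel, DIC = Dbar + pD with Dbar the posterior mean deviance and
pD = Dbar - D(posterior means of everything conditioned on, including the
random effects).  The conditional convention makes pD grow with the number
of patients, reflecting the effective cost of the latent effects.

Also provides the head-to-head fits: separate (no shared effects), joint
(cubic and semiparametric), and the two-stage sensitivity variant where
posterior-mean random effects from a longitudinal-only fit are plugged into
the event submodel as fixed covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import SplineSpec
from .mcmc import FitReport, MCMCConfig, PosteriorDraws, run_mcmc, summarize
from .params import EVENT_COVARIATES, LONG_COVARIATES, PriorSpec
from .registry import Registry

COMPARISON_VARIANTS = ("separate", "joint-cubic", "joint-semiparametric", "two-stage")


@dataclass
class DICComponents:
    dbar: float
    pd: float

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


@dataclass
class DICReport:
    """Per-submodel DIC components and their total for one model variant."""

    model: str
    longitudinal: DICComponents | None
    event: DICComponents | None

    @property
    def dic_total(self) -> float:
        total = 0.0
        for part in (self.longitudinal, self.event):
            if part is not None:
                total += part.dic
        return total

    def to_row(self) -> dict:
        row: dict = {"model": self.model}
        if self.longitudinal is not None:
            row.update(
                DIC1=self.longitudinal.dic,
                Dbar1=self.longitudinal.dbar,
                pD1=self.longitudinal.pd,
            )
        if self.event is not None:
            row.update(DIC2=self.event.dic, Dbar2=self.event.dbar, pD2=self.event.pd)
        row["DIC_total"] = self.dic_total
        return row


# ---------------------------------------------------------------------------
# deviance evaluation
# ---------------------------------------------------------------------------


def _long_deviance(registry: Registry, spline: SplineSpec, coef, sigma_eps2, U) -> float:
    X, y, ages = registry.long_design(spline)
    pidx = registry.patient_index()
    mean = X @ coef + U[pidx, 0] + U[pidx, 1] * ages
    r = y - mean
    return float(y.size * np.log(2.0 * np.pi * sigma_eps2) + (r @ r) / sigma_eps2)


def _event_deviance(registry: Registry, k, alpha2, theta, U, U3=None) -> float:
    X2, t, status = registry.event_design()
    eta = X2 @ alpha2
    if theta is not None:
        eta = eta + theta[0] * U[:, 0] + theta[1] * U[:, 1]
    if U3 is not None:
        eta = eta + U3
    logh = np.log(k) + (k - 1.0) * np.log(t) + eta
    return float(-2.0 * (status @ logh - np.sum(t**k * np.exp(eta))))


def dic_components(
    draws: PosteriorDraws, registry: Registry, submodel: str
) -> DICComponents:
    """DIC components for one submodel from stored draws.

    ``submodel`` is ``"longitudinal"`` or ``"event"``.  Dbar uses the
    per-draw deviance trace recorded during sampling; the plug-in deviance
    is recomputed at the posterior means of the parameters and random
    effects.
    """
    if submodel not in ("longitudinal", "event"):
        raise ValueError("submodel must be 'longitudinal' or 'event'")
    dev_name = "deviance_long" if submodel == "longitudinal" else "deviance_event"
    if not draws.has(dev_name):
        raise ValueError(f"draws for variant {draws.variant!r} lack {dev_name}")
    if draws.patient_ids is not None and len(draws.patient_ids) != registry.n_patients:
        raise ValueError("draws and registry cohorts do not match")
    dbar = float(draws.get(dev_name).mean())
    Umean = draws.U_flat().mean(axis=0) if draws.U is not None else np.zeros((registry.n_patients, 2))
    U3mean = draws.U3.reshape(-1, registry.n_patients).mean(axis=0) if draws.U3 is not None else None
    if submodel == "longitudinal":
        K = draws.spline.n_knots
        coef = np.array(
            [draws.mean(f"beta{i}") for i in range(4)]
            + [draws.mean(f"b{m + 1}") for m in range(K)]
            + [draws.mean(f"alpha1_{c}") for c in LONG_COVARIATES]
        )
        dhat = _long_deviance(
            registry, draws.spline, coef, draws.mean("sigma_eps2"), Umean
        )
    else:
        alpha2 = np.array([draws.mean(f"alpha2_{c}") for c in EVENT_COVARIATES])
        theta = None
        U = Umean
        if draws.has("theta0"):
            theta = (draws.mean("theta0"), draws.mean("theta1"))
            if draws.U is None:  # two-stage: plug-in effects live in meta
                U = np.asarray(draws.meta["plug_in_effects"], dtype=float)
        dhat = _event_deviance(registry, draws.mean("k"), alpha2, theta, U, U3mean)
    return DICComponents(dbar=dbar, pd=dbar - dhat)


# ---------------------------------------------------------------------------
# fit drivers
# ---------------------------------------------------------------------------


def fit_joint(
    registry: Registry,
    spline: SplineSpec | int | None = None,
    cubic: bool = False,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    frailty: bool = False,
) -> tuple[FitReport, DICReport, PosteriorDraws]:
    """Fit a joint variant and report posterior summaries plus DIC."""
    variant = "joint-cubic" if cubic else "joint-semiparametric"
    draws = run_mcmc(registry, variant, spline=spline, prior=prior, config=config, frailty=frailty)
    report = summarize(draws)
    dic = DICReport(
        model=variant,
        longitudinal=dic_components(draws, registry, "longitudinal"),
        event=dic_components(draws, registry, "event"),
    )
    report.dic = dic
    return report, dic, draws


def fit_separate(
    registry: Registry,
    spline: SplineSpec | int | None = None,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> tuple[FitReport, FitReport, DICReport, tuple[PosteriorDraws, PosteriorDraws]]:
    """Fit the longitudinal and event submodels independently.

    The longitudinal fit keeps its random effects; the event fit has no
    shared term (W2 = 0), so it never sees the FEV1 data.
    """
    cfg = config if config is not None else MCMCConfig()
    d_long = run_mcmc(registry, "separate-longitudinal", spline=spline, prior=prior, config=cfg)
    d_event = run_mcmc(registry, "separate-event", prior=prior, config=cfg)
    rep_long, rep_event = summarize(d_long), summarize(d_event)
    dic = DICReport(
        model="separate",
        longitudinal=dic_components(d_long, registry, "longitudinal"),
        event=dic_components(d_event, registry, "event"),
    )
    rep_long.dic = dic
    return rep_long, rep_event, dic, (d_long, d_event)


def fit_two_stage(
    registry: Registry,
    spline: SplineSpec | int | None = None,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> tuple[FitReport, DICReport, tuple[PosteriorDraws, PosteriorDraws]]:
    """Two-stage sensitivity fit.

    Stage 1 fits the longitudinal submodel alone; stage 2 fits the Weibull
    submodel with each patient's posterior-mean (U0, U1) plugged in as fixed
    covariates whose coefficients are theta0, theta1.  Unlike the joint fit,
    uncertainty in the random effects does not propagate to stage 2, which
    attenuates the estimated association.
    """
    cfg = config if config is not None else MCMCConfig()
    d_long = run_mcmc(registry, "separate-longitudinal", spline=spline, prior=prior, config=cfg)
    Uhat = d_long.U_flat().mean(axis=0)
    plug = pd.DataFrame(Uhat, columns=["U0", "U1"], index=d_long.patient_ids)
    d_event = run_mcmc(
        registry, "separate-event", prior=prior, config=cfg, plug_in_effects=plug
    )
    d_event.meta["plug_in_effects"] = Uhat
    rep = summarize(d_event)
    dic = DICReport(
        model="two-stage",
        longitudinal=dic_components(d_long, registry, "longitudinal"),
        event=dic_components(d_event, registry, "event"),
    )
    rep.dic = dic
    return rep, dic, (d_long, d_event)


def compare_models(
    registry: Registry,
    variants: list[str] = list(COMPARISON_VARIANTS),
    spline: SplineSpec | int | None = None,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> pd.DataFrame:
    """Fit the requested variants and rank them by total DIC (ascending).

    Lower DIC indicates better fit after accounting for effective model
    complexity.
    """
    if len(variants) < 2:
        raise ValueError("need at least two model variants to compare")
    unknown = set(variants) - set(COMPARISON_VARIANTS)
    if unknown:
        raise ValueError(f"unknown comparison variants: {sorted(unknown)}")
    rows = []
    for variant in variants:
        if variant == "separate":
            *_, dic, _d = fit_separate(registry, spline=spline, prior=prior, config=config)
        elif variant == "two-stage":
            _, dic, _d = fit_two_stage(registry, spline=spline, prior=prior, config=config)
        else:
            _, dic, _d = fit_joint(
                registry,
                spline=spline,
                cubic=(variant == "joint-cubic"),
                prior=prior,
                config=config,
            )
        rows.append(dic.to_row())
    table = pd.DataFrame(rows).sort_values("DIC_total", kind="mergesort")
    return table.reset_index(drop=True)
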