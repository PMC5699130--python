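"""Posterior sampling for the joint model.

The reference backend is a blocked Metropolis-within-Gibbs sampler written in
numpy: fixed effects, variance components and the random-effects covariance
have conjugate updates (Gaussian, inverse-gamma, Wishart); per-patient random
effects use a vectorized bivariate random-walk Metropolis step (exact
conjugate draws when no event submodel is attached); the Weibull block
(log k, event coefficients, association parameters) uses component-wise
adaptive random-walk Metropolis.  Proposal scales adapt only during burn-in,
so the retained chain targets the exact posterior.

Internally the event covariates are mean-centered and follow-up times are
scaled by their geometric mean to decorrelate the Weibull shape from the
intercept; draws are transformed back before being recorded, so recorded
parameters are always on the natural scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SplineSpec, choose_knots
from .params import (
    EVENT_COVARIATES,
    LONG_COVARIATES,
    PriorSpec,
)
from .registry import Registry

VARIANTS = (
    "joint-semiparametric",
    "joint-cubic",
    "separate-longitudinal",
    "separate-event",
)

_TARGET_ACC_1D = 0.40  # scalar random-walk target acceptance
_TARGET_ACC_2D = 0.30  # bivariate random-effect target acceptance


@dataclass
class MCMCConfig:
    """Chain settings.  The default run is 2 chains of 6,000 iterations with a
    1,000-iteration burn-in and no thinning."""

    n_chains: int = 2
    n_iterations: int = 6000
    n_burnin: int = 1000
    thinning: int = 1
    seed: int = 0
    backend: str = "gibbs"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.backend != "gibbs":
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thinning - 1) // self.thinning


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: scalar parameters plus per-patient effects."""

    params: np.ndarray  # (n_chains, n_kept, n_params)
    names: list[str]
    U: np.ndarray | None  # (n_chains, n_kept, n_patients, 2) or None
    patient_ids: np.ndarray | None
    variant: str
    spline: SplineSpec | None
    meta: dict = field(default_factory=dict)
    U3: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.params.ndim != 3 or self.params.shape[2] != len(self.names):
            raise ValueError("params must be (chains, draws, names)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("draws contain non-finite values")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_draws(self) -> int:
        return self.params.shape[0] * self.params.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Flat (all-chain) draw vector for one scalar parameter."""
        return self.params[:, :, self._index[name]].reshape(-1)

    def get_chains(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) draws for one scalar parameter."""
        return self.params[:, :, self._index[name]]

    def has(self, name: str) -> bool:
        return name in self._index

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def U_flat(self) -> np.ndarray:
        """(n_draws, n_patients, 2) random-effect draws across chains."""
        if self.U is None:
            raise ValueError(f"variant {self.variant!r} has no random-effect draws")
        return self.U.reshape(-1, *self.U.shape[2:])

    def to_dataframe(self) -> pd.DataFrame:
        flat = self.params.reshape(-1, len(self.names))
        df = pd.DataFrame(flat, columns=self.names)
        nc, nk = self.params.shape[:2]
        df.insert(0, "chain", np.repeat(np.arange(nc), nk))
        df.insert(1, "draw", np.tile(np.arange(nk), nc))
        return df


@dataclass
class FitReport:
    """Posterior summary table plus diagnostics (and DIC when attached)."""

    table: pd.DataFrame  # index: parameter; mean, hpd_low, hpd_high, rhat, ess
    variant: str
    meta: dict = field(default_factory=dict)
    dic: object | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"FitReport[{self.variant}]\n" + self.table.to_string(float_format="%.4g")


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties in width are broken toward the smallest lower endpoint.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))  # argmin takes the first (smallest lower) tie
    return float(x[j]), float(x[j + m - 1])


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _draw_wishart_2x2(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bartlett draw of a 2x2 Wishart(df, scale) matrix."""
    L = np.linalg.cholesky(scale)
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.normal()
    LA = L @ A
    return LA @ LA.T


def _inv_2x2(M: np.ndarray) -> np.ndarray:
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det


class _AdaptiveScale:
    """Robbins-Monro log-scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, init: float, target: float):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.it = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.it += 1
        gamma = min(0.25, 2.0 / np.sqrt(self.it))
        self.log_s += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -12.0, 6.0, out=self.log_s)


class _ChainState:
    """One chain of the blocked Gibbs sampler (see module docstring)."""

    def __init__(self, problem: "_Problem", rng: np.random.Generator):
        self.pb = problem
        self.rng = rng
        self._initialize()

    # -- initialization -------------------------------------------------
    def _initialize(self) -> None:
        pb, rng = self.pb, self.rng
        fixed = pb.fixed
        if pb.has_long:
            XtX = pb.XtX + 1e-8 * np.eye(pb.p_long)
            self.phi = np.linalg.solve(XtX, pb.X.T @ pb.y)
            resid = pb.y - pb.X @ self.phi
            self.sigma_eps2 = float(fixed.get("sigma_eps2", max(np.var(resid), 1e-6)))
            if pb.K > 0:
                self.sigma_b2 = max(float(np.var(self.phi[4 : 4 + pb.K])), 1e-6)
            else:
                self.sigma_b2 = None
            self.U = np.zeros((pb.n_pat, 2))
            if "Sigma" in fixed:
                self.Sigma = np.asarray(fixed["Sigma"], dtype=float)
            else:
                v0, v1 = self._moment_re_variances(resid)
                self.Sigma = np.array([[v0, 0.0], [0.0, v1]])
            self.Sigma_inv = _inv_2x2(self.Sigma)
            self.u_scale = _AdaptiveScale(pb.n_pat, 0.3, _TARGET_ACC_2D)
        if pb.has_event:
            total = pb.ts.sum()
            rate = max(pb.status.sum(), 0.5) / max(total, 1e-12)
            self.psi = np.zeros(pb.n_psi)
            self.psi[pb.i_logk] = np.log(float(fixed.get("k", 1.0)))
            self.psi[pb.i_alpha0] = np.log(rate)
            if pb.i_theta is not None:
                self.psi[pb.i_theta] = [
                    float(fixed.get("theta0", 0.0)),
                    float(fixed.get("theta1", 0.0)),
                ]
            self.psi_scale = _AdaptiveScale(pb.n_psi, 0.05, _TARGET_ACC_1D)
        if pb.frailty:
            self.U3 = np.zeros(pb.n_pat)
            self.sigma3_sq = 1.0
            self.u3_scale = _AdaptiveScale(pb.n_pat, 0.3, _TARGET_ACC_1D)

    def _moment_re_variances(self, resid: np.ndarray) -> tuple[float, float]:
        """Method-of-moments starting variances from per-patient OLS lines."""
        pb = self.pb
        S_r = np.bincount(pb.pidx, resid, minlength=pb.n_pat)
        S_ra = np.bincount(pb.pidx, resid * pb.ages, minlength=pb.n_pat)
        det = pb.n_i * pb.S_aa - pb.S_a**2
        ok = (pb.n_i >= 3) & (det > 1e-8)
        if ok.sum() < 2:
            return 100.0, 1.0
        b0 = (pb.S_aa[ok] * S_r[ok] - pb.S_a[ok] * S_ra[ok]) / det[ok]
        b1 = (pb.n_i[ok] * S_ra[ok] - pb.S_a[ok] * S_r[ok]) / det[ok]
        return max(float(np.var(b0)), 1.0), max(float(np.var(b1)), 0.01)

    # -- conjugate updates ----------------------------------------------
    def update_fixed_effects(self) -> None:
        pb, rng = self.pb, self.rng
        prior_prec = np.full(pb.p_long, 1.0 / pb.prior.coef_var)
        if pb.K > 0:
            prior_prec[4 : 4 + pb.K] = 1.0 / self.sigma_b2
        resid_u = pb.y - self.U[pb.pidx, 0] - self.U[pb.pidx, 1] * pb.ages
        A = pb.XtX / self.sigma_eps2 + np.diag(prior_prec)
        rhs = pb.X.T @ resid_u / self.sigma_eps2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, rhs)
        z = rng.standard_normal(pb.p_long)
        self.phi = mean + np.linalg.solve(L.T, z)
        self.resid = pb.y - pb.X @ self.phi

    def update_variances(self) -> None:
        pb, rng = self.pb, self.rng
        r = self.resid - self.U[pb.pidx, 0] - self.U[pb.pidx, 1] * pb.ages
        self.ssr = float(r @ r)
        if "sigma_eps2" not in pb.fixed:
            a = pb.prior.var_a + 0.5 * pb.n_obs
            b = pb.prior.var_b + 0.5 * self.ssr
            self.sigma_eps2 = b / rng.gamma(a)
        if pb.K > 0:
            bvec = self.phi[4 : 4 + pb.K]
            a = pb.prior.spline_a + 0.5 * pb.K
            b = pb.prior.spline_b + 0.5 * float(bvec @ bvec)
            self.sigma_b2 = b / rng.gamma(a)

    def update_Sigma(self) -> None:
        pb, rng = self.pb, self.rng
        if "Sigma" in pb.fixed:
            return
        S = pb.prior.wishart_scale + self.U.T @ self.U
        prec = _draw_wishart_2x2(pb.prior.wishart_df + pb.n_pat, _inv_2x2(S), rng)
        self.Sigma = _inv_2x2(prec)
        self.Sigma_inv = prec

    # -- random effects --------------------------------------------------
    def _patient_suffstats(self):
        pb = self.pb
        S_r = np.bincount(pb.pidx, self.resid, minlength=pb.n_pat)
        S_ra = np.bincount(pb.pidx, self.resid * pb.ages, minlength=pb.n_pat)
        S_rr = np.bincount(pb.pidx, self.resid**2, minlength=pb.n_pat)
        return S_r, S_ra, S_rr

    def update_U_conjugate(self) -> None:
        """Exact bivariate-normal draw of (U0, U1) when no event submodel."""
        pb, rng = self.pb, self.rng
        S_r, S_ra, _ = self._patient_suffstats()
        s2 = self.sigma_eps2
        a = pb.n_i / s2 + self.Sigma_inv[0, 0]
        c = pb.S_a / s2 + self.Sigma_inv[0, 1]
        d = pb.S_aa / s2 + self.Sigma_inv[1, 1]
        b0, b1 = S_r / s2, S_ra / s2
        det = a * d - c * c
        m0 = (d * b0 - c * b1) / det
        m1 = (a * b1 - c * b0) / det
        # chol of per-patient precision A = [[a, c], [c, d]]
        l00 = np.sqrt(a)
        l10 = c / l00
        l11 = np.sqrt(d - l10**2)
        z0 = rng.standard_normal(pb.n_pat)
        z1 = rng.standard_normal(pb.n_pat)
        # solve L^T x = z
        x1 = z1 / l11
        x0 = (z0 - l10 * x1) / l00
        self.U = np.column_stack([m0 + x0, m1 + x1])

    def update_U_mh(self, adapt: bool) -> None:
        """Vectorized per-patient Metropolis step (joint model)."""
        pb, rng = self.pb, self.rng
        S_r, S_ra, _ = self._patient_suffstats()
        k = np.exp(self.psi[pb.i_logk])
        th0, th1 = self.psi[pb.i_theta]
        eta_x = self._eta_covariates()
        lam0 = pb.ts**k * np.exp(eta_x + (self.U3 if pb.frailty else 0.0))
        Lp = np.linalg.cholesky(self.Sigma + 1e-10 * np.eye(2))
        step = (rng.standard_normal((pb.n_pat, 2)) @ Lp.T) * self.u_scale.scale[:, None]
        Up = self.U + step

        def logpost(U):
            u0, u1 = U[:, 0], U[:, 1]
            ll = (
                -(0.5 / self.sigma_eps2)
                * (
                    -2 * u0 * S_r
                    - 2 * u1 * S_ra
                    + 2 * u0 * u1 * pb.S_a
                    + u0**2 * pb.n_i
                    + u1**2 * pb.S_aa
                )
            )
            w2 = th0 * u0 + th1 * u1
            ll += pb.status * w2 - lam0 * np.exp(w2)
            Si = self.Sigma_inv
            ll -= 0.5 * (
                Si[0, 0] * u0**2 + 2 * Si[0, 1] * u0 * u1 + Si[1, 1] * u1**2
            )
            return ll

        logr = logpost(Up) - logpost(self.U)
        acc = np.log(rng.random(pb.n_pat)) < logr
        self.U[acc] = Up[acc]
        if adapt:
            self.u_scale.update(acc)

    def update_U3(self, adapt: bool) -> None:
        pb, rng = self.pb, self.rng
        k = np.exp(self.psi[pb.i_logk])
        th0, th1 = self.psi[pb.i_theta] if pb.i_theta is not None else (0.0, 0.0)
        base = self._eta_covariates() + th0 * self.U[:, 0] + th1 * self.U[:, 1]
        lam0 = pb.ts**k * np.exp(base)
        prop = self.U3 + rng.standard_normal(pb.n_pat) * self.u3_scale.scale
        s3 = self.sigma3_sq

        def lp(u3):
            return pb.status * u3 - lam0 * np.exp(u3) - 0.5 * u3**2 / s3

        logr = lp(prop) - lp(self.U3)
        acc = np.log(rng.random(pb.n_pat)) < logr
        self.U3[acc] = prop[acc]
        if adapt:
            self.u3_scale.update(acc)
        a = pb.prior.var_a + 0.5 * pb.n_pat
        b = pb.prior.var_b + 0.5 * float(self.U3 @ self.U3)
        self.sigma3_sq = b / rng.gamma(a)

    # -- event block -----------------------------------------------------
    def _eta_covariates(self) -> np.ndarray:
        """Event linear predictor from centered covariates (no U, no frailty)."""
        pb = self.pb
        return pb.X2c @ self.psi[pb.i_alpha]

    def _eta_full(self) -> np.ndarray:
        pb = self.pb
        eta = self._eta_covariates()
        if pb.i_theta is not None:
            th0, th1 = self.psi[pb.i_theta]
            eta = eta + th0 * pb.theta_cols[:, 0] + th1 * pb.theta_cols[:, 1]
        if pb.frailty:
            eta = eta + self.U3
        return eta

    def _event_loglik_prior(self, psi: np.ndarray, eta: np.ndarray, tsk: np.ndarray) -> float:
        """Scaled-time event log-likelihood + log prior of the block."""
        pb = self.pb
        k = np.exp(psi[pb.i_logk])
        ll = (
            pb.status.sum() * psi[pb.i_logk]
            + (k - 1.0) * pb.status_tl
            + float(pb.status @ eta)
            - float(tsk @ np.exp(eta))
        )
        # prior on the natural scale
        a_orig = psi[pb.i_alpha].copy()
        a_orig[0] = a_orig[0] - a_orig[1:] @ pb.x2_mean[1:] - k * pb.log_tref
        lp = -0.5 * float(a_orig @ a_orig) / pb.prior.coef_var
        if pb.i_theta is not None:
            th = psi[pb.i_theta]
            lp += -0.5 * float(th @ th) / pb.prior.coef_var
        # Gamma(k_shape, k_rate) prior on k, plus Jacobian for log-k sampling
        lp += (pb.prior.k_shape - 1.0) * np.log(k) - pb.prior.k_rate * k + np.log(k)
        return ll + lp

    def update_event_block(self, adapt: bool) -> None:
        pb, rng = self.pb, self.rng
        if pb.i_theta is not None and not pb.plug_in:
            pb.theta_cols = self.U
        eta = self._eta_full()
        k = np.exp(self.psi[pb.i_logk])
        tsk = pb.ts**k
        cur = self._event_loglik_prior(self.psi, eta, tsk)
        acc_flags = np.zeros(pb.n_psi)
        scales = self.psi_scale.scale
        order = pb.update_coords
        for j in order:
            if j == pb.i_logk and "k" in pb.fixed:
                continue
            if pb.i_theta is not None and j in pb.i_theta_list and pb.theta_fixed[j]:
                continue
            prop = self.psi.copy()
            prop[j] = prop[j] + rng.standard_normal() * scales[j]
            if j == pb.i_logk:
                tsk_p = pb.ts ** np.exp(prop[j])
                eta_p = eta
            else:
                tsk_p = tsk
                if j in pb.i_alpha_list:
                    col = pb.X2c[:, j - 1]
                else:
                    col = pb.theta_cols[:, j - pb.i_theta.start]
                eta_p = eta + (prop[j] - self.psi[j]) * col
            new = self._event_loglik_prior(prop, eta_p, tsk_p)
            if np.log(rng.random()) < new - cur:
                self.psi = prop
                eta, tsk, cur = eta_p, tsk_p, new
                acc_flags[j] = 1.0
        if adapt:
            self.psi_scale.update(acc_flags)
        self._eta_cache = eta
        self._tsk_cache = tsk

    # -- recording -------------------------------------------------------
    def record(self) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
        pb = self.pb
        out = np.empty(len(pb.param_names))
        pos = 0
        if pb.has_long:
            out[pos : pos + pb.p_long] = self.phi
            pos += pb.p_long
            out[pos] = self.sigma_eps2
            pos += 1
            if pb.K > 0:
                out[pos] = self.sigma_b2
                pos += 1
            out[pos : pos + 3] = (self.Sigma[0, 0], self.Sigma[1, 1], self.Sigma[0, 1])
            pos += 3
            if pb.frailty:
                out[pos] = self.sigma3_sq
                pos += 1
            # longitudinal deviance (conditional on random effects)
            dev1 = pb.n_obs * np.log(2.0 * np.pi * self.sigma_eps2) + self.ssr / self.sigma_eps2
            out[pos] = dev1
            pos += 1
        if pb.has_event:
            k = np.exp(self.psi[pb.i_logk])
            a_orig = self.psi[pb.i_alpha].copy()
            a_orig[0] = a_orig[0] - a_orig[1:] @ pb.x2_mean[1:] - k * pb.log_tref
            out[pos] = k
            pos += 1
            out[pos : pos + a_orig.size] = a_orig
            pos += a_orig.size
            if pb.i_theta is not None:
                out[pos : pos + 2] = self.psi[pb.i_theta]
                pos += 2
            # event deviance in natural time units
            eta_orig = self._eta_full() - k * pb.log_tref
            logh = np.log(k) + (k - 1.0) * pb.log_t + eta_orig
            dev2 = -2.0 * float(pb.status @ logh - np.sum(pb.t**k * np.exp(eta_orig)))
            out[pos] = dev2
            pos += 1
        U = self.U.copy() if pb.has_long else None
        U3 = self.U3.copy() if pb.frailty else None
        return out, U, U3

    # -- one sweep -------------------------------------------------------
    def sweep(self, adapt: bool) -> None:
        pb = self.pb
        if pb.has_long:
            self.update_fixed_effects()
            if pb.has_event and not pb.plug_in:
                self.update_U_mh(adapt)
            else:
                self.update_U_conjugate()
            self.update_variances()
            self.update_Sigma()
        if pb.has_event:
            self.update_event_block(adapt)
        if pb.frailty:
            self.update_U3(adapt)


class _Problem:
    """Immutable data/design bundle shared by all chains."""

    def __init__(
        self,
        registry: Registry,
        variant: str,
        spline: SplineSpec | None,
        prior: PriorSpec,
        fixed: dict,
        plug_in_effects: pd.DataFrame | None,
        frailty: bool,
    ):
        self.variant = variant
        self.prior = prior
        self.fixed = fixed
        self.frailty = frailty
        self.plug_in = plug_in_effects is not None
        self.has_long = variant != "separate-event"
        self.has_event = variant != "separate-longitudinal"
        self.n_pat = registry.n_patients
        self.patient_ids = registry.patient_ids
        self.spline = spline

        names: list[str] = []
        if self.has_long:
            X, y, ages = registry.long_design(spline)
            self.X, self.y, self.ages = X, y, ages
            self.pidx = registry.patient_index()
            self.n_obs = y.size
            self.p_long = X.shape[1]
            self.K = spline.n_knots
            self.XtX = X.T @ X
            self.n_i = np.bincount(self.pidx, minlength=self.n_pat).astype(float)
            self.S_a = np.bincount(self.pidx, ages, minlength=self.n_pat)
            self.S_aa = np.bincount(self.pidx, ages**2, minlength=self.n_pat)
            names += [f"beta{i}" for i in range(4)]
            names += [f"b{m + 1}" for m in range(self.K)]
            names += [f"alpha1_{c}" for c in LONG_COVARIATES]
            names += ["sigma_eps2"]
            if self.K > 0:
                names += ["sigma_b2"]
            names += ["sigma0_sq", "sigma1_sq", "sigma01"]
            if frailty:
                names += ["sigma3_sq"]
            names += ["deviance_long"]
        if self.has_event:
            X2, t, status = registry.event_design()
            self.t, self.status = t, status.astype(float)
            self.log_t = np.log(t)
            self.log_tref = float(self.log_t.mean())
            self.ts = t / np.exp(self.log_tref)
            self.status_tl = float(self.status @ (self.log_t - self.log_tref))
            self.x2_mean = X2.mean(axis=0)
            self.x2_mean[0] = 0.0  # keep the intercept column untouched
            self.X2c = X2 - self.x2_mean
            p2 = X2.shape[1]
            self.i_logk = 0
            self.i_alpha = slice(1, 1 + p2)
            self.i_alpha0 = 1
            self.i_alpha_list = set(range(1, 1 + p2))
            with_theta = (variant.startswith("joint")) or self.plug_in
            if with_theta:
                self.i_theta = slice(1 + p2, 3 + p2)
                self.i_theta_list = {1 + p2, 2 + p2}
                self.n_psi = 3 + p2
                self.theta_fixed = {
                    1 + p2: "theta0" in fixed,
                    2 + p2: "theta1" in fixed,
                }
                if self.plug_in:
                    pe = plug_in_effects.reindex(self.patient_ids)
                    if pe.isna().any().any():
                        raise ValueError("plug-in effects missing for some patients")
                    self.theta_cols = pe[["U0", "U1"]].to_numpy(float)
                else:
                    self.theta_cols = np.zeros((self.n_pat, 2))  # rebound each sweep
            else:
                self.i_theta = None
                self.i_theta_list = set()
                self.n_psi = 1 + p2
                self.theta_fixed = {}
            self.update_coords = [j for j in range(self.n_psi)]
            names += ["k"]
            names += [f"alpha2_{c}" for c in EVENT_COVARIATES]
            if with_theta:
                names += ["theta0", "theta1"]
            names += ["deviance_event"]
        self.param_names = names


def _resolve_spline(registry: Registry, variant: str, spline) -> SplineSpec | None:
    if variant == "separate-event":
        return None
    if variant == "joint-cubic":
        return SplineSpec(knots=())
    if spline is None:
        spline = 6
    if isinstance(spline, int):
        return choose_knots(registry.long["age"].to_numpy(float), spline)
    return spline


def run_mcmc(
    registry: Registry,
    variant: str = "joint-semiparametric",
    spline: SplineSpec | int | None = None,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict | None = None,
    plug_in_effects: pd.DataFrame | None = None,
    frailty: bool = False,
    progress: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of the selected model variant.

    Parameters
    ----------
    variant
        One of ``joint-semiparametric``, ``joint-cubic``,
        ``separate-longitudinal``, ``separate-event``.
    spline
        A :class:`SplineSpec`, a knot count (quantile placement), or None
        for the 6-knot default.  Ignored for the cubic and event-only
        variants.
    fixed
        Optional parameters to hold fixed (e.g. ``{"sigma_eps2": 59.2}`` or
        ``{"theta0": 0.0, "theta1": 0.0}``), mainly for validation studies.
    plug_in_effects
        For the two-stage event fit: per-patient posterior-mean ``U0, U1``
        (DataFrame indexed by patient id) treated as fixed covariates with
        coefficients theta0/theta1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if plug_in_effects is not None and variant != "separate-event":
        raise ValueError("plug_in_effects requires variant='separate-event'")
    prior = prior if prior is not None else PriorSpec()
    config = config if config is not None else MCMCConfig()
    fixed = dict(fixed or {})
    spl = _resolve_spline(registry, variant, spline)
    pb = _Problem(registry, variant, spl, prior, fixed, plug_in_effects, frailty)

    n_kept = config.n_kept
    P = len(pb.param_names)
    params = np.empty((config.n_chains, n_kept, P))
    U_draws = (
        np.empty((config.n_chains, n_kept, pb.n_pat, 2)) if pb.has_long else None
    )
    U3_draws = np.empty((config.n_chains, n_kept, pb.n_pat)) if frailty else None

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        state = _init_with_retries(pb, rng)
        kept = 0
        it_range = range(config.n_iterations)
        if progress:  # pragma: no cover - cosmetic
            from tqdm import tqdm

            it_range = tqdm(it_range, desc=f"chain {c + 1}")
        for it in it_range:
            state.sweep(adapt=it < config.n_burnin)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thinning == 0:
                row, U, U3 = state.record()
                params[c, kept] = row
                if U_draws is not None:
                    U_draws[c, kept] = U
                if U3_draws is not None:
                    U3_draws[c, kept] = U3
                kept += 1
    meta = {
        "config": config,
        "prior": prior,
        "fixed": {k: np.asarray(v).tolist() if hasattr(v, "tolist") else v for k, v in fixed.items()},
        "n_patients": pb.n_pat,
        "n_obs": getattr(pb, "n_obs", 0),
    }
    return PosteriorDraws(
        params=params,
        names=pb.param_names,
        U=U_draws,
        patient_ids=pb.patient_ids,
        variant=variant,
        spline=spl,
        meta=meta,
        U3=U3_draws,
    )


def _init_with_retries(pb: _Problem, rng: np.random.Generator, max_retries: int = 10):
    last_err: Exception | str | None = None
    for attempt in range(max_retries):
        try:
            state = _ChainState(pb, rng)
            if attempt > 0:  # re-initialize with prior-scale jitter
                if pb.has_long:
                    state.phi = state.phi + rng.normal(0.0, 0.1, state.phi.shape)
                if pb.has_event:
                    state.psi = state.psi + rng.normal(0.0, 0.1, state.psi.shape)
            state.sweep(adapt=True)  # probe sweep; raises on degenerate data
            row, _, _ = state.record()
            if not np.all(np.isfinite(row)):
                last_err = "non-finite state after initialization"
                continue
            return state
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    raise RuntimeError(
        f"failed to initialize the sampler after {max_retries} attempts: {last_err}"
    )


def summarize(draws: PosteriorDraws, mass: float = 0.95) -> FitReport:
    """Posterior mean, HPD bounds and convergence diagnostics per parameter.

    Uses split-chain R-hat and bulk effective sample size (via arviz).  With
    a single chain R-hat cannot be computed and is reported as NaN with a
    warning.
    """
    import arviz as az

    rows = []
    single = draws.params.shape[0] == 1
    if single:
        warnings.warn("single chain: split-R-hat unavailable", stacklevel=2)
    for name in draws.names:
        chains = draws.get_chains(name)
        flat = chains.reshape(-1)
        lo, hi = hpd_interval(flat, mass)
        constant = np.allclose(flat, flat[0])
        if constant:
            rhat, ess = np.nan, np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(chains[None] if chains.ndim == 1 else chains)) if not single else np.nan
                ess = float(az.ess(chains))
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
                "rhat": rhat,
                "ess": ess,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return FitReport(table=table, variant=draws.variant, meta=dict(draws.meta))
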