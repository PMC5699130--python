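"""Cubic truncated power basis for the population mean FEV1 curve.

The population-level trajectory f(age) is a penalized regression spline built
from the global cubic monomials ``1, age, age^2, age^3`` plus one truncated
cubic term ``(age - kappa_m)_+^3`` per interior knot.  The basis is C^2 in age,
so both the level curve and its first derivative (the rate of FEV1 change, in
% predicted per year) are smooth across knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Modeled age range in years; spirometry below 6 y is unreliable and patients
#: above 45 y represent atypically mild disease, so knots must lie inside it.
AGE_RANGE = (6.0, 45.0)

#: Default number of interior knots for the semiparametric mean curve.
DEFAULT_N_KNOTS = 6


class SplineConfigError(ValueError):
    """Raised for an invalid spline specification (e.g. unsorted knots)."""


@dataclass(frozen=True)
class SplineSpec:
    """Specification of the cubic truncated power basis.

    Parameters
    ----------
    knots
        Strictly increasing interior knot locations in years, all inside the
        modeled age range.  ``K = 0`` knots recovers the global-cubic model.

    Notes
    -----
    The basis dimension is ``4 + K``: four global monomials followed by one
    truncated cubic per knot.  The polynomial degree is fixed at 3.
    """

    knots: tuple[float, ...] = field(default_factory=tuple)

    degree: int = 3

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if self.degree != 3:
            raise SplineConfigError("only cubic (degree 3) splines are supported")
        if any(not np.isfinite(k) for k in knots):
            raise SplineConfigError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise SplineConfigError(f"knots must be strictly increasing, got {knots}")
        lo, hi = AGE_RANGE
        if knots and (knots[0] < lo or knots[-1] > hi):
            raise SplineConfigError(
                f"knots must lie inside the modeled age range {AGE_RANGE}, got {knots}"
            )

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        """Basis dimension, ``4 + K``."""
        return 4 + len(self.knots)

    def to_dict(self) -> dict:
        return {"knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(knots=tuple(d.get("knots", ())))


def build_basis(age, spec: SplineSpec) -> np.ndarray:
    """Evaluate the truncated power basis at one or more ages.

    Returns an array whose last axis has length ``4 + K``:
    ``[1, a, a^2, a^3, (a - kappa_1)_+^3, ..., (a - kappa_K)_+^3]``.
    """
    a = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("age must be finite")
    cols = [np.ones_like(a), a, a**2, a**3]
    for kappa in spec.knots:
        cols.append(np.clip(a - kappa, 0.0, None) ** 3)
    return np.stack(cols, axis=-1)


def build_basis_derivative(age, spec: SplineSpec) -> np.ndarray:
    """Elementwise derivative of :func:`build_basis` with respect to age.

    ``[0, 1, 2a, 3a^2, 3(a - kappa_1)_+^2, ...]`` -- the truncated terms are
    C^1 at their knots, so the derivative is continuous everywhere.
    """
    a = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("age must be finite")
    cols = [np.zeros_like(a), np.ones_like(a), 2.0 * a, 3.0 * a**2]
    for kappa in spec.knots:
        cols.append(3.0 * np.clip(a - kappa, 0.0, None) ** 2)
    return np.stack(cols, axis=-1)


def choose_knots(ages: Sequence[float], n_knots: int = DEFAULT_N_KNOTS) -> SplineSpec:
    """Place knots at equally spaced interior quantiles of the visit ages.

    Knot ``m`` sits at the ``m / (K + 1)`` quantile of the pooled age
    distribution (``m = 1..K``), the usual penalized-spline default, which is
    robust to uneven visit densities.  Deterministic given the input.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if n_knots < 0:
        raise ValueError("n_knots must be >= 0")
    if n_knots == 0:
        return SplineSpec(knots=())
    n_distinct = np.unique(ages).size
    if n_knots > n_distinct:
        raise SplineConfigError(
            f"cannot place {n_knots} knots with only {n_distinct} distinct ages"
        )
    levels = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(ages, levels)
    if np.any(np.diff(knots) <= 0):
        raise SplineConfigError(
            "quantile knots are not strictly increasing; reduce n_knots"
        )
    return SplineSpec(knots=tuple(knots))
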