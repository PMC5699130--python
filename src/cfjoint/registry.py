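"""In-memory registry container and design-matrix construction.

A registry holds a long-format table of FEV1 visits and a per-patient event
table (follow-up time since baseline, event indicator, baseline covariates),
mirroring the tabular extracts produced by CF patient registries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SplineSpec, build_basis
from .params import BIRTH_COHORTS, EVENT_COVARIATES, LONG_COVARIATES

#: Required columns of the longitudinal table.
LONG_COLUMNS = (
    "patient_id",
    "age",
    "fev1",
    "male",
    "birth_cohort",
    "low_ses",
    "cfrd",
    "mrsa",
    "b_cepacia",
    "pa",
)

#: Required columns of the event table.  ``baseline_age``/``baseline_fev1``
#: are derived from the first visit when absent.
EVENT_COLUMNS = ("patient_id", "time", "status")

_TIME_VARYING = ("cfrd", "mrsa", "b_cepacia", "pa")


class RegistryError(ValueError):
    """Base class for registry validation failures."""


class MissingColumnError(RegistryError):
    pass


class ColumnTypeError(RegistryError):
    pass


class DuplicateVisitError(RegistryError):
    pass


class UnknownPatientError(RegistryError):
    pass


class EmptyCohortError(RegistryError):
    pass


def cohort_contrasts(birth_cohort: pd.Series) -> pd.DataFrame:
    """Expand the 4-level birth-cohort factor to three dummy contrasts.

    The youngest cohort (born after 1994) is the reference level.
    """
    cats = set(birth_cohort.unique()) - set(BIRTH_COHORTS)
    if cats:
        raise ColumnTypeError(f"unknown birth_cohort levels: {sorted(cats)}")
    out = pd.DataFrame(index=birth_cohort.index)
    for level in BIRTH_COHORTS[:-1]:
        out[f"cohort_{level}"] = (birth_cohort == level).astype(float)
    return out


@dataclass
class Registry:
    """Validated longitudinal + event tables ready for model fitting."""

    long: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.long = self.long.reset_index(drop=True)
        self.events = self.events.reset_index(drop=True)
        self._validate()
        self._derive_baseline()
        self.events = self.events.set_index("patient_id", drop=False)

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        for col in LONG_COLUMNS:
            if col not in self.long.columns:
                raise MissingColumnError(f"longitudinal table lacks column '{col}'")
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                raise MissingColumnError(f"event table lacks column '{col}'")
        if len(self.long) == 0 or len(self.events) == 0:
            raise EmptyCohortError("registry tables must be non-empty")
        for col in ("age", "fev1"):
            if not pd.api.types.is_numeric_dtype(self.long[col]):
                raise ColumnTypeError(f"longitudinal column '{col}' must be numeric")
        if not pd.api.types.is_numeric_dtype(self.events["time"]):
            raise ColumnTypeError("event column 'time' must be numeric")
        if not set(np.unique(self.events["status"])) <= {0, 1}:
            raise ColumnTypeError("event 'status' must be 0/1")
        dup = self.long.duplicated(subset=["patient_id", "age"])
        if dup.any():
            pid = self.long.loc[dup, "patient_id"].iloc[0]
            raise DuplicateVisitError(
                f"duplicate (patient_id, age) rows, e.g. patient {pid!r}"
            )
        if self.events["patient_id"].duplicated().any():
            raise DuplicateVisitError("event table has duplicate patient_id rows")
        missing = set(self.events["patient_id"]) - set(self.long["patient_id"])
        if missing:
            raise UnknownPatientError(
                f"event-table patients absent from longitudinal table: {sorted(missing)[:5]}"
            )
        extra = set(self.long["patient_id"]) - set(self.events["patient_id"])
        if extra:
            raise UnknownPatientError(
                f"longitudinal patients absent from event table: {sorted(extra)[:5]}"
            )
        self.long = self.long.sort_values(["patient_id", "age"], kind="mergesort")
        self.long = self.long.reset_index(drop=True)

    def _derive_baseline(self) -> None:
        first = self.long.groupby("patient_id", sort=False).first()
        ev = self.events.set_index("patient_id")
        if "baseline_age" not in ev.columns:
            ev["baseline_age"] = first["age"]
        if "baseline_fev1" not in ev.columns:
            ev["baseline_fev1"] = first["fev1"]
        # static covariates live on the event table for the event design
        for col in ("male", "birth_cohort", "low_ses"):
            if col not in ev.columns:
                ev[col] = first[col]
        self.events = ev.reset_index()

    # -- accessors ------------------------------------------------------
    @property
    def patient_ids(self) -> np.ndarray:
        return self.events["patient_id"].to_numpy()

    @property
    def n_patients(self) -> int:
        return len(self.events)

    @property
    def n_obs(self) -> int:
        return len(self.long)

    def patient_index(self) -> np.ndarray:
        """Row -> patient position codes for the longitudinal table."""
        order = pd.Index(self.patient_ids)
        return order.get_indexer(self.long["patient_id"])

    # -- designs --------------------------------------------------------
    def long_design(self, spline: SplineSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (X, y, ages) for the longitudinal submodel.

        X columns: spline basis (4 + K) followed by LONG_COVARIATES.
        """
        ages = self.long["age"].to_numpy(dtype=float)
        B = build_basis(ages, spline)
        ev = self.events.set_index("patient_id")
        base_fev = ev["baseline_fev1"].reindex(self.long["patient_id"]).to_numpy(float)
        contr = cohort_contrasts(self.long["birth_cohort"])
        cols = {
            "baseline_fev1": base_fev,
            "male": self.long["male"].to_numpy(float),
            "cohort_lt1981": contr["cohort_lt1981"].to_numpy(),
            "cohort_1981_1988": contr["cohort_1981_1988"].to_numpy(),
            "cohort_1989_1994": contr["cohort_1989_1994"].to_numpy(),
            "low_ses": self.long["low_ses"].to_numpy(float),
            "cfrd": self.long["cfrd"].to_numpy(float),
            "mrsa": self.long["mrsa"].to_numpy(float),
            "b_cepacia": self.long["b_cepacia"].to_numpy(float),
            "pa": self.long["pa"].to_numpy(float),
        }
        X = np.column_stack([B] + [cols[c] for c in LONG_COVARIATES])
        y = self.long["fev1"].to_numpy(dtype=float)
        return X, y, ages

    def event_design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (X2, time, status) for the Weibull submodel.

        X2 columns follow EVENT_COVARIATES (leading intercept).
        """
        ev = self.events
        contr = cohort_contrasts(ev["birth_cohort"])
        cols = {
            "intercept": np.ones(len(ev)),
            "baseline_age": ev["baseline_age"].to_numpy(float),
            "baseline_fev1": ev["baseline_fev1"].to_numpy(float),
            "male": ev["male"].to_numpy(float),
            "cohort_lt1981": contr["cohort_lt1981"].to_numpy(),
            "cohort_1981_1988": contr["cohort_1981_1988"].to_numpy(),
            "cohort_1989_1994": contr["cohort_1989_1994"].to_numpy(),
            "low_ses": ev["low_ses"].to_numpy(float),
        }
        X2 = np.column_stack([cols[c] for c in EVENT_COVARIATES])
        time = ev["time"].to_numpy(dtype=float)
        status = ev["status"].to_numpy(dtype=int)
        if np.any(time <= 0):
            raise ColumnTypeError("event times must be positive")
        return X2, time, status

    def long_covariate_path(self, patient_id, ages: np.ndarray) -> np.ndarray:
        """Covariate rows (LONG_COVARIATES order) for one patient on an age
        grid, carrying time-varying flags forward from the last visit."""
        sub = self.long[self.long["patient_id"] == patient_id]
        if len(sub) == 0:
            raise UnknownPatientError(f"unknown patient id {patient_id!r}")
        ev = self.events.loc[patient_id]
        contr = cohort_contrasts(sub["birth_cohort"].iloc[:1]).iloc[0]
        static = np.array(
            [
                ev["baseline_fev1"],
                float(sub["male"].iloc[0]),
                contr["cohort_lt1981"],
                contr["cohort_1981_1988"],
                contr["cohort_1989_1994"],
                float(sub["low_ses"].iloc[0]),
            ]
        )
        out = np.empty((len(ages), len(LONG_COVARIATES)))
        out[:, :6] = static
        visit_ages = sub["age"].to_numpy(float)
        idx = np.clip(np.searchsorted(visit_ages, ages, side="right") - 1, 0, None)
        for j, col in enumerate(_TIME_VARYING):
            vals = sub[col].to_numpy(float)
            out[:, 6 + j] = vals[idx]
        return out
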