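"""File formats and run configuration.

Registry tables are plain delimited text (CSV) — CF registry extracts are
tabular EHR data, so no binary or sequence format applies.  Posterior draws
persist as a gzipped CSV (one column per scalar, one row per retained draw)
with a JSON sidecar carrying the seed, configuration hash and versions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import SplineSpec
from .mcmc import MCMCConfig, PosteriorDraws
from .registry import LONG_COLUMNS, ColumnTypeError, MissingColumnError, Registry
from .simulate import CohortConfig, RawRegistry

_TIME_VARYING = ("cfrd", "mrsa", "b_cepacia", "pa")


def read_registry(long_path, event_path) -> Registry:
    """Read and validate longitudinal + event CSV tables.

    Missing time-varying covariate values are carried forward from the
    patient's last observed visit; missing values before any observed one
    are set to 0 with a warning.
    """
    long = pd.read_csv(long_path)
    events = pd.read_csv(event_path)
    for col in ("age", "fev1"):
        if col in long.columns and not pd.api.types.is_numeric_dtype(long[col]):
            raise ColumnTypeError(f"longitudinal column '{col}' must be numeric")
    missing_tv = [c for c in _TIME_VARYING if c in long.columns and long[c].isna().any()]
    if missing_tv:
        long = long.sort_values(["patient_id", "age"], kind="mergesort")
        for col in missing_tv:
            long[col] = long.groupby("patient_id")[col].ffill()
            n_lead = int(long[col].isna().sum())
            if n_lead:
                warnings.warn(
                    f"{n_lead} leading missing values in time-varying covariate "
                    f"'{col}' set to 0"
                )
                long[col] = long[col].fillna(0)
    return Registry(long=long, events=events)


def write_registry(data: Registry | RawRegistry, long_path, event_path, truth_path=None) -> None:
    """Write tables as CSV; the latent truth block goes to a separate sidecar."""
    long_cols = [c for c in LONG_COLUMNS if c in data.long.columns]
    data.long[long_cols].to_csv(long_path, index=False)
    ev = data.events.reset_index(drop=True)
    data_cols = [c for c in ev.columns if c != "index"]
    ev[data_cols].to_csv(event_path, index=False)
    if truth_path is not None and getattr(data, "truth", None) is not None:
        data.truth.to_csv(truth_path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Schema-validated configuration of a fitting run."""

    long_path: str | None = None
    event_path: str | None = None
    out_dir: str = "."
    variant: str = "joint-semiparametric"
    n_knots: int = 6
    knots: list[float] | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    cohort: CohortConfig | None = None

    def spline(self) -> SplineSpec | int:
        if self.knots is not None:
            return SplineSpec(knots=tuple(self.knots))
        return self.n_knots


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcmc = MCMCConfig(**raw.pop("mcmc", {}))
    cohort = raw.pop("cohort", None)
    if cohort is not None:
        cohort = CohortConfig(**cohort)
    return RunConfig(mcmc=mcmc, cohort=cohort, **raw)


def config_hash(cfg) -> str:
    """Stable short hash of a configuration object for provenance logging."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    payload = json.dumps(cfg, default=_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# draws persistence
# ---------------------------------------------------------------------------


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist scalar draws as gzipped CSV plus a JSON metadata sidecar.

    Per-patient random-effect draws are summarized to posterior means in the
    sidecar (full U draws are an in-memory object; refit to regenerate).
    """
    path = Path(path)
    draws.to_dataframe().to_csv(path, index=False, compression="gzip")
    meta = {
        "variant": draws.variant,
        "names": draws.names,
        "n_chains": int(draws.params.shape[0]),
        "n_kept": int(draws.params.shape[1]),
        "spline_knots": list(draws.spline.knots) if draws.spline else None,
        "patient_ids": [str(p) for p in draws.patient_ids] if draws.patient_ids is not None else None,
        "U_mean": draws.U_flat().mean(axis=0).tolist() if draws.U is not None else None,
        "config": asdict(draws.meta["config"]) if "config" in draws.meta else None,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_draws(path) -> pd.DataFrame:
    """Load the scalar draw table written by :func:`save_draws`."""
    return pd.read_csv(path, compression="gzip")
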