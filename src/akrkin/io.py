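"""File formats and run configuration.

Progress-curve sets travel as long-format CSV with molar concentrations and
explicit unit suffixes in the column names (silent unit errors are the main
practical risk in an assay that mixes mM, uM and nM):

    curve_id, dataset_id, replicate, inhibitor_conc_M, time_s, absorbance_AU

Parameter files are YAML/JSON mapping MechanismParams fields in SI units
with ``null`` for not-determined constants.  Run configuration is validated
with pydantic; unknown keys are rejected and per-enzyme assay defaults are
filled in.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import constants
from .mechanism import MechanismParams
from .simulate import CurveMeta, CurveSet, ProgressCurve
from .synthetic import AssayDesign, default_assay_design

__all__ = [
    "REQUIRED_COLUMNS",
    "read_curveset",
    "write_curveset",
    "load_mechanism_params",
    "RunConfig",
    "validate_config",
    "CurveSetParseError",
]

REQUIRED_COLUMNS = ("curve_id", "dataset_id", "replicate",
                    "inhibitor_conc_M", "time_s", "absorbance_AU")

FLOAT_FORMAT = "%.12g"  # >= 12 significant digits through a write/read cycle


class CurveSetParseError(ValueError):
    """Malformed progress-curve CSV, with offending rows/columns named."""


def write_curveset(curves: CurveSet, path) -> None:
    rows = []
    for c in curves:
        rows.append(pd.DataFrame({
            "curve_id": c.meta.curve_id,
            "dataset_id": c.meta.dataset_id,
            "replicate": c.meta.replicate,
            "inhibitor_conc_M": c.meta.inhibitor_conc_M,
            "time_s": c.times,
            "absorbance_AU": c.absorbance,
        }))
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_curveset(path) -> CurveSet:
    """Parse a long-format progress-curve CSV into a typed CurveSet.

    Rows are grouped by curve_id and sorted by time; duplicated
    (curve_id, time_s) pairs and non-numeric cells are rejected with the
    offending rows named.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurveSetParseError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}")
    for col in ("inhibitor_conc_M", "time_s", "absorbance_AU", "replicate"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise CurveSetParseError(
                f"{path}: non-numeric value(s) in column {col!r} at data "
                f"row(s) {list(bad[:5] + 2)}")  # +2: header + 1-based
        if converted.isna().any():
            raise CurveSetParseError(
                f"{path}: empty cell(s) in column {col!r} at data row(s) "
                f"{list(df.index[converted.isna()][:5] + 2)}")
        df[col] = converted
    curves = []
    for curve_id, g in df.groupby("curve_id", sort=True):
        dup = g["time_s"].duplicated()
        if dup.any():
            raise CurveSetParseError(
                f"{path}: duplicate (curve_id, time_s) for curve "
                f"{curve_id!r} at data row(s) {list(g.index[dup][:5] + 2)}")
        g = g.sort_values("time_s")
        iconc = g["inhibitor_conc_M"].unique()
        if len(iconc) != 1:
            raise CurveSetParseError(
                f"{path}: curve {curve_id!r} mixes inhibitor concentrations {iconc}")
        meta = CurveMeta(
            curve_id=str(curve_id),
            inhibitor_conc_M=float(iconc[0]),
            replicate=int(g["replicate"].iloc[0]),
            dataset_id=str(g["dataset_id"].iloc[0]),
        )
        curves.append(ProgressCurve(
            times=g["time_s"].to_numpy(float),
            absorbance=g["absorbance_AU"].to_numpy(float),
            meta=meta,
        ))
    return CurveSet(curves, {"source": str(path)})


# ---------------------------------------------------------------------------
# parameter files


def load_mechanism_params(path) -> MechanismParams:
    """Load MechanismParams from YAML/JSON (SI units, null = not determined)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    return MechanismParams(**data)


# ---------------------------------------------------------------------------
# run configuration


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseSettings(_Section):
    sd_AU: float = 0.002
    drift_AU_per_h: float = 0.0
    seed: int  # mandatory: no hidden global randomness

    @field_validator("sd_AU")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("noise sd_AU must be >= 0")
        return v


class FitSettings(_Section):
    variant: str = "auto"
    multistarts: int = Field(default=8, ge=1)
    spread_decades: float = Field(default=2.0, gt=0)
    seed: int = 0

    @field_validator("variant")
    @classmethod
    def _variant(cls, v):
        allowed = {"auto", "reversible_only", "full", "parabolic"}
        if v not in allowed:
            raise ValueError(f"variant must be one of {sorted(allowed)}")
        return v


class DesignOverrides(_Section):
    S_total_M: Optional[float] = Field(default=None, gt=0)
    E_total_M: Optional[float] = Field(default=None, gt=0)
    NAD0_M: Optional[float] = Field(default=None, gt=0)
    inhibitor_concs_M: Optional[list] = None
    replicates: Optional[int] = Field(default=None, ge=1)
    n_datasets: Optional[int] = Field(default=None, ge=1)
    duration_s: Optional[float] = Field(default=None, gt=0)
    interval_s: Optional[float] = Field(default=None, gt=0)
    path_length_cm: Optional[float] = Field(default=None, gt=0)

    @field_validator("inhibitor_concs_M")
    @classmethod
    def _concs(cls, v):
        if v is not None and any(c < 0 for c in v):
            raise ValueError("inhibitor concentrations must be non-negative")
        return v


class RunConfig(_Section):
    """Validated, normalized run configuration with defaults filled."""

    enzyme: str
    params_file: Optional[str] = None
    shared: dict = Field(default_factory=dict)
    design: DesignOverrides = Field(default_factory=DesignOverrides)
    noise: Optional[NoiseSettings] = None
    fit: FitSettings = Field(default_factory=FitSettings)
    log_level: str = "INFO"

    @field_validator("enzyme")
    @classmethod
    def _enzyme(cls, v):
        if v not in constants.ENZYMES:
            raise ValueError(f"unknown enzyme {v!r}; valid: {list(constants.ENZYMES)}")
        return v

    def resolved_design(self) -> AssayDesign:
        base = default_assay_design(self.enzyme)
        o = self.design
        changes = {}
        if o.S_total_M is not None:
            changes["S_total"] = o.S_total_M
        if o.E_total_M is not None:
            changes["E_total"] = o.E_total_M
        if o.NAD0_M is not None:
            changes["NAD0"] = o.NAD0_M
        if o.inhibitor_concs_M is not None:
            changes["inhibitor_concs"] = tuple(o.inhibitor_concs_M)
        for src, dst in (("replicates", "replicates"), ("n_datasets", "n_datasets"),
                         ("duration_s", "duration"), ("interval_s", "interval"),
                         ("path_length_cm", "path_length")):
            v = getattr(o, src)
            if v is not None:
                changes[dst] = v
        return base.evolve(**changes) if changes else base


def validate_config(raw: dict) -> RunConfig:
    """Validate a parsed YAML/JSON config and fill defaults.

    Unknown keys, negative concentrations and a missing seed in the noise
    section are rejected; shared kinetic constants absent from the config
    fall back to the published per-enzyme values (e.g. K_NAD = 0.16 mM).
    """
    cfg = RunConfig(**raw)
    shared = dict(constants.SHARED_CONSTANTS[cfg.enzyme])
    for key, val in cfg.shared.items():
        if key not in shared:
            raise ValueError(f"unknown shared-constant key {key!r}; "
                             f"valid: {sorted(shared)}")
        if not val > 0:
            raise ValueError(f"shared constant {key} must be > 0")
        shared[key] = val
    cfg.shared = shared
    return cfg


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(data)
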