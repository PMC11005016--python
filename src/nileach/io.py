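"""File I/O and run configuration.

CSV is the canonical tabular format (immersion data, biodistribution
data, trajectories, ensembles), JSON carries fitted parameters, reports
and run manifests, YAML carries the run configuration.  All times are
serialized in days; week/hour inputs are converted at ingest only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    COMPARTMENTS,
    ControlState,
    DeviceReleaseParams,
    Physiology,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "read_immersion",
    "read_biodistribution",
    "write_params",
    "read_params",
    "write_manifest",
    "config_hash",
]

_TIME_TO_DAYS = {"days": 1.0, "weeks": 7.0, "hours": 1.0 / 24.0}


class SchemaError(ValueError):
    """An input file or config block violates its schema."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration (see the bundled example in docs)."""

    physiology: Physiology = field(default_factory=Physiology)
    control: ControlState = field(default_factory=ControlState)
    datasets: Dict[str, str] = field(default_factory=dict)
    optimizer: Dict = field(default_factory=lambda: {
        "algorithm": "nelder-mead", "maxfev": 1200, "tolerance": 1e-6,
        "restarts": 0, "seed": 0})
    monte_carlo: Dict = field(default_factory=lambda: {
        "n": 5000, "seed": 0, "acceptance_floor": 0.1})
    risk: Dict = field(default_factory=lambda: {
        "ti_ng_per_kg_day": 500.0, "horizon_days": 126.0})
    units: Dict[str, str] = field(default_factory=lambda: {"time": "days"})
    raw: Dict = field(default_factory=dict)

    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(config: Mapping) -> str:
    """Stable sha256 of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_block(cls, block: Mapping, name: str):
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(block) - valid
    if unknown:
        raise SchemaError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid config block {name!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    cfg = RunConfig(raw=raw)
    if "physiology" in raw:
        cfg.physiology = _build_block(Physiology, raw["physiology"], "physiology")
    if "control" in raw:
        cfg.control = _build_block(ControlState, raw["control"], "control")
    for block in ("optimizer", "monte_carlo", "risk", "units", "datasets"):
        if block in raw:
            if not isinstance(raw[block], dict):
                raise SchemaError(f"config block {block!r} must be a mapping")
            getattr(cfg, block).update(raw[block])
    tu = cfg.units.get("time", "days")
    if tu not in _TIME_TO_DAYS:
        raise SchemaError(f"unsupported time unit {tu!r}")
    return cfg


# ---------------------------------------------------------------------------
# dataset readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_immersion(path, *, time_unit: str = "days",
                   blank_ng_per_ml: float = 0.0) -> pd.DataFrame:
    """Read a cumulative immersion-release dataset.

    Accepts either (device_id, time_days, cumulative_ng) or the
    concentration dialect (device_id, time_days, conc_ng_per_ml,
    volume_ml); in the latter, a declared blank concentration is
    subtracted before the per-specimen mass conversion.  Returns columns
    device_id, time_days, cumulative_ng.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["device_id", "time_days"], path)
    factor = _TIME_TO_DAYS.get(time_unit)
    if factor is None:
        raise SchemaError(f"{path}: unknown time unit {time_unit!r}")
    df["time_days"] = df["time_days"].astype(float) * factor
    if (df["time_days"] < 0).any():
        row = int(df.index[df["time_days"] < 0][0])
        raise SchemaError(f"{path}: negative time at row {row}")
    if "cumulative_ng" in df.columns:
        out = df[["device_id", "time_days", "cumulative_ng"]].copy()
    elif {"conc_ng_per_ml", "volume_ml"}.issubset(df.columns):
        conc = (df["conc_ng_per_ml"].astype(float) - blank_ng_per_ml).clip(lower=0.0)
        out = df[["device_id", "time_days"]].copy()
        out["cumulative_ng"] = conc * df["volume_ml"].astype(float)
    else:
        raise SchemaError(
            f"{path}: need either column 'cumulative_ng' or columns "
            "'conc_ng_per_ml' + 'volume_ml'")
    out["cumulative_ng"] = out["cumulative_ng"].astype(float)
    if (out["cumulative_ng"] < 0).any():
        row = int(out.index[out["cumulative_ng"] < 0][0])
        raise SchemaError(f"{path}: negative cumulative mass at row {row}")
    return out


#: Residence volume used to convert excreta concentrations to pool masses.
_CONC_VOLUMES = {"blood": "v_b", "urine": "v_u", "feces": "v_f"}


def read_biodistribution(path, phys: Physiology, *,
                         time_unit: str = "days") -> pd.DataFrame:
    """Read in vivo biodistribution records to the mass scale (ng).

    Expects columns (compartment, time_days, value, unit) with unit in
    {ng, ng_per_ml}; concentrations are converted with the matching
    physiological volume (blood, urine, feces).  Every compartment must
    carry a control row at time 0.  Duplicate compartment-time rows are
    kept as replicates.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["compartment", "time_days", "value", "unit"], path)
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise SchemaError(f"{path}: unknown compartments {sorted(bad)}")
    factor = _TIME_TO_DAYS.get(time_unit)
    if factor is None:
        raise SchemaError(f"{path}: unknown time unit {time_unit!r}")
    times = df["time_days"].astype(float) * factor
    masses = np.empty(len(df))
    for i, (comp, value, unit) in enumerate(
            zip(df["compartment"], df["value"].astype(float), df["unit"])):
        if unit == "ng":
            masses[i] = value
        elif unit == "ng_per_ml":
            vol_attr = _CONC_VOLUMES.get(comp)
            if vol_attr is None:
                raise SchemaError(
                    f"{path}: row {i}: concentration unit unsupported for "
                    f"compartment {comp!r}")
            masses[i] = value * getattr(phys, vol_attr)
        else:
            raise SchemaError(f"{path}: row {i}: unknown unit {unit!r}")
    out = pd.DataFrame({"compartment": df["compartment"],
                        "time_days": times, "mass_ng": masses})
    for comp in out["compartment"].unique():
        if not (out.loc[out["compartment"] == comp, "time_days"] == 0.0).any():
            raise SchemaError(f"{path}: compartment {comp!r} lacks a control "
                              "row at time 0")
    return out


# ---------------------------------------------------------------------------
# parameter / manifest serialization
# ---------------------------------------------------------------------------

def write_params(path, payload: Mapping) -> None:
    """Write a parameter payload (fit results, release params) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def read_params(path) -> dict:
    return json.loads(Path(path).read_text())


def release_to_dict(p: DeviceReleaseParams) -> dict:
    return {"alpha": p.alpha, "tau": p.tau, "a_surf": p.a_surf}


def release_from_dict(d: Mapping) -> DeviceReleaseParams:
    return DeviceReleaseParams(float(d["alpha"]), float(d["tau"]),
                               float(d["a_surf"]))


def write_manifest(path, *, command: str, config: Optional[Mapping] = None,
                   seed: Optional[int] = None,
                   inputs: Optional[Mapping] = None,
                   outputs: Optional[Mapping] = None,
                   extra: Optional[Mapping] = None) -> dict:
    """Write a run manifest alongside an artifact; returns the manifest."""
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "inputs": dict(inputs or {}),
        "outputs": dict(outputs or {}),
    }
    if extra:
        manifest.update(_jsonable(extra))
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
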