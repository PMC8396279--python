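"""Run configuration: TOML parsing, defaults, validation, result provenance.

One config file describes one scan: a model specification, a box, a list
of fluid densities ``rho0`` (the isotherm axis), a protocol, analysis bin
widths, and replicate seeds.  Every omitted field falls back to a logged
default; values outside the replication ranges raise warnings, not
errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import MODEL_VARIANTS, ConfigurationError

__all__ = ["RunConfig", "read_config", "write_config", "write_results", "validate_results"]

log = logging.getLogger("brushmd")

REPLICATION_RHO0 = (0.0001, 0.3)
REPLICATION_M = (5, 10, 15, 20, 30)
REPLICATION_F = (5, 10, 20, 30)

_REQUIRED = ("variant", "f", "M")

_DEFAULTS = dict(
    geometry="sphere",
    sigma_c=4.0,
    sigma_P=1.0,
    eps_Ps=1.5,
    kss=1000.0,
    L=57.0,
    Lz=40.0,
    rho_gr=0.398,
    rho0=[0.01],
    anneal=[],
    equilibration_steps=100_000,
    production_steps=100_000,
    sample_interval=500,
    dt=0.002,
    T_star=1.0,
    tau_damp=0.1,
    bin_width=0.05,
    bulk_window=None,
    seeds=[1, 2, 3],
    output_dir="results",
)


@dataclass
class RunConfig:
    """Fully resolved state-point scan specification."""

    variant: str
    f: int
    M: int
    geometry: str = "sphere"
    sigma_c: float = 4.0
    sigma_P: float = 1.0
    eps_Ps: float = 1.5
    kss: float = 1000.0
    L: float = 57.0
    Lz: float = 40.0
    rho_gr: float = 0.398
    rho0: list = field(default_factory=lambda: [0.01])
    anneal: list = field(default_factory=list)
    equilibration_steps: int = 100_000
    production_steps: int = 100_000
    sample_interval: int = 500
    dt: float = 0.002
    T_star: float = 1.0
    tau_damp: float = 0.1
    bin_width: float = 0.05
    bulk_window: tuple | None = None
    seeds: list = field(default_factory=lambda: [1, 2, 3])
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.variant not in MODEL_VARIANTS:
            raise ConfigurationError(f"unknown model variant {self.variant!r}")
        for rho in self.rho0:
            if not REPLICATION_RHO0[0] <= rho <= REPLICATION_RHO0[1] and rho != 0.0:
                warnings.warn(
                    f"rho0={rho} outside the replication range {REPLICATION_RHO0}",
                    stacklevel=3,
                )
        if self.M not in REPLICATION_M:
            warnings.warn(f"M={self.M} outside the replication set {REPLICATION_M}",
                          stacklevel=3)
        if self.f not in REPLICATION_F and self.f != 0:
            warnings.warn(f"f={self.f} outside the replication set {REPLICATION_F}",
                          stacklevel=3)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["bulk_window"] is not None:
            d["bulk_window"] = list(d["bulk_window"])
        else:
            d.pop("bulk_window")
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_config(path) -> RunConfig:
    """Parse a TOML run config; missing required keys raise a named error,
    every defaulted value is logged."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    flat: dict = {}
    for key, val in raw.items():
        if isinstance(val, dict):
            flat.update(val)
        else:
            flat[key] = val
    for name in _REQUIRED:
        if name not in flat:
            raise ConfigurationError(f"config is missing required field {name!r}")
    kwargs = {}
    for name in RunConfig.__dataclass_fields__:
        if name in flat:
            kwargs[name] = flat[name]
        elif name in _DEFAULTS:
            log.info("config default applied: %s = %r", name, _DEFAULTS[name])
            kwargs[name] = _DEFAULTS[name]
    if "bulk_window" in kwargs and kwargs["bulk_window"] is not None:
        kwargs["bulk_window"] = tuple(kwargs["bulk_window"])
    unknown = set(flat) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(float(v)) if isinstance(v, float) else str(v)


def write_config(path, config: RunConfig) -> None:
    """Emit the resolved config as a flat TOML table (lossless round trip)."""
    lines = [f"{k} = {_toml_value(v)}" for k, v in config.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


RESULTS_SCHEMA = {
    "schema": "brushmd-results-v1",
    "required": ["schema", "config", "config_hash", "version", "state_points"],
    "state_point_required": ["rho0", "seed", "rho_b", "Gamma", "Gamma_star", "H", "H_star"],
}


def write_results(path, config: RunConfig, state_points: list[dict]) -> dict:
    """Write a results JSON record with full provenance; returns the record."""
    from . import __version__

    record = {
        "schema": RESULTS_SCHEMA["schema"],
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "version": __version__,
        "state_points": state_points,
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))
    return record


def validate_results(record: dict) -> None:
    """Check a results record against the shipped schema; raises on failure."""
    for key in RESULTS_SCHEMA["required"]:
        if key not in record:
            raise ValueError(f"results record missing {key!r}")
    if record["schema"] != RESULTS_SCHEMA["schema"]:
        raise ValueError(f"unexpected schema tag {record['schema']!r}")
    for sp in record["state_points"]:
        for key in RESULTS_SCHEMA["state_point_required"]:
            if key not in sp:
                raise ValueError(f"state point missing {key!r}")
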