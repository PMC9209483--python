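"""Shared I/O helpers: unit handling, probe configuration, delimited tables.

All analysis code works in SI units internally.  File readers convert from
the units declared in a sidecar configuration (YAML or TOML) at load time.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

#: Multiplicative factors to SI for the unit strings accepted in sidecar
#: configs.  Micro may be spelled "u" or the Greek letter.
UNIT_TO_SI: dict[str, float] = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "pm": 1e-12,
    # force
    "N": 1.0, "mN": 1e-3, "uN": 1e-6, "µN": 1e-6, "nN": 1e-9, "pN": 1e-12,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6,
    # pressure
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9,
    # frequency
    "Hz": 1.0, "kHz": 1e3,
    # radians
    "rad": 1.0,
}


def unit_factor(unit: str) -> float:
    """Return the factor converting a value in ``unit`` to SI."""
    try:
        return UNIT_TO_SI[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}") from None


def to_si(value, unit: str):
    """Convert a scalar or array from ``unit`` to the corresponding SI unit."""
    return value * unit_factor(unit)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class ProbeConfig:
    """Cantilever/indenter metadata shared by the indentation and
    microrheology modules.

    Parameters are stored in SI.  ``units`` maps column names of the data
    files to their declared units (e.g. ``{"height": "nm", "force": "nN"}``).
    """

    spring_constant: float          # N/m
    indenter_radius: float          # m
    poisson_ratio: float = 0.5
    setpoint: float | None = None   # N
    approach_speed: float | None = None  # m/s
    units: Mapping[str, str] = field(default_factory=dict)
    columns: Mapping[str, str] = field(default_factory=dict)
    extra: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.indenter_radius <= 0:
            raise ValueError("indenter_radius must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")

    @classmethod
    def from_mapping(cls, d: Mapping[str, Any]) -> "ProbeConfig":
        d = dict(d)
        units = d.pop("units", {})
        # parameter values may carry their own units, e.g. setpoint_nN
        k = to_si(d.pop("spring_constant"), d.pop("spring_constant_unit", "N"))
        # spring constant unit is N/m; only the force prefix scales
        r = to_si(d.pop("indenter_radius"), d.pop("indenter_radius_unit", "m"))
        nu = float(d.pop("poisson_ratio", 0.5))
        sp = d.pop("setpoint", None)
        if sp is not None:
            sp = to_si(sp, d.pop("setpoint_unit", "N"))
        speed = d.pop("approach_speed", None)
        if speed is not None:
            speed = to_si(speed, d.pop("approach_speed_unit", "m"))
        cols = d.pop("columns", {})
        return cls(spring_constant=k, indenter_radius=r, poisson_ratio=nu,
                   setpoint=sp, approach_speed=speed, units=units,
                   columns=cols, extra=d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ProbeConfig":
        return cls.from_mapping(load_config(path))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or TOML configuration file into a dict."""
    path = Path(path)
    if path.suffix.lower() in {".toml", ".tml"}:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return out


def save_yaml(obj: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing the separator.

    Lines starting with ``#`` are treated as comments.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse delimited table: {exc}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    return df
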