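"""Reproducible-run plumbing: validated run configurations, stage dispatch,
and descriptive group summaries.

Every run writes its outputs together with the exact configuration, the
seed and the package version into the output directory, so a result
directory is self-describing and re-running the same config reproduces it.
Statistics here are descriptive only (n, mean, SEM, median, IQR);
hypothesis testing is left to standard statistics libraries.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, io as _io

__all__ = ["RunConfig", "run", "summarize"]

STAGES = ("fit-indentation", "microrheology", "mre-invert", "simulate")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass
class RunConfig:
    """Validated description of one analysis run."""

    stage: str
    inputs: tuple[str, ...]
    out_dir: str
    config: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0
    options: Mapping[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}; choose from {STAGES}")
        if not self.inputs and self.stage != "simulate":
            raise ConfigError("at least one input path is required")
        for p in self.inputs:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _expand_tables(inputs: Sequence[str], pattern: str) -> list[Path]:
    paths: list[Path] = []
    for p in inputs:
        p = Path(p)
        if p.is_dir():
            paths.extend(sorted(p.glob(pattern)))
        else:
            paths.append(p)
    return paths


def run(config: RunConfig) -> Path:
    """Execute one stage and write its artifacts to the output directory.

    Results are computed fully in memory first and written in one pass at
    the end, together with the serialized config and package version, so a
    failed run leaves no partial result tables behind.  Returns the path of
    the primary output table.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        primary = _dispatch(config, staging)
        _io.save_yaml(config.to_dict(), staging / "run_config.yaml")
        if out_dir.exists():
            shutil.rmtree(out_dir)
        staging.rename(out_dir)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return out_dir / primary.name


def _dispatch(config: RunConfig, out_dir: Path) -> Path:
    if config.stage == "fit-indentation":
        return _run_indentation(config, out_dir)
    if config.stage == "microrheology":
        return _run_microrheology(config, out_dir)
    if config.stage == "mre-invert":
        return _run_mre(config, out_dir)
    if config.stage == "simulate":
        return _run_simulate(config, out_dir)
    raise ConfigError(f"unknown stage {config.stage!r}")  # pragma: no cover


def _run_indentation(config: RunConfig, out_dir: Path) -> Path:
    from . import indentation as ind

    probe = _io.ProbeConfig.from_mapping(config.config)
    paths = _expand_tables(config.inputs, "*.tsv") or \
        _expand_tables(config.inputs, "*.csv")
    fits = []
    for p in paths:
        curve = ind.read_force_curve(p, probe)
        fits.append(ind.analyze_curve(
            curve, model=config.options.get("model", "hertz")))
    fmap = ind.aggregate_force_map(fits, geometry=config.config.get("grid", {}))
    out = out_dir / "fits.csv"
    fmap.table.to_csv(out, index=False)
    fmap.summary.to_csv(out_dir / "summary.csv", index=False)
    records = [dataclasses.asdict(f) for f in fits]
    with open(out_dir / "fits.json", "w") as fh:
        json.dump(records, fh, indent=1, default=str)
    return out


def _run_microrheology(config: RunConfig, out_dir: Path) -> Path:
    from . import oscillation as osc

    probe = _io.ProbeConfig.from_mapping(config.config)
    drag_path = config.options.get("drag")
    b0 = None
    if drag_path is not None:
        tab = _io.read_table(drag_path)
        calib = osc.DragCalibration(tab.iloc[:, 0].to_numpy(),
                                    tab.iloc[:, 1].to_numpy())
        b0 = calib.b0()
    elif "b0" in config.options:
        b0 = float(config.options["b0"])

    segments = []
    for p in _expand_tables(config.inputs, "*.tsv"):
        tab = _io.read_table(p)
        meta = _io.load_config(p.with_suffix(".yaml")) if p.with_suffix(".yaml").exists() \
            else {}
        f = float(meta.get("frequency_Hz", _frequency_from_name(p)))
        segments.append(osc.OscillationSegment(
            time=tab["t"].to_numpy(), force=tab["force"].to_numpy(),
            indentation=tab["indentation"].to_numpy(), frequency=f,
            indenter_radius=probe.indenter_radius,
            poisson_ratio=probe.poisson_ratio,
            spring_constant=probe.spring_constant,
            operating_indentation=config.options.get("delta0"),
            segment_id=p.stem))
    spectrum = osc.rheology_spectrum(segments, b0)
    out = out_dir / "spectrum.csv"
    spectrum.to_csv(out, index=False)
    return out


def _frequency_from_name(path: Path) -> float:
    # oscillation_f<value>Hz.tsv layout written by the simulator
    stem = path.stem
    try:
        return float(stem.split("_f")[-1].rstrip("Hz"))
    except ValueError:
        raise ConfigError(
            f"{path}: drive frequency not in sidecar or filename") from None


def _run_mre(config: RunConfig, out_dir: Path) -> Path:
    from . import mre

    acqs = []
    for p in config.inputs:
        p = Path(p)
        meta = config.config or p.with_suffix(".yaml")
        acqs.append(mre.load_acquisition(p, meta))
    table = mre.invert_to_table(acqs, n_bins=int(config.options.get("n_bins", 32)))
    out = out_dir / "mre.csv"
    table.to_csv(out, index=False)
    return out


def _run_simulate(config: RunConfig, out_dir: Path) -> Path:
    from . import synthetic as syn

    kind = config.options.get("kind", "force-curves")
    cfg = dict(config.config)
    if kind == "force-curves":
        n = int(cfg.pop("n_curves", 1))
        base = syn.ForceCurveSpec(**cfg)
        seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
        for i in range(n):
            spec = dataclasses.replace(base, seed=int(seeds[i]))
            syn.write_force_curve(spec, out_dir / f"curve_{i:04d}.tsv")
        return out_dir / "curve_0000.tsv"
    if kind == "oscillation":
        model = syn.PowerLawModulus(**cfg.pop("modulus"))
        if "frequencies" in cfg:
            cfg["frequencies"] = tuple(cfg["frequencies"])
        spec = syn.OscillationSpec(modulus=model, seed=config.seed, **cfg)
        paths = syn.write_oscillation(spec, out_dir)
        return paths[0]
    if kind == "mre":
        spec = syn.MRESpec(seed=config.seed, **cfg)
        return syn.write_mre_movie(spec, out_dir / "mre_movie.tif")
    raise ConfigError(f"unknown simulation kind {kind!r}")


def summarize(table: pd.DataFrame, grouping: Sequence[str],
              values: Sequence[str] | None = None) -> pd.DataFrame:
    """Descriptive per-group summary: n, mean, SEM, median, IQR.

    ``values`` defaults to all numeric non-grouping columns.  Groups with a
    single observation report NaN SEM; empty inputs yield an empty frame.
    """
    grouping = list(grouping)
    for col in grouping:
        if col not in table.columns:
            raise KeyError(f"grouping column {col!r} not in table")
    if values is None:
        values = [c for c in table.columns
                  if c not in grouping and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for key, g in table.groupby(grouping, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(grouping, key))
        for col in values:
            x = g[col].dropna()
            n = len(x)
            row[f"{col}_n"] = n
            row[f"{col}_mean"] = x.mean() if n else np.nan
            row[f"{col}_sem"] = x.sem(ddof=1) if n > 1 else np.nan
            row[f"{col}_median"] = x.median() if n else np.nan
            row[f"{col}_iqr"] = (x.quantile(0.75) - x.quantile(0.25)) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
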