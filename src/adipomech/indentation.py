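"""AFM indentation analysis: contact detection, tip–sample separation and
spherical Hertz/Sneddon fitting of force–distance curves.

The measurement: a colloidal-probe cantilever (sphere of radius ``R`` glued
to a soft cantilever of spring constant ``k``) is driven into a cell or
tissue at constant piezo speed until a force setpoint is reached.  The
recorded piezo height ``z`` and cantilever force ``F`` are converted to the
true indentation depth ``δ = (z − z0) − F/k`` (tip–sample separation), and
the approach portion is fitted with the paraboloidal Hertz model for a
sphere,

    F = (4/3) · E/(1 − ν²) · √R · δ^{3/2},

yielding the apparent Young's modulus ``E``.  The paraboloidal
approximation is the community default for indentation depths well below
the probe radius; the exact Sneddon sphere solution is available via
``model="sneddon"`` for deeper indentations.

Contact-point detection is a two-stage procedure: a linear baseline
(offset + tilt) is estimated on the non-contact part of the approach, and
the contact point is taken at the first sustained crossing of three times
the baseline noise level, then refined as a free parameter of the final
least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import FormatError, ProbeConfig, to_si

__all__ = [
    "ForceCurve",
    "ContactPoint",
    "IndentationFit",
    "ForceMap",
    "read_force_curve",
    "detect_contact_point",
    "tip_sample_separation",
    "fit_hertz_sphere",
    "analyze_curve",
    "aggregate_force_map",
    "hertz_force",
    "sneddon_force",
]

# typed rejection/quality reasons
FLAG_TOO_FEW_SAMPLES = "too_few_samples"
FLAG_NON_MONOTONE = "non_monotone_height"
FLAG_SATURATED = "saturated_deflection"
FLAG_NO_BASELINE = "no_baseline"
FLAG_NO_CONTACT = "no_contact"
FLAG_NEGATIVE_MODULUS = "negative_modulus"
FLAG_FIT_FAILED = "fit_failed"

MIN_SAMPLES = 50


@dataclass
class ForceCurve:
    """A single force–distance curve plus probe metadata (SI units).

    ``piezo_height`` increases towards the sample, so the approach segment
    runs from the start of the record to the maximum piezo extension.
    """

    piezo_height: np.ndarray      # m
    force: np.ndarray             # N
    spring_constant: float        # N/m
    indenter_radius: float        # m
    poisson_ratio: float = 0.5
    approach_speed: float | None = None  # m/s
    setpoint: float | None = None        # N
    segment: np.ndarray | None = None    # "approach"/"retract" labels
    curve_id: str = ""
    grid: tuple | None = None     # (row, col, region) for force maps
    n_dropped: int = 0            # non-finite rows removed by the reader

    def __post_init__(self) -> None:
        self.piezo_height = np.asarray(self.piezo_height, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.piezo_height.shape != self.force.shape:
            raise ValueError("piezo_height and force must have equal length")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.indenter_radius <= 0:
            raise ValueError("indenter_radius must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.segment is not None:
            self.segment = np.asarray(self.segment)

    @property
    def deflection(self) -> np.ndarray:
        """Cantilever deflection d = F/k (m)."""
        return self.force / self.spring_constant

    def approach(self) -> "ForceCurve":
        """Return the approach segment (up to maximum piezo extension)."""
        if self.segment is not None:
            idx = np.flatnonzero(self.segment == "approach")
        else:
            idx = np.arange(int(np.argmax(self.piezo_height)) + 1)
        return replace(
            self,
            piezo_height=self.piezo_height[idx],
            force=self.force[idx],
            segment=None,
        )

    def validate(self) -> list[str]:
        """Typed reasons why this curve cannot be analysed (empty = usable)."""
        reasons = []
        z = self.piezo_height
        if z.size < MIN_SAMPLES:
            reasons.append(FLAG_TOO_FEW_SAMPLES)
        app = self.approach()
        dz = np.diff(app.piezo_height)
        if dz.size and (dz < -1e-12).any():
            reasons.append(FLAG_NON_MONOTONE)
        # saturated deflection: a long run of identical extreme values
        f = app.force
        if f.size >= 10:
            fmax = np.max(np.abs(f))
            if fmax > 0:
                run = np.sum(np.abs(f - f[np.argmax(np.abs(f))]) < 1e-15 * max(fmax, 1.0))
                if run > 0.2 * f.size:
                    reasons.append(FLAG_SATURATED)
        return reasons


@dataclass(frozen=True)
class ContactPoint:
    """Result of contact-point detection on the approach segment."""

    z0: float                 # m, piezo height at contact
    baseline_offset: float    # N
    baseline_tilt: float      # N/m of piezo travel
    noise_sd: float           # N, residual SD in the baseline window
    index: int                # sample index of contact in the approach
    flags: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return FLAG_NO_BASELINE not in self.flags and FLAG_NO_CONTACT not in self.flags


@dataclass(frozen=True)
class IndentationFit:
    """Spherical-indentation fit result."""

    apparent_young_modulus: float   # Pa
    contact_point: float            # m (refined z0)
    max_indentation: float          # m
    residual_rms: float             # N
    n_points: int                   # in-contact samples used
    fit_window: tuple[int, int] = (0, 0)
    flags: tuple[str, ...] = ()
    model: str = "hertz"
    curve_id: str = ""
    grid: tuple | None = None

    @property
    def accepted(self) -> bool:
        return len(self.flags) == 0 and np.isfinite(self.residual_rms)


def hertz_force(delta, E: float, R: float, nu: float = 0.5):
    """Paraboloidal Hertz force for a sphere: F = (4/3)E√R δ^{3/2}/(1−ν²).

    Negative indentations contribute zero force.
    """
    d = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * d**1.5


def _sneddon_contact_radius(delta: np.ndarray, R: float) -> np.ndarray:
    """Solve δ = (a/2)·ln((R+a)/(R−a)) for the contact radius a."""
    out = np.zeros_like(delta)

    def g(a, d):
        return 0.5 * a * np.log((R + a) / (R - a)) - d

    for i, d in enumerate(delta):
        if d <= 0:
            continue
        out[i] = optimize.brentq(g, 1e-18, R * (1 - 1e-12), args=(d,))
    return out


def sneddon_force(delta, E: float, R: float, nu: float = 0.5):
    """Exact Sneddon solution for a rigid sphere on an elastic half-space.

    F = E/(1−ν²) · [ (a² + R²)/2 · ln((R+a)/(R−a)) − aR ], with the contact
    radius ``a`` solving δ = (a/2)·ln((R+a)/(R−a)).  Reduces to the
    paraboloidal Hertz expression for δ ≪ R.
    """
    d = np.clip(np.atleast_1d(np.asarray(delta, dtype=float)), 0.0, None)
    a = _sneddon_contact_radius(d, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.where(a > 0, np.log((R + a) / (R - a)), 0.0)
    f = E / (1.0 - nu**2) * (0.5 * (a**2 + R**2) * ln - a * R)
    return f if np.ndim(delta) else float(f[0])


def read_force_curve(path: str | Path, metadata: ProbeConfig | Mapping) -> ForceCurve:
    """Read a delimited force curve and return a validated :class:`ForceCurve`.

    The table must contain a height column and either a deflection or a
    force column.  Column names and units come from the sidecar config
    (``columns`` / ``units`` mappings); by default columns named ``height``,
    ``deflection`` and ``force`` are recognised, assumed to be in the units
    declared for them (SI if undeclared).
    """
    if not isinstance(metadata, ProbeConfig):
        metadata = ProbeConfig.from_mapping(metadata)
    from .io import read_table

    df = read_table(path)
    cols = {k: metadata.columns.get(k, k) for k in ("height", "deflection", "force")}
    if cols["height"] not in df.columns:
        raise FormatError(f"{path}: missing height column {cols['height']!r}")
    has_defl = cols["deflection"] in df.columns
    has_force = cols["force"] in df.columns
    if not (has_defl or has_force):
        raise FormatError(f"{path}: need a deflection or force column")

    z = df[cols["height"]].to_numpy(dtype=float)
    z = to_si(z, metadata.units.get("height", "m"))
    if has_force:
        f = df[cols["force"]].to_numpy(dtype=float)
        f = to_si(f, metadata.units.get("force", "N"))
    else:
        d = df[cols["deflection"]].to_numpy(dtype=float)
        d = to_si(d, metadata.units.get("deflection", "m"))
        f = metadata.spring_constant * d

    finite = np.isfinite(z) & np.isfinite(f)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} non-finite rows")
        z, f = z[finite], f[finite]

    # split approach/retract at maximum piezo extension
    i_max = int(np.argmax(z))
    segment = np.array(["approach"] * (i_max + 1) + ["retract"] * (z.size - i_max - 1))

    grid = None
    g = metadata.extra.get("grid")
    if g is not None:
        grid = tuple(g)
    return ForceCurve(
        piezo_height=z,
        force=f,
        spring_constant=metadata.spring_constant,
        indenter_radius=metadata.indenter_radius,
        poisson_ratio=metadata.poisson_ratio,
        approach_speed=metadata.approach_speed,
        setpoint=metadata.setpoint,
        segment=segment,
        curve_id=Path(path).stem,
        grid=grid,
        n_dropped=n_dropped,
    )


def detect_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.6,
    threshold_factor: float = 3.0,
    sustain: int = 5,
) -> ContactPoint:
    """Detect the tip–sample contact point on the approach segment.

    A linear baseline (offset + tilt) is fitted over the first
    ``baseline_fraction`` of the approach; the contact point is the last
    sub-threshold sample before the first run of ``sustain`` samples
    exceeding ``threshold_factor`` × the baseline noise SD.

    Returns a :class:`ContactPoint`; curves whose force rises from the very
    first samples (no detectable baseline) or that never contact are flagged
    unusable rather than raising.
    """
    app = curve.approach()
    z, f = app.piezo_height, app.force
    n = z.size
    nb = max(int(baseline_fraction * n), 2)

    # iterate: the initial window may overlap the contact onset for soft
    # curves, so re-fit the baseline over the detected pre-contact region
    # until the detected contact index stabilises
    idx = None
    for _ in range(8):
        coef = np.polyfit(z[:nb], f[:nb], 1)
        tilt, offset = float(coef[0]), float(coef[1])
        f_corr = f - (tilt * z + offset)
        sd = float(np.std(f_corr[:nb]))
        fscale = max(float(np.max(np.abs(f_corr))), 1e-30)
        thresh = max(threshold_factor * sd, 1e-9 * fscale)

        above = f_corr > thresh
        # first index where `sustain` consecutive samples exceed the threshold
        idx = None
        if n >= sustain:
            runs = np.convolve(above.astype(int), np.ones(sustain, dtype=int),
                               "valid")
            hits = np.flatnonzero(runs == sustain)
            if hits.size:
                idx = int(hits[0])
        if idx is None or idx >= nb:
            break
        nb = max(idx, 2)

    flags: list[str] = []
    if idx is None:
        flags.append(FLAG_NO_CONTACT)
        return ContactPoint(z0=float(z[-1]), baseline_offset=offset,
                            baseline_tilt=tilt, noise_sd=sd, index=n - 1,
                            flags=tuple(flags))
    # walk back to the last sample at or below zero corrected force
    j = idx
    while j > 0 and f_corr[j - 1] > 0:
        j -= 1
    if j <= max(2, int(0.02 * n)):
        # force rises essentially from the first sample: baseline not estimable
        flags.append(FLAG_NO_BASELINE)
    return ContactPoint(z0=float(z[j]), baseline_offset=offset,
                        baseline_tilt=tilt, noise_sd=sd, index=j,
                        flags=tuple(flags))


def tip_sample_separation(
    curve: ForceCurve, z0: float, force: np.ndarray | None = None
) -> np.ndarray:
    """Tip–sample separation δ = (z − z0) − F/k on the approach segment.

    ``force`` may supply a baseline-corrected force series; by default the
    curve's recorded force is used.  Values are returned for all approach
    samples (negative before contact); fitting clips to δ ≥ 0.
    """
    app = curve.approach()
    f = app.force if force is None else np.asarray(force, dtype=float)
    return (app.piezo_height - z0) - f / curve.spring_constant


def _linearized_hertz(delta: np.ndarray, force: np.ndarray,
                      R: float, nu: float) -> float:
    """Closed-form E from regression of F on δ^{3/2} through the origin."""
    x = np.clip(delta, 0.0, None) ** 1.5
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return 0.0
    H = float(np.dot(x, force)) / sxx
    return H * 0.75 * (1.0 - nu**2) / np.sqrt(R)


def fit_hertz_sphere(
    delta: np.ndarray,
    force: np.ndarray,
    R: float,
    nu: float = 0.5,
    refine_contact: bool = True,
    model: str = "hertz",
    curve_id: str = "",
    grid: tuple | None = None,
) -> IndentationFit:
    """Fit the spherical contact model to an indentation series.

    Parameters
    ----------
    delta, force
        Tip–sample separation (m) and baseline-corrected force (N); samples
        with δ < 0 (pre-contact) may be included — they anchor the contact
        refinement and contribute zero model force.
    R, nu
        Indenter radius (m) and Poisson ratio.
    refine_contact
        Refine the contact point as a free fit parameter (a shift of the
        δ axis) alongside the modulus.
    model
        ``"hertz"`` (paraboloidal approximation, default) or ``"sneddon"``
        (exact sphere; no contact refinement).

    Returns an :class:`IndentationFit` with ``apparent_young_modulus`` in Pa.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    in_contact = delta > 0
    n_in = int(in_contact.sum())
    if n_in < 10:
        return IndentationFit(np.nan, np.nan, np.nan, np.nan, n_in,
                              flags=(FLAG_FIT_FAILED,), model=model,
                              curve_id=curve_id, grid=grid)

    if model == "sneddon":
        shape = _sneddon_shape(delta, R, nu)
        sxx = float(np.dot(shape, shape))
        E = float(np.dot(shape, force)) / sxx if sxx > 0 else 0.0
        resid = force - E * shape
        flags = ()
        if E < 0:
            E, flags = 0.0, (FLAG_NEGATIVE_MODULUS,)
        return IndentationFit(
            apparent_young_modulus=E, contact_point=0.0,
            max_indentation=float(delta.max()),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            n_points=n_in, fit_window=(0, delta.size), flags=flags,
            model="sneddon", curve_id=curve_id, grid=grid)

    E0 = max(_linearized_hertz(delta, force, R, nu), 1e-3)
    pref = (4.0 / 3.0) / (1.0 - nu**2) * np.sqrt(R)

    # nondimensionalize: forces in units of f_scale, depths in units of
    # d_scale, so the optimizer sees O(1) residuals and parameters
    d_scale = float(delta.max())
    f_scale = max(float(np.max(np.abs(force))), 1e-30)
    u = delta / d_scale
    y = force / f_scale
    h0 = pref * E0 * d_scale**1.5 / f_scale

    if refine_contact:
        def resid(p):
            h, v = p
            return h * np.clip(u - v, 0.0, None) ** 1.5 - y

        u_min = float(u.min())
        sol = optimize.least_squares(
            resid, x0=[h0, 0.0],
            bounds=([0.0, min(u_min, -0.5)], [np.inf, 0.9]))
        E = float(sol.x[0]) * f_scale / (pref * d_scale**1.5)
        dz = float(sol.x[1]) * d_scale
        res = sol.fun * f_scale
    else:
        def resid1(p):
            return p[0] * np.clip(u, 0.0, None) ** 1.5 - y

        sol = optimize.least_squares(resid1, x0=[h0], bounds=([0.0], [np.inf]))
        E = float(sol.x[0]) * f_scale / (pref * d_scale**1.5)
        dz = 0.0
        res = sol.fun * f_scale

    flags = ()
    if not sol.success:
        flags = (FLAG_FIT_FAILED,)
    elif E <= 0:
        E, flags = 0.0, (FLAG_NEGATIVE_MODULUS,)
    return IndentationFit(
        apparent_young_modulus=E,
        contact_point=dz,
        max_indentation=float(np.max(delta - dz)),
        residual_rms=float(np.sqrt(np.mean(res**2))),
        n_points=int((delta - dz > 0).sum()),
        fit_window=(0, delta.size),
        flags=flags,
        model="hertz",
        curve_id=curve_id,
        grid=grid,
    )


def _sneddon_shape(delta: np.ndarray, R: float, nu: float) -> np.ndarray:
    """Sneddon force per unit modulus, F/E, for each δ."""
    d = np.clip(delta, 0.0, None)
    a = _sneddon_contact_radius(d, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.where(a > 0, np.log((R + a) / (R - a)), 0.0)
    return (0.5 * (a**2 + R**2) * ln - a * R) / (1.0 - nu**2)


def _joint_refine(z: np.ndarray, f: np.ndarray, k: float, pref: float,
                  E0: float, z00: float, b00: float, b10: float):
    """Joint least-squares refinement of modulus, contact point and baseline.

    Model: F(z) = b0 + b1·z + pref·E·δ^{3/2} with the tip–sample separation
    δ = (z − z0) − (F_meas − b0 − b1·z)/k using the measured force.  The
    staged estimates seed the fit; for soft curves with a gradual force
    onset this removes the bias a contaminated baseline window would leave.
    All quantities are nondimensionalized so the optimizer sees O(1) values.
    """
    zs = float(z.max() - z.min())
    fs = max(float(np.max(np.abs(f))), 1e-30)
    zn = (z - z.min()) / zs
    fn = f / fs

    def unpack(p):
        h, v, c0, c1 = p
        E = h * fs / (pref * zs**1.5)
        z0 = z.min() + v * zs
        b0 = c0 * fs - (c1 * fs / zs) * z.min()
        b1 = c1 * fs / zs
        return E, z0, b0, b1

    def resid(p):
        h, v, c0, c1 = p
        base = c0 + c1 * zn
        delta_n = (zn - v) - (fn - base) * fs / (k * zs)
        return base + h * np.clip(delta_n, 0.0, None) ** 1.5 - fn

    h0 = pref * E0 * zs**1.5 / fs
    v0 = (z00 - z.min()) / zs
    c10 = b10 * zs / fs
    c00 = (b00 + b10 * z.min()) / fs
    sol = optimize.least_squares(
        resid, x0=[h0, np.clip(v0, 0.0, 1.0), c00, c10],
        bounds=([0.0, 0.0, -np.inf, -np.inf], [np.inf, 1.0, np.inf, np.inf]))
    E, z0, b0, b1 = unpack(sol.x)
    return E, z0, b0, b1, sol.fun * fs, sol.success


def analyze_curve(curve: ForceCurve, model: str = "hertz",
                  refine_contact: bool = True) -> IndentationFit:
    """Full per-curve pipeline: validate → contact point → separation → fit.

    The fit window runs from the start of the approach (the pre-contact
    baseline anchors the refined contact point) to the force setpoint taken
    from the curve metadata; retract data are never used.  With the default
    Hertz model and ``refine_contact=True`` the contact point and linear
    baseline are refined jointly with the modulus in the final fit.
    """
    reasons = curve.validate()
    if reasons:
        return IndentationFit(np.nan, np.nan, np.nan, np.nan, 0,
                              flags=tuple(reasons), model=model,
                              curve_id=curve.curve_id, grid=curve.grid)
    cp = detect_contact_point(curve)
    if not cp.usable:
        return IndentationFit(np.nan, np.nan, np.nan, np.nan, 0,
                              flags=cp.flags, model=model,
                              curve_id=curve.curve_id, grid=curve.grid)
    app = curve.approach()
    f_corr = app.force - (cp.baseline_tilt * app.piezo_height + cp.baseline_offset)
    if curve.setpoint is not None:
        stop = np.flatnonzero(f_corr >= curve.setpoint)
        i_stop = int(stop[0]) + 1 if stop.size else f_corr.size
    else:
        i_stop = f_corr.size

    if model == "hertz" and refine_contact:
        z = app.piezo_height[:i_stop]
        f = app.force[:i_stop]
        pref = (4.0 / 3.0) / (1.0 - curve.poisson_ratio**2) \
            * np.sqrt(curve.indenter_radius)
        E0 = _linearized_hertz(
            tip_sample_separation(curve, cp.z0, force=f_corr)[:i_stop],
            f_corr[:i_stop], curve.indenter_radius, curve.poisson_ratio)
        E, z0, b0, b1, res, success = _joint_refine(
            z, f, curve.spring_constant, pref, max(E0, 1e-3), cp.z0,
            cp.baseline_offset, cp.baseline_tilt)
        delta = (z - z0) - (f - b0 - b1 * z) / curve.spring_constant
        flags: tuple[str, ...] = ()
        if not success:
            flags = (FLAG_FIT_FAILED,)
        elif E <= 0:
            E, flags = 0.0, (FLAG_NEGATIVE_MODULUS,)
        return IndentationFit(
            apparent_young_modulus=E, contact_point=z0,
            max_indentation=float(np.max(delta)),
            residual_rms=float(np.sqrt(np.mean(res**2))),
            n_points=int((delta > 0).sum()), fit_window=(0, i_stop),
            flags=flags, model="hertz", curve_id=curve.curve_id,
            grid=curve.grid)

    delta = tip_sample_separation(curve, cp.z0, force=f_corr)[:i_stop]
    fit = fit_hertz_sphere(delta, f_corr[:i_stop], curve.indenter_radius,
                           curve.poisson_ratio, refine_contact=refine_contact,
                           model=model, curve_id=curve.curve_id,
                           grid=curve.grid)
    # express the refined contact point on the absolute piezo axis
    return replace(fit, contact_point=cp.z0 + fit.contact_point,
                   fit_window=(0, i_stop))


@dataclass
class ForceMap:
    """Grid of indentation fits with per-region summaries.

    ``table`` holds one row per fit; ``summary`` aggregates accepted fits
    per region (median/mean/SEM, with rejection bookkeeping).  Empty regions
    produce NaN summaries, never silent zeros.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    geometry: Mapping = field(default_factory=dict)


def aggregate_force_map(fits: Sequence[IndentationFit],
                        geometry: Mapping | None = None) -> ForceMap:
    """Aggregate grid-based indentation fits into per-region summaries."""
    rows = []
    for f in fits:
        row, col, region = (f.grid + (None,) * 3)[:3] if f.grid else (None, None, None)
        rows.append({
            "curve_id": f.curve_id, "row": row, "col": col, "region": region,
            "E_Pa": f.apparent_young_modulus, "z0_m": f.contact_point,
            "delta_max_m": f.max_indentation, "rms_N": f.residual_rms,
            "accepted": f.accepted, "flags": ";".join(f.flags),
        })
    table = pd.DataFrame(rows)

    def _summ(g: pd.DataFrame) -> pd.Series:
        acc = g.loc[g["accepted"], "E_Pa"]
        n = len(acc)
        return pd.Series({
            "n": n,
            "n_rejected": int((~g["accepted"]).sum()),
            "median_Pa": acc.median() if n else np.nan,
            "mean_Pa": acc.mean() if n else np.nan,
            "sem_Pa": acc.sem() if n > 1 else np.nan,
        })

    if table.empty:
        summary = pd.DataFrame(
            columns=["region", "n", "n_rejected", "median_Pa", "mean_Pa", "sem_Pa"])
    else:
        summary = (table.groupby("region", dropna=False)
                   .apply(_summ, include_groups=False).reset_index())
    return ForceMap(table=table, summary=summary, geometry=dict(geometry or {}))
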