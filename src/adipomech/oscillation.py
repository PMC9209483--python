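"""Oscillatory AFM microrheology: complex shear modulus from small
sinusoidal indentation oscillations.

At an operating indentation δ0 the probe is oscillated sinusoidally with a
small amplitude at a drive frequency f.  Linearizing the spherical Hertz
model about δ0 and moving to the frequency domain gives

    G*(ω) = G′ + iG″ = (1 − ν) / (4 √(R δ0)) · F(ω)/δ(ω),

where the complex transfer ratio F(ω)/δ(ω) = (A^F/A^δ)·e^{i(θ^F − θ^δ)}
is formed from the amplitudes and phases of the force and indentation
signals.  The hydrodynamic drag of the medium on the oscillating cantilever
adds a purely imaginary contribution that is removed before the prefactor:

    G*(ω) = (1 − ν)/(4 √(R δ0)) · [ F(ω)/δ(ω) − iω b(0) ],

with b(0) the drag coefficient extrapolated to zero cantilever–sample
distance from non-contact oscillations.

Phase convention: cosine basis, s(t) = A·cos(2πft + θ); a positive phase
difference θ^F − θ^δ (force leading indentation) corresponds to viscous
dissipation and lies in [0, π/2] for a physical viscoelastic response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OscillationSegment",
    "HarmonicFit",
    "DragCalibration",
    "ShearModulusPoint",
    "fit_harmonic",
    "single_bin_fourier",
    "complex_ratio",
    "shear_modulus",
    "drag_correct",
    "extrapolate_drag",
    "analyze_segment",
    "rheology_spectrum",
    "hertz_prefactor",
]

FLAG_PHASE_UNPHYSICAL = "phase_outside_0_pi2"
FLAG_NOMINAL_DELTA0 = "nominal_delta0"


def _wrap_phase(theta: float) -> float:
    """Wrap an angle to (−π, π]."""
    out = math.remainder(theta, 2.0 * math.pi)
    if out <= -math.pi:
        out += 2.0 * math.pi
    return out


@dataclass
class OscillationSegment:
    """One oscillation trace at a single drive frequency (SI units)."""

    time: np.ndarray              # s
    force: np.ndarray             # N
    indentation: np.ndarray       # m
    frequency: float              # Hz
    indenter_radius: float        # m
    poisson_ratio: float = 0.5
    spring_constant: float | None = None   # N/m (metadata)
    nominal_amplitude: float | None = None  # m
    operating_indentation: float | None = None  # δ0 (m), nominal fallback
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.indentation = np.asarray(self.indentation, dtype=float)
        if not (self.time.shape == self.force.shape == self.indentation.shape):
            raise ValueError("time, force, indentation must have equal length")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        dt = np.median(np.diff(self.time))
        if dt <= 0 or 1.0 / dt < 10 * self.frequency:
            raise ValueError("sampling rate must be ≥ 10× the drive frequency")


@dataclass(frozen=True)
class HarmonicFit:
    """Amplitude/phase of a sinusoid fitted to one signal."""

    amplitude: float    # signal units, ≥ 0
    phase: float        # rad, in (−π, π]
    offset: float       # DC component
    drift: float        # linear drift slope (units/s)
    residual_rms: float
    frequency: float    # Hz

    @property
    def phasor(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class DragCalibration:
    """Hydrodynamic drag coefficient b(h) versus cantilever–sample distance."""

    distances: np.ndarray   # h, m
    drag: np.ndarray        # b(h), N·s/m

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.drag = np.asarray(self.drag, dtype=float)
        if self.distances.shape != self.drag.shape:
            raise ValueError("distances and drag must have equal length")
        if self.distances.size < 2:
            raise ValueError("need at least two calibration distances")
        if (self.drag < 0).any():
            raise ValueError("drag coefficients must be ≥ 0")

    def b0(self) -> float:
        return extrapolate_drag(self.distances, self.drag)


@dataclass(frozen=True)
class ShearModulusPoint:
    """Complex shear modulus at one drive frequency."""

    frequency: float        # Hz
    g_storage: float        # G′, Pa
    g_loss: float           # G″, Pa
    drag_corrected: bool = False
    indenter_radius: float = np.nan
    poisson_ratio: float = np.nan
    operating_indentation: float = np.nan
    flags: tuple[str, ...] = ()
    segment_id: str = ""

    @property
    def loss_tangent(self) -> float:
        if self.g_storage > 0:
            return self.g_loss / self.g_storage
        return np.nan

    @property
    def g_complex(self) -> complex:
        return complex(self.g_storage, self.g_loss)


def fit_harmonic(signal: np.ndarray, t: np.ndarray, f: float):
    """Least-squares fit of s(t) = A·cos(2πft + θ) + c0 + c1·t.

    Returns a :class:`HarmonicFit` with A ≥ 0 (enforced by the phase
    convention) and θ wrapped to (−π, π].  Requires at least 3 cycles and
    8 samples per cycle.  A constant signal yields A = 0 with undefined
    (NaN) phase.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(signal, dtype=float)
    if t.shape != s.shape:
        raise ValueError("signal and time must have equal length")
    duration = t[-1] - t[0]
    if duration * f < 3 - 1e-9:
        raise ValueError("need at least 3 cycles for a harmonic fit")
    dt = np.median(np.diff(t))
    if 1.0 / dt < 8 * f:
        raise ValueError("need at least 8 samples per cycle")

    w = 2.0 * np.pi * f
    tc = t - t[0]
    X = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t), tc])
    coef, _, rank, _ = np.linalg.lstsq(X, s, rcond=None)
    a, b, c0, c1 = coef
    A = float(np.hypot(a, b))
    resid = s - X @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    scale = max(float(np.max(np.abs(s))), 1e-30)
    if A < 1e-12 * scale or rank < 2:
        return HarmonicFit(0.0, np.nan, float(c0), float(c1), rms, f)
    theta = _wrap_phase(math.atan2(-b, a))
    return HarmonicFit(A, theta, float(c0), float(c1), rms, f)


def single_bin_fourier(signal: np.ndarray, t: np.ndarray, f: float):
    """Single-bin discrete Fourier estimate of (A, θ) at frequency f.

    Independent cross-check for :func:`fit_harmonic`; exact when the record
    spans an integer number of cycles.  The DC component is removed first.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(signal, dtype=float)
    s = s - s.mean()
    w = 2.0 * np.pi * f
    C = 2.0 * np.mean(s * np.exp(-1j * w * t))
    return float(abs(C)), _wrap_phase(float(np.angle(C)))


def complex_ratio(force_fit: HarmonicFit, indent_fit: HarmonicFit) -> complex:
    """Complex transfer ratio F(ω)/δ(ω) = (A^F/A^δ)·e^{i(θ^F − θ^δ)} (N/m)."""
    if not np.isfinite(force_fit.amplitude) or not np.isfinite(indent_fit.amplitude):
        raise ValueError("harmonic amplitudes must be finite")
    if indent_fit.amplitude == 0:
        raise ZeroDivisionError("indentation amplitude is zero")
    dtheta = _wrap_phase(force_fit.phase - indent_fit.phase)
    return (force_fit.amplitude / indent_fit.amplitude) * np.exp(1j * dtheta)


def hertz_prefactor(R: float, nu: float, delta0: float) -> float:
    """Linearized-Hertz prefactor (1 − ν) / (4 √(R δ0)) in 1/m."""
    if R <= 0 or delta0 <= 0:
        raise ValueError("R and delta0 must be > 0")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("poisson ratio must lie in [0, 0.5]")
    return (1.0 - nu) / (4.0 * np.sqrt(R * delta0))


def shear_modulus(ratio: complex, R: float, nu: float, delta0: float) -> complex:
    """Complex shear modulus G* = (1 − ν)/(4√(R δ0)) · F(ω)/δ(ω) (Pa)."""
    return hertz_prefactor(R, nu, delta0) * ratio


def drag_correct(ratio: complex, f: float, b0: float) -> complex:
    """Subtract the hydrodynamic drag term iω b(0) from the transfer ratio.

    Leaves the real part unchanged; with b(0) = 0 this is the identity.
    """
    if b0 < 0:
        raise ValueError("b(0) must be ≥ 0")
    return ratio - 1j * 2.0 * np.pi * f * b0


def extrapolate_drag(distances: np.ndarray, drag: np.ndarray) -> float:
    """Extrapolate the drag coefficient b(h) linearly to h = 0.

    A negative extrapolated b(0) is clipped to 0 with a warning.
    """
    h = np.asarray(distances, dtype=float)
    b = np.asarray(drag, dtype=float)
    if h.size < 2:
        raise ValueError("need at least two calibration points")
    slope, intercept = np.polyfit(h, b, 1)
    b0 = float(intercept)
    if b0 < 0:
        warnings.warn("extrapolated b(0) negative; clipped to 0")
        b0 = 0.0
    return b0


def analyze_segment(segment: OscillationSegment,
                    b0: float | None = None) -> ShearModulusPoint:
    """Analyse one oscillation segment into a :class:`ShearModulusPoint`.

    δ0 defaults to the measured mean indentation of the segment (the DC
    offset of the harmonic fit); the nominal operating indentation from the
    metadata is used as a fallback and flagged.
    """
    fF = fit_harmonic(segment.force, segment.time, segment.frequency)
    fd = fit_harmonic(segment.indentation, segment.time, segment.frequency)
    ratio = complex_ratio(fF, fd)
    flags: list[str] = []
    delta0 = fd.offset + fd.drift * 0.5 * (segment.time[-1] - segment.time[0])
    if delta0 <= 0:
        if segment.operating_indentation is None:
            raise ValueError("measured δ0 ≤ 0 and no nominal value provided")
        delta0 = segment.operating_indentation
        flags.append(FLAG_NOMINAL_DELTA0)
    corrected = b0 is not None and b0 > 0
    if b0 is not None:
        ratio = drag_correct(ratio, segment.frequency, b0)
    g = shear_modulus(ratio, segment.indenter_radius,
                      segment.poisson_ratio, delta0)
    dtheta = float(np.angle(ratio))
    if not -1e-9 <= dtheta <= np.pi / 2 + 1e-9:
        flags.append(FLAG_PHASE_UNPHYSICAL)
    return ShearModulusPoint(
        frequency=segment.frequency,
        g_storage=float(g.real), g_loss=float(g.imag),
        drag_corrected=corrected,
        indenter_radius=segment.indenter_radius,
        poisson_ratio=segment.poisson_ratio,
        operating_indentation=float(delta0),
        flags=tuple(flags),
        segment_id=segment.segment_id,
    )


def rheology_spectrum(
    segments: Sequence[OscillationSegment],
    calibration: DragCalibration | float | None = None,
) -> pd.DataFrame:
    """Per-frequency rheology spectrum across repeated segments.

    Returns a tidy table with one row per drive frequency: mean and SEM of
    G′, G″ and the loss tangent over repetitions, plus bookkeeping columns.
    Frequencies at which every repetition was rejected appear as gaps (rows
    absent), never interpolated.
    """
    if isinstance(calibration, DragCalibration):
        b0 = calibration.b0()
    else:
        b0 = calibration
    points = []
    for seg in segments:
        try:
            points.append(analyze_segment(seg, b0=b0))
        except (ValueError, ZeroDivisionError) as exc:
            warnings.warn(f"segment {seg.segment_id!r} rejected: {exc}")
    rows = [{
        "f_Hz": p.frequency, "Gp_Pa": p.g_storage, "Gpp_Pa": p.g_loss,
        "loss_tangent": p.loss_tangent, "flags": ";".join(p.flags),
    } for p in points]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=[
            "f_Hz", "Gp_Pa", "Gpp_Pa", "loss_tangent",
            "Gp_sem_Pa", "Gpp_sem_Pa", "loss_tangent_sem", "n_reps", "flags"])
    g = df.groupby("f_Hz")
    out = pd.DataFrame({
        "Gp_Pa": g["Gp_Pa"].mean(),
        "Gpp_Pa": g["Gpp_Pa"].mean(),
        "loss_tangent": g["loss_tangent"].mean(),
        "Gp_sem_Pa": g["Gp_Pa"].sem(ddof=1),
        "Gpp_sem_Pa": g["Gpp_Pa"].sem(ddof=1),
        "loss_tangent_sem": g["loss_tangent"].sem(ddof=1),
        "n_reps": g["Gp_Pa"].size(),
        "flags": g["flags"].agg(lambda s: ";".join(x for x in s if x)),
    }).reset_index()
    return out.sort_values("f_Hz", ignore_index=True)
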