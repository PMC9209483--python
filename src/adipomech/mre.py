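"""Tabletop MRE inversion for cylindrical samples.

A cylindrical tissue sample sits in a vertically vibrated glass tube; shear
waves are excited at the cylinder wall and travel inward.  A
motion-sensitized phase-contrast sequence encodes the z-deflection (parallel
to the cylinder axis) into the image phase.  The inversion chain is

  1. spatial unwrapping of each phase frame inside the cylinder mask,
  2. temporal Fourier transform to the complex wave image at the drive
     frequency (convention u(t) = Re[U·e^{−iωt}]),
  3. azimuthal averaging onto a single complex radial profile u(r),
  4. complex nonlinear least-squares fit of the z-infinite-cylinder
     solution u(r) = U0·J0(k*·r), giving the complex wavenumber
     k* = k′ + i·k″ (J0: Bessel function of the first kind, order zero;
     axisymmetric z-polarized wave),
  5. conversion to shear wave speed and penetration rate,
         c = ω/k′,     a = −ω/(2π k″),
     and to the complex shear modulus,
         G* = ρ / (1/c − i/(2π a))²  (= ρ ω²/k*², an exact identity).

Sign convention: with the e^{−iωt} time dependence, attenuation implies
k″ < 0 so that the penetration rate a is positive.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special
from skimage.restoration import unwrap_phase as _unwrap_2d

from . import io as _io

__all__ = [
    "MREAcquisition",
    "ComplexWaveImage",
    "RadialProfile",
    "WavenumberFit",
    "unwrap_phase",
    "phase_residue_count",
    "temporal_fourier",
    "radial_average",
    "fit_cylinder_wave",
    "speed_and_penetration",
    "shear_modulus_from_ca",
    "invert_acquisition",
    "load_acquisition",
]

FLAG_HIGH_RESIDUE = "high_residue_count"
FLAG_LEAKAGE = "noninteger_cycles"
FLAG_POSITIVE_KPP = "positive_k_imag"


@dataclass
class MREAcquisition:
    """One MRE phase-image time series at a single drive frequency."""

    phase: np.ndarray            # (T, Ny, Nx) rad, possibly wrapped
    frequency: float             # Hz
    pixel_size: float            # m
    cylinder_radius: float       # m (inner radius of the tube)
    center: tuple[float, float] | None = None  # (row, col) px; image centre default
    encoding_efficiency: float = 1.0  # ξ, rad per m of deflection
    density: float = 1000.0      # ρ, kg/m³ (adipose preset ≈ 920)
    slice_thickness: float | None = None
    n_cycles: int = 1            # drive cycles spanned by the time steps

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be a (T, Ny, Nx) stack")
        if self.phase.shape[0] < 4:
            raise ValueError("need at least 4 time steps")
        if self.cylinder_radius <= 0 or self.pixel_size <= 0:
            raise ValueError("cylinder_radius and pixel_size must be > 0")
        if self.frequency <= 0 or self.density <= 0:
            raise ValueError("frequency and density must be > 0")
        if self.center is None:
            ny, nx = self.phase.shape[1:]
            self.center = ((ny - 1) / 2.0, (nx - 1) / 2.0)

    def radius_map(self) -> np.ndarray:
        """Distance of each pixel from the cylinder axis (m)."""
        ny, nx = self.phase.shape[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        cy, cx = self.center
        return np.hypot(yy - cy, xx - cx) * self.pixel_size

    def mask(self) -> np.ndarray:
        m = self.radius_map() <= self.cylinder_radius
        if not m.any():
            raise ValueError("cylinder mask is empty")
        return m


@dataclass
class ComplexWaveImage:
    """Complex deflection phasor U(x, y) (m) at the drive frequency."""

    field: np.ndarray          # complex (Ny, Nx); defined only inside mask
    mask: np.ndarray           # bool (Ny, Nx)
    frequency: float
    flags: tuple[str, ...] = ()


@dataclass
class RadialProfile:
    """Azimuthally averaged complex wave profile u(r)."""

    r: np.ndarray              # bin centers, m
    u: np.ndarray              # complex mean per bin (NaN for empty bins)
    counts: np.ndarray         # pixels per bin
    dispersion: np.ndarray     # per-bin SD of |U|


@dataclass(frozen=True)
class WavenumberFit:
    """Fitted complex wavenumber and the quantities derived from it."""

    k_real: float              # k′, 1/m
    k_imag: float              # k″, 1/m (≤ 0 for attenuating media)
    amplitude: complex         # U0, m
    residual_rms: float
    frequency: float           # Hz
    density: float             # kg/m³
    wave_speed: float          # c = ω/k′, m/s
    penetration_rate: float    # a = −ω/(2π k″), m/s (inf if k″ = 0)
    g_storage: float           # G′, Pa
    g_loss: float              # G″, Pa
    bessel_order: int = 0
    flags: tuple[str, ...] = ()

    @property
    def k_complex(self) -> complex:
        return complex(self.k_real, self.k_imag)


def phase_residue_count(wrapped: np.ndarray) -> int:
    """Count 2π residues (non-zero wrapped loop sums over 2×2 plaquettes).

    A large residue density signals inconsistent phase data that no path-
    following unwrapper can resolve cleanly.
    """
    def wrap(d):
        return (d + np.pi) % (2 * np.pi) - np.pi

    d1 = wrap(np.diff(wrapped, axis=1))[:-1, :]      # top edge
    d2 = wrap(np.diff(wrapped, axis=0))[:, 1:]       # right edge
    d3 = -wrap(np.diff(wrapped, axis=1))[1:, :]      # bottom edge (reversed)
    d4 = -wrap(np.diff(wrapped, axis=0))[:, :-1]     # left edge (reversed)
    loop = d1 + d2 + d3 + d4
    return int(np.sum(np.abs(loop) > np.pi))


def unwrap_phase(acquisition: MREAcquisition,
                 residue_density_limit: float = 0.05):
    """Spatially unwrap each phase frame inside the cylinder mask.

    Uses reliability-ordered 2-D unwrapping per time step; the per-frame
    mean over the mask (an arbitrary global phase offset) is subtracted.
    Returns ``(movie, flags)`` where ``movie`` is the unwrapped stack with
    zeros outside the mask.
    """
    mask = acquisition.mask()
    out = np.zeros_like(acquisition.phase)
    n_res = 0
    for j, frame in enumerate(acquisition.phase):
        n_res += phase_residue_count(frame)
        ma = np.ma.array(frame, mask=~mask)
        uw = np.ma.filled(_unwrap_2d(ma), 0.0)
        uw[mask] -= uw[mask].mean()
        out[j] = np.where(mask, uw, 0.0)
    flags: tuple[str, ...] = ()
    n_px = acquisition.phase.shape[0] * int(mask.sum())
    if n_px and n_res / n_px > residue_density_limit:
        warnings.warn("high phase-residue density; unwrapping unreliable")
        flags = (FLAG_HIGH_RESIDUE,)
    return out, flags


def temporal_fourier(movie: np.ndarray, acquisition: MREAcquisition,
                     flags: tuple[str, ...] = ()) -> ComplexWaveImage:
    """Extract the complex wave image at the drive frequency.

    With time steps t_j = j·n_cycles/(N·f) spanning an integer number of
    cycles, the first-harmonic coefficient under the u(t) = Re[U·e^{−iωt}]
    convention is U = (2/N) Σ_j φ_j e^{+iω t_j} / ξ.
    """
    n = movie.shape[0]
    j = np.arange(n)
    phases = np.exp(2j * np.pi * j * acquisition.n_cycles / n)
    U = 2.0 / n * np.tensordot(phases, movie, axes=(0, 0))
    U = U / acquisition.encoding_efficiency
    mask = acquisition.mask()
    return ComplexWaveImage(field=np.where(mask, U, 0.0), mask=mask,
                            frequency=acquisition.frequency, flags=flags)


def radial_average(image: ComplexWaveImage, center: tuple[float, float],
                   pixel_size: float, cylinder_radius: float,
                   n_bins: int = 32) -> RadialProfile:
    """Average the complex wave image over the azimuthal angle.

    Pixels are binned into ``n_bins`` annuli of equal radial width spanning
    [0, R_cyl]; each bin reports the complex mean of U at the annulus
    mid-radius.  Empty bins are NaN-marked, never zero-filled.
    """
    ny, nx = image.field.shape
    cy, cx = center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("center lies outside the image")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx) * pixel_size
    sel = image.mask & (r <= cylinder_radius)
    edges = np.linspace(0.0, cylinder_radius, n_bins + 1)
    idx = np.clip(np.digitize(r[sel], edges) - 1, 0, n_bins - 1)
    vals = image.field[sel]

    u = np.full(n_bins, np.nan, dtype=complex)
    counts = np.zeros(n_bins, dtype=int)
    disp = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = vals[idx == b]
        counts[b] = v.size
        if v.size:
            u[b] = v.mean()
            disp[b] = np.std(np.abs(v))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=centers, u=u, counts=counts, dispersion=disp)


def _bessel_model(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    u0 = p[0] + 1j * p[1]
    k = p[2] + 1j * p[3]
    c = (p[4] + 1j * p[5]) if p.size > 4 else 0.0
    return u0 * special.jv(0, k * r) + c


def fit_cylinder_wave(profile: RadialProfile, omega: float,
                      density: float = 1000.0,
                      fit_offset: bool = True) -> WavenumberFit:
    """Fit u(r) = U0·J0(k*·r) + C to the radial profile (complex least squares).

    The constant complex offset C (``fit_offset=True``, default) absorbs the
    spatial-mean gauge removed during per-frame unwrapping; it does not
    affect k*.  Multistart over k′ = ω/c0 for 8 log-spaced trial speeds
    c0 ∈ [1, 20] m/s with k″ = −k′/10; the start with the smallest residual
    wins, ties broken by smaller |k″|.  k′ is constrained positive and k″
    non-positive (attenuating-media convention).
    """
    ok = np.isfinite(profile.u)
    r = profile.r[ok]
    u = profile.u[ok]
    if r.size < 8:
        raise ValueError("need at least 8 usable radial bins")
    scale = float(np.max(np.abs(u)))
    if scale == 0.0:
        raise ValueError("profile is identically zero")
    # nondimensionalize: amplitudes in units of `scale`, wavenumbers in
    # units of 1/r_max, so the optimizer sees O(1) residuals and parameters
    r_max = float(r.max())
    un = u / scale
    rn = r / r_max
    data = np.concatenate([un.real, un.imag])

    def resid(p):
        m = _bessel_model(p, rn)
        return np.concatenate([m.real, m.imag]) - data

    lb = [-np.inf, -np.inf, 1e-9, -np.inf]
    ub = [np.inf, np.inf, np.inf, 0.0]
    if fit_offset:
        lb += [-np.inf, -np.inf]
        ub += [np.inf, np.inf]
    best = None
    for c0 in np.geomspace(1.0, 20.0, 8):
        kp0 = omega / c0 * r_max
        # amplitude start: profile value nearest the axis (J0(0) = 1)
        u00 = un[np.argmin(r)]
        x0 = [u00.real, u00.imag, kp0, -kp0 / 10.0]
        if fit_offset:
            x0 += [0.0, 0.0]
        try:
            sol = optimize.least_squares(resid, x0=x0, bounds=(lb, ub))
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        if (best is None or sol.cost < best.cost * (1 - 1e-9)
                or (abs(sol.cost - best.cost) <= 1e-9 * best.cost
                    and abs(sol.x[3]) < abs(best.x[3]))):
            best = sol
    if best is None:
        raise RuntimeError("cylinder-wave fit failed to converge from any start")

    u0 = complex(best.x[0], best.x[1]) * scale
    kp, kpp = float(best.x[2]) / r_max, float(best.x[3]) / r_max
    c, a = speed_and_penetration(complex(kp, kpp), omega)
    g = shear_modulus_from_ca(c, a, density)
    rms = float(np.sqrt(np.mean(best.fun**2))) * scale
    return WavenumberFit(
        k_real=kp, k_imag=kpp, amplitude=u0, residual_rms=rms,
        frequency=omega / (2 * np.pi), density=density,
        wave_speed=c, penetration_rate=a,
        g_storage=float(g.real), g_loss=float(g.imag))


def speed_and_penetration(k: complex, omega: float):
    """Shear wave speed and penetration rate: c = ω/k′, a = −ω/(2π k″).

    k″ = 0 yields a = +inf (lossless limit); a positive k″ (wrong sign under
    the adopted e^{−iωt} convention) is warned about and yields a < 0.
    """
    kp, kpp = k.real, k.imag
    if kp <= 0:
        raise ValueError("k' must be > 0")
    c = omega / kp
    if kpp == 0:
        return c, np.inf
    if kpp > 0:
        warnings.warn("k'' > 0: amplification under the e^{-iωt} convention")
    a = -omega / (2.0 * np.pi * kpp)
    return c, a


def shear_modulus_from_ca(c: float, a: float, rho: float) -> complex:
    """Complex shear modulus G* = ρ / (1/c − i/(2π a))².

    ``a = inf`` gives the elastic limit G* = ρc².  Algebraically identical
    to G* = ρω²/k*² for (c, a) derived from the same k*.
    """
    if c <= 0 or rho <= 0:
        raise ValueError("c and rho must be > 0")
    if not a > 0:
        raise ValueError("a must be > 0 (or inf for the lossless limit)")
    if np.isinf(a):
        return complex(rho * c * c, 0.0)
    return rho / (1.0 / c - 1j / (2.0 * np.pi * a)) ** 2


def invert_acquisition(acquisition: MREAcquisition,
                       n_bins: int = 32) -> WavenumberFit:
    """Full inversion chain for one acquisition.

    unwrap → temporal Fourier → radial average → Bessel fit → (c, a) → G*.
    """
    movie, flags = unwrap_phase(acquisition)
    img = temporal_fourier(movie, acquisition, flags=flags)
    prof = radial_average(img, acquisition.center, acquisition.pixel_size,
                          acquisition.cylinder_radius, n_bins=n_bins)
    omega = 2.0 * np.pi * acquisition.frequency
    fit = fit_cylinder_wave(prof, omega, density=acquisition.density)
    if flags:
        fit = dataclasses.replace(fit, flags=flags)
    return fit


def invert_to_table(acquisitions, n_bins: int = 32) -> pd.DataFrame:
    """Invert several acquisitions (one per drive frequency) into a tidy table."""
    rows = []
    for acq in acquisitions:
        fit = invert_acquisition(acq, n_bins=n_bins)
        rows.append({
            "f_Hz": fit.frequency, "kp_1_per_m": fit.k_real,
            "kpp_1_per_m": fit.k_imag, "c_m_s": fit.wave_speed,
            "a_m_s": fit.penetration_rate, "Gp_Pa": fit.g_storage,
            "Gpp_Pa": fit.g_loss, "residual": fit.residual_rms,
            "rho_kg_m3": fit.density, "bessel_order": fit.bessel_order,
            "flags": ";".join(fit.flags),
        })
    return pd.DataFrame(rows).sort_values("f_Hz", ignore_index=True)


def load_acquisition(stack_path: str | Path,
                     meta: str | Path | Mapping) -> MREAcquisition:
    """Load an acquisition from a multi-page TIFF plus YAML/TOML metadata."""
    import tifffile

    if not isinstance(meta, Mapping):
        meta = _io.load_config(meta)
    phase = tifffile.imread(stack_path)
    center = meta.get("center")
    return MREAcquisition(
        phase=np.asarray(phase, dtype=float),
        frequency=float(meta["frequency_Hz"]),
        pixel_size=float(meta["pixel_size_m"]),
        cylinder_radius=float(meta["cylinder_radius_m"]),
        center=tuple(center) if center is not None else None,
        encoding_efficiency=float(meta.get("encoding_efficiency_rad_per_m", 1.0)),
        density=float(meta.get("density_kg_m3", 1000.0)),
        slice_thickness=meta.get("slice_thickness_m"),
        n_cycles=int(meta.get("n_cycles", 1)),
    )
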