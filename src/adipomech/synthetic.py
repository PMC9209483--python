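"""Synthetic data generators with known ground truth.

Every analysis stage of the package has exactly one generator here that
inverts its measurement equation, so each stage is testable by parameter
recovery without any experimental data:

* :func:`gen_force_curve` — Hertzian approach curves with baseline,
  optional tilt and Gaussian force noise, solving the force–indentation
  coupling F = (4/3)E√R[(z − z0) − F/k]^{3/2}/(1 − ν²) exactly (the
  cantilever is not assumed infinitely stiff);
* :func:`gen_oscillation` — sinusoidal microrheology traces with a
  prescribed G*(f) model and an additive hydrodynamic drag force;
* :func:`gen_mre_movie` — wrapped phase movies of a J0(k*·r) cylinder
  shear wave;
* :func:`gen_fibril_image`, :func:`gen_droplet_image`,
  :func:`gen_tomogram` — striped/isotropic textures, disk droplets and
  ellipsoidal refractive-index volumes.

All generators are deterministic for a fixed spec and seed, and each file
writer emits a machine-readable ground-truth sidecar (JSON) next to the
data file.  Defaults mirror the experimental protocol the package analyses:
a 5 µm polystyrene bead (R = 2.5 µm) on a soft cantilever, a 2.5 nN
setpoint, 10 nm oscillation amplitude over 10 cycles, and a 64 × 64 MRE
matrix over a 9.6 mm field of view around an 8 mm inner-diameter tube.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .indentation import ForceCurve
from .mre import MREAcquisition
from .oscillation import OscillationSegment, hertz_prefactor

__all__ = [
    "ForceCurveSpec",
    "PowerLawModulus",
    "OscillationSpec",
    "MRESpec",
    "FibrilImageSpec",
    "DropletImageSpec",
    "TomogramSpec",
    "gen_force_curve",
    "gen_oscillation",
    "gen_mre_movie",
    "gen_fibril_image",
    "gen_droplet_image",
    "gen_tomogram",
    "write_force_curve",
    "write_oscillation",
    "write_mre_movie",
]


def _truth_sidecar(path: Path, payload: dict) -> None:
    side = path.with_suffix(path.suffix + ".truth.json")
    with open(side, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# force curves

@dataclass(frozen=True)
class ForceCurveSpec:
    """Ground truth for one synthetic Hertzian force curve (SI units)."""

    young_modulus: float           # E, Pa
    indenter_radius: float = 2.5e-6
    poisson_ratio: float = 0.5
    spring_constant: float = 0.04  # N/m
    setpoint: float = 2.5e-9       # N
    approach_speed: float = 5e-6   # m/s
    sampling_rate: float = 2000.0  # Hz
    baseline_length: float = 2e-6  # non-contact piezo travel, m
    baseline_tilt: float = 0.0     # N per m of piezo travel
    baseline_offset: float = 0.0   # N
    noise_sd: float = 0.0          # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.young_modulus < 0:
            raise ValueError("young_modulus must be ≥ 0")
        for name in ("indenter_radius", "spring_constant", "approach_speed",
                     "sampling_rate", "baseline_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _hertz_coeff(spec: ForceCurveSpec) -> float:
    return (4.0 / 3.0) * spec.young_modulus / (1.0 - spec.poisson_ratio**2) \
        * np.sqrt(spec.indenter_radius)


def _solve_contact_force(s: np.ndarray, C: float, k: float) -> np.ndarray:
    """Solve F = C·(s − F/k)^{3/2} for each piezo travel s past contact.

    Newton iteration on the monotone residual; exact force–indentation
    coupling, no stiff-cantilever approximation.
    """
    F = C * np.clip(s, 0.0, None) ** 1.5  # stiff-cantilever start (upper bound)
    for _ in range(60):
        d = np.clip(s - F / k, 0.0, None)
        g = C * d**1.5 - F
        dg = -1.5 * C * np.sqrt(d) / k - 1.0
        step = g / dg
        F_new = F - step
        # keep the indentation argument non-negative
        F_new = np.clip(F_new, 0.0, k * np.clip(s, 0.0, None))
        if np.max(np.abs(F_new - F)) < 1e-20 + 1e-14 * np.max(np.abs(F_new), initial=0.0):
            F = F_new
            break
        F = F_new
    return F


def gen_force_curve(spec: ForceCurveSpec) -> tuple[ForceCurve, dict]:
    """Generate a synthetic approach force curve.

    Returns ``(curve, truth)`` where ``truth`` records the generating
    parameters including the exact contact point ``z0``.  Raises if the
    setpoint is unreachable for a non-zero modulus.
    """
    rng = np.random.default_rng(spec.seed)
    dz = spec.approach_speed / spec.sampling_rate
    z0 = spec.baseline_length
    C = _hertz_coeff(spec)

    if spec.young_modulus > 0:
        # closed-form indentation at the setpoint plus cantilever deflection
        delta_sp = (spec.setpoint / C) ** (2.0 / 3.0)
        travel = delta_sp + spec.setpoint / spec.spring_constant
        z_max = z0 + 1.25 * travel
    else:
        z_max = z0 + 2e-6
    z = np.arange(0.0, z_max, dz)
    s = z - z0
    F = _solve_contact_force(s, C, spec.spring_constant) if spec.young_modulus > 0 \
        else np.zeros_like(z)

    if spec.young_modulus > 0:
        reach = np.flatnonzero(F >= spec.setpoint)
        if reach.size == 0:
            raise ValueError("setpoint unreachable within the height range")
        z = z[: reach[0] + 1]
        F = F[: reach[0] + 1]

    F = F + spec.baseline_offset + spec.baseline_tilt * z
    if spec.noise_sd > 0:
        F = F + rng.normal(0.0, spec.noise_sd, size=F.size)

    curve = ForceCurve(
        piezo_height=z, force=F,
        spring_constant=spec.spring_constant,
        indenter_radius=spec.indenter_radius,
        poisson_ratio=spec.poisson_ratio,
        approach_speed=spec.approach_speed,
        setpoint=spec.setpoint,
        curve_id=f"synthetic-E{spec.young_modulus:g}-seed{spec.seed}",
    )
    truth = dataclasses.asdict(spec) | {"stage": "force_curve", "z0_m": z0}
    return curve, truth


def write_force_curve(spec: ForceCurveSpec, path: str | Path) -> Path:
    """Write a synthetic curve as TSV (height, force in SI) plus sidecars."""
    curve, truth = gen_force_curve(spec)
    path = Path(path)
    df = pd.DataFrame({"height": curve.piezo_height, "force": curve.force})
    df.to_csv(path, sep="\t", index=False, float_format="%.12e")
    _truth_sidecar(path, truth)
    return path


def force_curve_ensemble(young_modulus: float, n: int, seed: int = 0,
                         noise_sd: float = 25e-12,
                         **kwargs) -> list[ForceCurve]:
    """Generate ``n`` independent noisy curves at one ground-truth modulus.

    Per-curve seeds are spawned deterministically from ``seed``; keyword
    arguments override the remaining :class:`ForceCurveSpec` defaults.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    curves = []
    for s in seeds:
        spec = ForceCurveSpec(young_modulus=young_modulus, noise_sd=noise_sd,
                              seed=int(s), **kwargs)
        curves.append(gen_force_curve(spec)[0])
    return curves


# ---------------------------------------------------------------------------
# oscillation / microrheology

@dataclass(frozen=True)
class PowerLawModulus:
    """Structural-damping power-law rheology G*(f) = G0·(1 + iη)·(f/f0)^α.

    η is the (frequency-independent) loss factor; α = 0 with η = 0 is a
    purely elastic solid.
    """

    g0: float                 # Pa
    eta: float = 0.0
    alpha: float = 0.0
    f0: float = 1.0           # Hz

    def __call__(self, f: float) -> complex:
        return self.g0 * (1.0 + 1j * self.eta) * (f / self.f0) ** self.alpha


@dataclass(frozen=True)
class OscillationSpec:
    """Ground truth for synthetic microrheology traces."""

    modulus: PowerLawModulus
    frequencies: tuple[float, ...] = (3.0, 10.0, 30.0, 100.0, 200.0)
    indenter_radius: float = 2.5e-6
    poisson_ratio: float = 0.5
    spring_constant: float = 0.08
    operating_indentation: float = 1e-6   # δ0, m
    amplitude: float = 10e-9              # m
    drag_b0: float = 0.0                  # N·s/m
    cycles: int = 10
    samples_per_cycle: int = 64
    force_noise_sd: float = 0.0           # N
    indentation_noise_sd: float = 0.0     # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_cycle < 10:
            raise ValueError("need at least 10 samples per cycle")
        for name in ("indenter_radius", "operating_indentation", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def gen_oscillation(spec: OscillationSpec) -> tuple[list[OscillationSegment], dict]:
    """Generate one oscillation segment per drive frequency.

    The force response is the exact inverse of the analysis chain:
    with H(f) = 4√(R δ0)·G*(f)/(1 − ν) the linearized contact stiffness,

        δ(t) = δ0 + A·cos(ωt)
        F(t) = F_DC + |H|·A·cos(ωt + arg H) + ω b(0)·A·cos(ωt + π/2) + noise,

    the drag entering as a separate additive quadrature force.  F_DC is the
    static Hertz force consistent with |G*| at the lowest frequency through
    E = 2(1 + ν)·G.
    """
    rng = np.random.default_rng(spec.seed)
    R, nu, d0, A = (spec.indenter_radius, spec.poisson_ratio,
                    spec.operating_indentation, spec.amplitude)
    f_min = min(spec.frequencies)
    e_static = 2.0 * (1.0 + nu) * abs(spec.modulus(f_min))
    f_dc = (4.0 / 3.0) * e_static / (1.0 - nu**2) * np.sqrt(R) * d0**1.5

    segments = []
    for f in spec.frequencies:
        w = 2.0 * np.pi * f
        n = spec.cycles * spec.samples_per_cycle
        t = np.arange(n) / (f * spec.samples_per_cycle)
        g = spec.modulus(f)
        H = g / hertz_prefactor(R, nu, d0)   # = 4√(Rδ0)·G*/(1−ν)
        delta = d0 + A * np.cos(w * t)
        force = (f_dc
                 + abs(H) * A * np.cos(w * t + np.angle(H))
                 + w * spec.drag_b0 * A * np.cos(w * t + np.pi / 2))
        if spec.force_noise_sd > 0:
            force = force + rng.normal(0.0, spec.force_noise_sd, n)
        if spec.indentation_noise_sd > 0:
            delta = delta + rng.normal(0.0, spec.indentation_noise_sd, n)
        segments.append(OscillationSegment(
            time=t, force=force, indentation=delta, frequency=f,
            indenter_radius=R, poisson_ratio=nu,
            spring_constant=spec.spring_constant,
            nominal_amplitude=A, operating_indentation=d0,
            segment_id=f"synthetic-f{f:g}-seed{spec.seed}"))
    truth = dataclasses.asdict(spec) | {
        "stage": "oscillation",
        "g_star": {f"{f:g}": [spec.modulus(f).real, spec.modulus(f).imag]
                   for f in spec.frequencies},
    }
    return segments, truth


def write_oscillation(spec: OscillationSpec, out_dir: str | Path) -> list[Path]:
    """Write one TSV per frequency (t, F, delta in SI) plus a truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments, truth = gen_oscillation(spec)
    paths = []
    for seg in segments:
        p = out_dir / f"oscillation_f{seg.frequency:g}Hz.tsv"
        pd.DataFrame({"t": seg.time, "force": seg.force,
                      "indentation": seg.indentation}).to_csv(
            p, sep="\t", index=False, float_format="%.12e")
        paths.append(p)
    _truth_sidecar(out_dir / "oscillation", truth)
    return paths


# ---------------------------------------------------------------------------
# MRE

@dataclass(frozen=True)
class MRESpec:
    """Ground truth for a synthetic MRE phase movie.

    Supply either the complex wavenumber ``k`` directly or the pair
    ``(wave_speed c, penetration_rate a)`` from which
    k* = ω·(1/c − i/(2π a)) is derived (k′ > 0, k″ < 0 branch).
    """

    frequency: float                     # Hz
    wave_speed: float | None = None      # c, m/s
    penetration_rate: float | None = None  # a, m/s
    k: complex | None = None             # 1/m
    density: float = 1000.0              # kg/m³
    shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.15e-3          # m
    cylinder_radius: float = 4.0e-3      # m (8 mm inner diameter)
    amplitude: float = 20e-6             # |U0|, m
    amplitude_phase: float = 0.0         # arg U0, rad
    encoding_efficiency: float = 4.0e4   # ξ, rad/m
    phase_offset: float = 0.0            # φ0, rad
    n_steps: int = 8
    phase_noise_sd: float = 0.0          # rad
    seed: int = 0

    def k_star(self) -> complex:
        if self.k is not None:
            return complex(self.k)
        if self.wave_speed is None or self.penetration_rate is None:
            raise ValueError("give either k or (wave_speed, penetration_rate)")
        w = 2.0 * np.pi * self.frequency
        return w * (1.0 / self.wave_speed - 1j / (2.0 * np.pi * self.penetration_rate))

    def g_star(self) -> complex:
        w = 2.0 * np.pi * self.frequency
        return self.density * w**2 / self.k_star() ** 2


def gen_mre_movie(spec: MRESpec) -> tuple[MREAcquisition, dict]:
    """Generate a wrapped phase movie of a J0(k*·r) cylinder shear wave.

    u(x, y, t) = Re[U0·J0(k*·r)·e^{−iωt}] inside the cylinder; the recorded
    phase is wrap(ξ·u + φ0) plus Gaussian phase noise.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k_star()
    if k.real * spec.cylinder_radius > 50:
        import warnings

        warnings.warn("k'·R_cyl > 50: wave unresolvably oscillatory on this grid")
    ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx) * spec.pixel_size
    inside = r <= spec.cylinder_radius
    U0 = spec.amplitude * np.exp(1j * spec.amplitude_phase)
    U = np.where(inside, U0 * special.jv(0, k * r), 0.0)

    t_idx = np.arange(spec.n_steps)
    movie = np.empty((spec.n_steps, ny, nx))
    for j in t_idx:
        u = np.real(U * np.exp(-2j * np.pi * j / spec.n_steps))
        phi = spec.encoding_efficiency * u + spec.phase_offset
        if spec.phase_noise_sd > 0:
            phi = phi + rng.normal(0.0, spec.phase_noise_sd, phi.shape)
        movie[j] = np.angle(np.exp(1j * phi))  # wrap to (−π, π]

    acq = MREAcquisition(
        phase=movie, frequency=spec.frequency, pixel_size=spec.pixel_size,
        cylinder_radius=spec.cylinder_radius, center=(cy, cx),
        encoding_efficiency=spec.encoding_efficiency, density=spec.density,
        n_cycles=1)
    truth = {
        "stage": "mre", "seed": spec.seed, "frequency_Hz": spec.frequency,
        "k_real_1_per_m": k.real, "k_imag_1_per_m": k.imag,
        "g_storage_Pa": spec.g_star().real, "g_loss_Pa": spec.g_star().imag,
        "density_kg_m3": spec.density,
    }
    return acq, truth


def write_mre_movie(spec: MRESpec, stack_path: str | Path) -> Path:
    """Write the movie as multi-page float32 TIFF + YAML metadata sidecar."""
    import tifffile

    from .io import save_yaml

    acq, truth = gen_mre_movie(spec)
    stack_path = Path(stack_path)
    tifffile.imwrite(stack_path, acq.phase.astype(np.float32))
    save_yaml({
        "frequency_Hz": acq.frequency,
        "pixel_size_m": acq.pixel_size,
        "cylinder_radius_m": acq.cylinder_radius,
        "center": list(acq.center),
        "encoding_efficiency_rad_per_m": acq.encoding_efficiency,
        "density_kg_m3": acq.density,
        "n_cycles": acq.n_cycles,
    }, stack_path.with_suffix(".yaml"))
    _truth_sidecar(stack_path, truth)
    return stack_path


# ---------------------------------------------------------------------------
# imaging fixtures

@dataclass(frozen=True)
class FibrilImageSpec:
    """Striped (or isotropic) fibril texture with known orientation."""

    shape: tuple[int, int] = (256, 256)
    orientation: float = 0.0     # stripe axis, rad
    period_px: float = 16.0
    coherence: float = 1.0       # 1 = pure stripes, 0 = pure noise
    noise_sd: float = 0.0
    seed: int = 0


def gen_fibril_image(spec: FibrilImageSpec) -> tuple[np.ndarray, dict]:
    """Sinusoidal stripes along ``orientation`` mixed with isotropic noise."""
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    # intensity varies perpendicular to the stripe axis
    qx = np.cos(spec.orientation + np.pi / 2)
    qy = np.sin(spec.orientation + np.pi / 2)
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * (xx * qx + yy * qy) / spec.period_px)
    noise = rng.standard_normal((ny, nx))
    img = spec.coherence * stripes + (1.0 - spec.coherence) * noise
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    truth = dataclasses.asdict(spec) | {"stage": "fibrils"}
    return img, truth


@dataclass(frozen=True)
class DropletImageSpec:
    """Disk-shaped droplets with listed radii (µm) on a dark background."""

    radii_um: tuple[float, ...] = (1.0, 2.0)
    centers_px: tuple[tuple[float, float], ...] | None = None
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.2      # µm
    noise_sd: float = 0.0
    seed: int = 0


def gen_droplet_image(spec: DropletImageSpec) -> tuple[np.ndarray, dict]:
    """Binary-contrast disks plus optional Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    img = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    centers = spec.centers_px
    if centers is None:
        # deterministic grid placement with margins
        n = len(spec.radii_um)
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        centers = tuple(
            ((i // cols + 0.5) * ny / rows, (i % cols + 0.5) * nx / cols)
            for i in range(n))
    for (cy, cx), r_um in zip(centers, spec.radii_um):
        r_px = r_um / spec.pixel_size
        if (cy - r_px < 0 or cy + r_px >= ny or cx - r_px < 0 or cx + r_px >= nx):
            raise ValueError("droplet exceeds the canvas")
        img[np.hypot(yy - cy, xx - cx) <= r_px] = 1.0
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    truth = dataclasses.asdict(spec) | {
        "stage": "droplets",
        "areas_um2": [float(np.pi * r**2) for r in spec.radii_um],
    }
    return img, truth


@dataclass(frozen=True)
class TomogramSpec:
    """Ellipsoidal refractive-index volume with known analytic volume."""

    semiaxes_um: tuple[float, float, float] = (10.0, 10.0, 10.0)  # (az, ay, ax)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.25, 0.25)  # (dz, dy, dx)
    margin_um: float = 2.0
    n_background: float = 1.337
    n_contrast: float = 0.03
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def volume_um3(self) -> float:
        az, ay, ax = self.semiaxes_um
        return 4.0 / 3.0 * np.pi * az * ay * ax


def gen_tomogram(spec: TomogramSpec) -> tuple[np.ndarray, dict]:
    """Ellipsoid of elevated RI centred in a background-RI volume."""
    rng = np.random.default_rng(spec.seed)
    dims = []
    for a, d in zip(spec.semiaxes_um, spec.voxel_size_um):
        dims.append(int(np.ceil(2 * (a + spec.margin_um) / d)) | 1)
    nz, ny, nx = dims
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az, ay, ax = spec.semiaxes_um
    dz, dy, dx = spec.voxel_size_um
    inside = (((zz - cz) * dz / az) ** 2 + ((yy - cy) * dy / ay) ** 2
              + ((xx - cx) * dx / ax) ** 2) <= 1.0
    vol = np.full(dims, spec.n_background)
    vol[inside] += spec.n_contrast
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)
    truth = dataclasses.asdict(spec) | {
        "stage": "tomogram", "volume_um3": spec.volume_um3}
    return vol, truth
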