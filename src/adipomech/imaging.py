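"""Image-derived morphometrics for adipocyte biology.

Covers the quantities read off fluorescence images, refractive-index
tomograms and Brillouin point measurements:

* F-actin fibril anisotropy from the nematic tensor of local gradient
  orientations (the FibrilTool protocol: score = eigenvalue difference of
  the ROI-averaged unit-orientation tensor, 0 isotropic … 1 aligned);
* stress-fibril counting as local maxima along a cross-section profile;
* lipid-droplet segmentation and size classing (a deterministic
  threshold-and-label stand-in for interactive ML pixel classification);
* nuclear-to-cytoplasmic intensity ratio (YAP/TAZ localisation);
* cell volume from a refractive-index tomogram by thresholding;
* longitudinal modulus from the Brillouin shift, M = ρ·(λ ν_B / 2n)².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from skimage import filters, measure, segmentation

__all__ = [
    "AnisotropyResult",
    "DropletSegmentation",
    "VolumeResult",
    "BrillouinPoint",
    "fibril_anisotropy",
    "count_fibrils",
    "segment_droplets",
    "classify_droplets",
    "nuclear_cytoplasmic_ratio",
    "tomogram_volume",
    "longitudinal_modulus",
]

#: default droplet size-class edges in µm² (small / intermediate / large);
#: configurable — the boundaries are a convention, not a measured quantity.
DEFAULT_DROPLET_CLASS_EDGES = (0.0, 10.0, 50.0, np.inf)
DROPLET_CLASS_NAMES = ("small", "intermediate", "large")


@dataclass(frozen=True)
class AnisotropyResult:
    """Fibril anisotropy of an image region.

    ``score`` ∈ [0, 1] is the eigenvalue difference λ1 − λ2 of the
    ROI-averaged nematic orientation tensor; ``orientation`` is the
    principal fibril axis in radians within (−π/2, π/2] (NaN when the score
    is zero, where no axis is defined).
    """

    score: float
    orientation: float   # rad
    n_pixels: int


@dataclass
class DropletSegmentation:
    """Labelled lipid droplets and their cross-sectional areas."""

    labels: np.ndarray           # int label image
    areas: np.ndarray            # µm² per droplet (label order 1..n)
    pixel_size: float            # µm
    threshold: float = np.nan


@dataclass(frozen=True)
class VolumeResult:
    """Thresholded tomogram volume."""

    volume: float                # µm³
    threshold: float             # refractive-index threshold used
    voxel_size: tuple            # (dz, dy, dx) µm
    n_voxels: int
    over_segmentation: bool = False


@dataclass(frozen=True)
class BrillouinPoint:
    """One Brillouin point measurement and its longitudinal modulus."""

    shift: float                 # ν_B, Hz
    refractive_index: float      # n
    wavelength: float            # λ, m
    density: float               # ρ, kg/m³

    def __post_init__(self) -> None:
        for name in ("shift", "refractive_index", "wavelength", "density"):
            if getattr(self, name) < 0 or (name != "shift" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @property
    def longitudinal_modulus(self) -> float:
        return longitudinal_modulus(self.shift, self.refractive_index,
                                    self.wavelength, self.density)


def fibril_anisotropy(image: np.ndarray, roi: np.ndarray | None = None,
                      sigma: float = 1.0, min_pixels: int = 100) -> AnisotropyResult:
    """Fibril anisotropy from the nematic tensor of gradient orientations.

    The local fibril direction is taken perpendicular to the intensity
    gradient (after Gaussian smoothing with ``sigma`` pixels).  Unit
    orientation vectors t = (tx, ty) of all ROI pixels with non-zero
    gradient are averaged as the nematic tensor M = ⟨t⊗t⟩ (trace 1); the
    score is λ1 − λ2 ∈ [0, 1] and the orientation the principal eigenvector
    angle.

    A constant image has no gradients anywhere: score 0, orientation NaN.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    sm = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    gy, gx = np.gradient(sm)
    mag2 = gx**2 + gy**2
    sel = mag2 > 1e-12 * max(float(mag2.max()), 1e-300)
    if roi is not None:
        sel &= np.asarray(roi, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        return AnisotropyResult(score=0.0, orientation=np.nan, n_pixels=0)
    if n < min_pixels:
        raise ValueError(f"ROI has only {n} gradient pixels (< {min_pixels})")
    norm = np.sqrt(mag2[sel])
    # fibril tangent: gradient rotated by 90°
    tx = -gy[sel] / norm
    ty = gx[sel] / norm
    mxx = float(np.mean(tx * tx))
    mxy = float(np.mean(tx * ty))
    myy = float(np.mean(ty * ty))
    # eigenvalue difference of [[mxx, mxy], [mxy, myy]] (trace = 1)
    score = float(np.sqrt((mxx - myy) ** 2 + 4.0 * mxy**2))
    if score == 0.0:
        return AnisotropyResult(score=0.0, orientation=np.nan, n_pixels=n)
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    # fold to (−π/2, π/2] (nematic: axis, not direction)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return AnisotropyResult(score=min(score, 1.0), orientation=float(theta),
                            n_pixels=n)


def count_fibrils(image: np.ndarray, start: Sequence[float],
                  end: Sequence[float], min_prominence: float,
                  min_separation_px: float = 3.0) -> int:
    """Count stress fibrils as intensity maxima along a cross-section.

    The intensity profile is sampled along the line from ``start`` to
    ``end`` (row, col coordinates) and local maxima above
    ``min_prominence`` separated by at least ``min_separation_px`` are
    counted.  Closer peaks merge into one, by design.
    """
    img = np.asarray(image, dtype=float)
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("degenerate cross-section line of length 0")
    n = max(int(np.ceil(length)) + 1, 2)
    rows = np.linspace(p0[0], p1[0], n)
    cols = np.linspace(p0[1], p1[1], n)
    profile = ndimage.map_coordinates(img, [rows, cols], order=1,
                                      mode="nearest")
    peaks, _ = signal.find_peaks(profile, prominence=min_prominence,
                                 distance=max(min_separation_px, 1))
    return int(peaks.size)


def segment_droplets(image: np.ndarray, pixel_size: float,
                     threshold: float | None = None,
                     min_area: float = 0.5,
                     split_touching: bool = False) -> DropletSegmentation:
    """Segment lipid droplets in a neutral-lipid stain image.

    Deterministic stand-in for interactive ML pixel classification: global
    automatic threshold (Otsu unless given), hole filling, connected
    components, and an optional watershed split of touching droplets.
    ``min_area`` is in µm²; an empty segmentation is a valid empty result.
    """
    img = np.asarray(image, dtype=float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if img.max() == img.min():
        return DropletSegmentation(labels=np.zeros(img.shape, dtype=int),
                                   areas=np.array([]), pixel_size=pixel_size,
                                   threshold=np.nan)
    thr = float(filters.threshold_otsu(img)) if threshold is None else threshold
    binary = ndimage.binary_fill_holes(img > thr)
    if split_touching:
        dist = ndimage.distance_transform_edt(binary)
        coords = _distance_peaks(dist)
        markers = np.zeros(img.shape, dtype=int)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        labels = segmentation.watershed(-dist, markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary)
    props = measure.regionprops(labels)
    keep = [p for p in props if p.area * pixel_size**2 >= min_area]
    out = np.zeros(img.shape, dtype=int)
    areas = []
    for i, p in enumerate(keep, start=1):
        out[labels == p.label] = i
        areas.append(p.area * pixel_size**2)
    return DropletSegmentation(labels=out, areas=np.asarray(areas),
                               pixel_size=pixel_size, threshold=thr)


def _distance_peaks(dist: np.ndarray) -> np.ndarray:
    from skimage.feature import peak_local_max

    return peak_local_max(dist, min_distance=3, exclude_border=False)


def classify_droplets(seg: DropletSegmentation | np.ndarray,
                      bin_edges: Sequence[float] = DEFAULT_DROPLET_CLASS_EDGES):
    """Histogram droplet areas into size classes.

    Returns ``(counts, fractions)`` arrays over the classes defined by the
    strictly increasing ``bin_edges`` (µm²).  Fractions sum to 1 over the
    detected droplets; an empty segmentation yields all-zero counts and
    NaN fractions.
    """
    areas = seg.areas if isinstance(seg, DropletSegmentation) else np.asarray(seg)
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(areas, bins=edges)
    total = counts.sum()
    fractions = counts / total if total else np.full(counts.shape, np.nan)
    return counts, fractions


def nuclear_cytoplasmic_ratio(image: np.ndarray, nucleus_mask: np.ndarray,
                              cell_mask: np.ndarray,
                              background: float = 0.0) -> float:
    """Mean nuclear over mean cytoplasmic intensity, background-subtracted.

    The cytoplasm is the cell mask minus the nucleus mask; both compartments
    must contain at least 20 pixels.  Zero cytoplasmic intensity yields
    +inf (fully nuclear localisation).
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cyto = np.asarray(cell_mask, dtype=bool) & ~nuc
    if nuc.sum() < 20 or cyto.sum() < 20:
        raise ValueError("nucleus and cytoplasm masks need ≥ 20 pixels each")
    num = float(img[nuc].mean()) - background
    den = float(img[cyto].mean()) - background
    if den == 0:
        return np.inf
    return num / den


def tomogram_volume(tomogram: np.ndarray, voxel_size: Sequence[float],
                    n_threshold: float,
                    n_background: float | None = None) -> VolumeResult:
    """Cell volume from a refractive-index tomogram by thresholding.

    Voxels with RI above ``n_threshold`` form the cell candidate; only the
    largest connected component is counted.  The background RI is estimated
    from the border voxels (median) unless given; a threshold at or below it
    flags likely over-segmentation.  ``voxel_size`` is (dz, dy, dx) in µm
    and the volume is returned in µm³.
    """
    vol = np.asarray(tomogram, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D tomogram")
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError("voxel_size must be three positive lengths")
    if n_background is None:
        border = np.concatenate([
            vol[0].ravel(), vol[-1].ravel(),
            vol[:, 0].ravel(), vol[:, -1].ravel(),
            vol[:, :, 0].ravel(), vol[:, :, -1].ravel()])
        n_background = float(np.median(border))
    over = n_threshold <= n_background
    mask = vol > n_threshold
    if not mask.any():
        return VolumeResult(volume=0.0, threshold=n_threshold, voxel_size=vs,
                            n_voxels=0, over_segmentation=over)
    labels, n_lab = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_lab + 1))
    n_vox = int(sizes.max())
    return VolumeResult(volume=n_vox * vs[0] * vs[1] * vs[2],
                        threshold=n_threshold, voxel_size=vs,
                        n_voxels=n_vox, over_segmentation=bool(over))


def longitudinal_modulus(shift: float, refractive_index: float,
                         wavelength: float, density: float) -> float:
    """Longitudinal modulus from a Brillouin shift (backscattering geometry).

    M = ρ · (λ ν_B / 2n)², with ν_B the Brillouin frequency shift (Hz),
    λ the probe wavelength (m), n the refractive index and ρ the mass
    density (kg/m³).  Returns M in Pa.
    """
    if refractive_index <= 0 or wavelength <= 0 or density <= 0:
        raise ValueError("refractive index, wavelength and density must be > 0")
    if shift < 0:
        raise ValueError("Brillouin shift must be ≥ 0")
    v = wavelength * shift / (2.0 * refractive_index)
    return density * v * v
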