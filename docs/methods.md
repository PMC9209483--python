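# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## AFM indentation

**Contact model.** The default model is the paraboloidal Hertz
approximation for a rigid sphere of radius R on an incompressible elastic
half-space,

    F = (4/3) · E/(1 − ν²) · √R · δ^{3/2},

valid for indentation depths δ well below R. This is the community default
for colloidal-probe cell indentation at δ ≲ 2 µm with R = 2.5–5 µm beads.
The exact Sneddon sphere solution — F = E/(1−ν²)·[(a²+R²)/2·ln((R+a)/(R−a))
− aR] with contact radius a solving δ = (a/2)·ln((R+a)/(R−a)) — is exposed
via `model="sneddon"` for deeper indentations; at δ ~ R the paraboloidal
form overestimates the force (by ~10% at δ = 0.8 R), which bounds the model
error of the default.

**Tip–sample separation.** The recorded piezo travel z is converted to true
indentation δ = (z − z₀) − F/k, subtracting the cantilever deflection F/k.
The synthetic generator solves the resulting implicit coupling
F = (4/3)E√R[(z − z₀) − F/k]^{3/2}/(1 − ν²) exactly (Newton iteration to
1e-14 relative), so this correction is tested honestly rather than against
a stiff-cantilever approximation.

**Contact point and baseline.** The paper-style processing software detects
contact implicitly; here the procedure is explicit and logged:

1. a linear baseline (offset + tilt) is fitted over the first 60% of the
   approach; the window is then iteratively shrunk to the detected
   pre-contact region (up to 8 passes) so a contact onset inside the
   initial window cannot contaminate the fit;
2. the contact point is the last sub-threshold sample before the first run
   of 5 consecutive samples above 3× the baseline noise SD;
3. in the final least squares, the contact point *and* the baseline offset
   and tilt are refined jointly with the modulus.

Step 3 goes beyond refining z₀ alone because for very soft samples
(E ≲ 200 Pa at a 2.5 nN setpoint) the force onset is so gradual that any
windowed baseline estimate retains a small tilt error which propagates into
a percent-level modulus bias; joint refinement restores recovery to better
than 1e-4 relative across E ∈ [0.1, 50] kPa (verified by the round-trip
property test). All fits are nondimensionalized (forces in units of the
curve maximum, depths in units of the maximum separation) so the optimizer
works on O(1) quantities regardless of the SI magnitudes.

**Fit window and rejection.** Fits use approach data only, from the start
of the record (the pre-contact baseline anchors the contact refinement) to
the first crossing of the force setpoint taken from metadata (2.5 nN for
the single-cell protocol; 2 nN cells / 4 nN tissue in the microrheology
protocol). Curves are rejected with typed reasons: fewer than 50 samples,
non-monotone approach height, saturated deflection, no detectable baseline,
no contact. Negative moduli from degenerate fits are clipped to zero and
flagged, never silently reported.

**Force maps.** Tissue grids (e.g. 4 × 4 positions over 200 µm × 200 µm)
are aggregated per region and per sample as median, mean and SEM over
accepted fits only, with rejection counts retained; an empty region yields
NaN, never zero. Because the acquisition protocol does not fix whether
summaries were taken per-region or per-animal before statistics, both
levels are emitted.

## AFM oscillatory microrheology

**Estimator.** Each force and indentation trace is fitted in the time
domain with s(t) = A·cos(2πft + θ) + c₀ + c₁t (least squares; offset and
linear drift included). Amplitudes are non-negative by construction and
phases wrapped to (−π, π]. A single-bin discrete Fourier estimator is kept
as an independent cross-check; the two agree to better than 0.1% on clean
integer-cycle records (tested). At least 3 cycles and 8 samples per cycle
are required; the default record is 10 cycles, matching the acquisition
protocol.

**Transfer ratio and prefactor.** The complex ratio
F(ω)/δ(ω) = (A^F/A^δ)·e^{i(θ^F−θ^δ)} is converted to the complex shear
modulus with the linearized-Hertz prefactor (1 − ν)/(4√(R δ₀)). The
operating indentation δ₀ defaults to the measured DC offset of the
indentation fit; the nominal ≈ 1 µm value from metadata is the logged
fallback. A phase difference outside [0, π/2] is physically impossible for
a passive viscoelastic response and is flagged, not clipped.

**Drag correction.** The hydrodynamic drag of the medium on the oscillating
cantilever adds iω·b(0) to the measured ratio; it is subtracted before the
prefactor. b(h) calibrations are extrapolated linearly to h = 0 (the
default model; choice logged), with at least two distances required and
negative extrapolations clipped to zero with a warning. Injecting the
literature drag coefficient for the soft triangular cantilevers used with
adipocytes, b(0) = 5.28 µN·s/m, and correcting with the same value is the
identity to numerical precision (tested); on the synthetic power-law medium
the corrected G′ and G″ match the generator to < 1% at every frequency of
the 3–200 Hz grid.

**Spectra.** Repetitions at the same frequency are averaged (mean ± SEM of
G′, G″ and loss tangent); a frequency at which all repetitions fail is a
gap, never an interpolation. The 10 nm vs 30 nm drive amplitude is treated
as metadata with no behavioural difference.

## Tabletop MRE inversion

**Chain.** Per drive frequency (400–1400 Hz grid): (1) each wrapped phase
frame is unwrapped inside the cylinder mask with reliability-ordered 2-D
unwrapping (`skimage.restoration.unwrap_phase`) and its mask mean is
subtracted; (2) the temporal first harmonic under the u(t) = Re[U·e^{−iωt}]
convention gives the complex wave image, divided by the motion-encoding
efficiency ξ to yield meters; (3) pixels are averaged azimuthally into
equal-width annular bins (default 32) spanning [0, R_cyl]; (4) the radial
profile is fitted with

    u(r) = U₀ · J₀(k*·r) + C,

complex nonlinear least squares over complex U₀, k* and C.

**Why the offset C.** Subtracting the per-frame mask mean is necessary —
path-following unwrappers return each frame only up to an arbitrary
additive constant (a multiple of 2π plus the encoding offset), and those
constants would otherwise leak into the temporal harmonic. But the
subtraction also removes the spatial mean of the wave signal itself, which
appears in the wave image as one constant complex offset. C absorbs it
exactly; it is a gauge parameter and does not bias k* (gauge invariance is
property-tested).

**Bessel order and sign conventions.** Order zero (axisymmetric z-polarized
wave driven from the cylinder wall) is the adopted reading; the order is
recorded in the output. With the e^{−iωt} time convention, attenuation
means k″ < 0, so the penetration rate a = −ω/(2πk″) is positive; the fit
constrains k′ > 0 and k″ ≤ 0, and externally supplied k″ > 0 is flagged,
not silently negated. The conversions c = ω/k′, a = −ω/(2πk″) and
G* = ρ/(1/c − i/(2πa))² satisfy G* = ρω²/k*² identically; the
implementation preserves this to 1e-12 relative (tested). A lossless medium
(k″ = 0) reports a = +inf and G* = ρc².

**Initialization and degeneracy.** The fit multistarts from
k′ = ω/c₀ for 8 log-spaced trial speeds c₀ ∈ [1, 20] m/s with k″ = −k′/10;
the lowest-residual start wins, ties broken by smaller |k″|. The fit is
nondimensionalized (amplitudes by the profile maximum, wavenumbers by
1/r_max). An all-zero profile, fewer than 8 usable bins, or failure from
every start raise errors with no numeric output. Frames with a high phase-
residue density (inconsistent wrapped data) are flagged.

**Density.** The tissue density entering G* is not measurable from the
phase data; the default is 1000 kg/m³ (adipose ≈ 920 kg/m³ available as a
preset), configurable, and recorded in every output row.

## Image morphometrics

**Fibril anisotropy.** After Gaussian smoothing (σ = 1 px), per-pixel
orientation is taken perpendicular to the intensity gradient; unit
orientation vectors of all ROI pixels with non-zero gradient are averaged
as the nematic tensor M = ⟨t⊗t⟩ (trace 1), and the score is the eigenvalue
difference λ₁ − λ₂ ∈ [0, 1] with the principal eigenvector as mean
orientation — the FibrilTool protocol. A constant image scores 0 with
undefined orientation. The score is invariant under 90° rotation and the
isotropic-noise null stays below 0.05 for ≥ 10⁴ pixels (both tested).

**Stress-fibril counts.** Intensity is sampled along a user-supplied
cross-section (linear interpolation) and local maxima above a prominence
threshold, separated by a minimum distance, are counted with
`scipy.signal.find_peaks`. Peaks closer than the minimum separation merge
— documented behaviour, not an error.

**Droplet segmentation.** A deterministic stand-in for interactive ML pixel
classification: global Otsu threshold (or a supplied one), hole filling,
connected components, optional watershed splitting of touching droplets,
and a minimum-area filter (default 0.5 µm²). Size classes default to
0–10 / 10–50 / > 50 µm² — arbitrary but configurable boundaries chosen to
span the biologically relevant range. Area error for a disk of radius
r px is bounded by the perimeter-pixel fraction, ~2/r relative (tested to
shrink with radius).

**Tomogram volume.** Voxels above an RI threshold form the cell candidate;
only the largest connected component is counted and multiplied by the voxel
volume. Background RI is estimated as the median of the border voxels
unless supplied; a threshold at or below background flags likely
over-segmentation. Volume is monotone non-increasing in the threshold and
scales exactly with the cube of the declared voxel size (both tested).

**Brillouin longitudinal modulus.** M = ρ·(λν_B/(2n))² in backscattering
geometry. The density and probe wavelength are required inputs: the
combined-setup instrument papers define the density model, and the Brillouin
wavelength is instrument-specific, so neither is assumed here.

## Synthetic generators

Each analysis equation has exactly one generator that inverts it; the
round-trip pairs are enumerated in the test suite. Defaults are the study
conditions: R = 2.5 µm bead, ν = 0.5, k = 0.04 N/m, 2.5 nN setpoint and
5 µm/s approach for force curves (2 kHz sampling, 2 µm non-contact
baseline); 10 nm amplitude, 10 cycles, δ₀ = 1 µm, 3–200 Hz grid for
oscillations; 64 × 64 matrix, 0.15 mm pixels, 8 mm inner-diameter cylinder,
8 time steps for MRE movies. Noise is additive Gaussian (force noise on the
pN scale, phase noise on the 0.01–0.1 rad scale); seeds are explicit,
outputs are byte-reproducible, and every file writer emits a
machine-readable ground-truth sidecar.

What the generators deliberately do **not** emulate: cantilever dynamics
beyond the additive drag term, instrument drift other than linear baseline
tilt, MRI acquisition physics (the phase movie is the ideal encoded wave),
confocal point-spread functions, out-of-plane wave components, and
population heterogeneity between curves of an ensemble. Passing recovery
tests therefore demonstrate the correctness of the inversion mathematics
and its noise robustness at realistic levels — not robustness to every
instrumental artefact of real acquisitions.

## Problem sizes

The acceptance script uses 200-curve ensembles (~2000 samples per curve)
per modulus target; the test suite uses 64 × 64 × 8 MRE movies, 100-seed
Monte-Carlo ensembles for the noisy-profile and noisy-movie checks, and
128–256 px image fixtures. These sizes put every Monte-Carlo standard error
comfortably below the tolerance it is tested against while keeping the full
suite under half a minute.

## Known limitations

* The Hertz fit assumes a homogeneous, isotropic, elastic half-space;
  apparent moduli from cells and tissues are effective quantities and
  depth-dependence is not modelled (no stress-relaxation or adhesion
  analysis; retract data are ignored).
* Microrheology assumes small oscillations about a fixed δ₀; the linearized
  prefactor is first-order in A/δ₀ (1% at A/δ₀ = 0.01 as used).
* The MRE inversion is single-slice and axisymmetric (J₀ only); azimuthal
  wave components average out rather than being modelled, and the wall
  boundary condition is not imposed — the complex amplitude is free.
* Droplet segmentation is intensity-based; it is a reproducible stand-in,
  not a re-implementation of ML pixel classification, and will undercount
  in low-contrast images where a trained classifier would not.
* Vendor binary formats (JPK/Bruker) are out of scope; inputs are delimited
  text, TIFF stacks and YAML/TOML sidecars.
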