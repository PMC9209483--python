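# adipomech

Mechanical analysis of adipocytes and adipose tissue, as a tested,
reusable Python package.

Adipocytes soften dramatically as they differentiate and fill with lipid
droplets, and quantifying that change requires several complementary
mechanical probes, each with its own inversion mathematics. `adipomech`
implements the complete analysis chain for four of them:

* **AFM indentation** — force–distance curves from a colloidal (spherical)
  probe are baseline-corrected, contact-detected, converted to tip–sample
  separation δ = (z − z₀) − F/k, and fitted with the spherical Hertz model

  F = (4/3) · E/(1 − ν²) · √R · δ^{3/2},

  yielding the apparent Young's modulus *E* (the exact Sneddon sphere
  solution is available for deep indentations). Grid-based tissue force
  maps are aggregated into per-region summaries.

* **AFM oscillatory microrheology** — small sinusoidal oscillations about an
  operating indentation δ₀ give the complex shear modulus through the
  linearized Hertz relation

  G*(ω) = G′ + iG″ = (1 − ν)/(4√(R δ₀)) · [F(ω)/δ(ω) − iω·b(0)],

  where F(ω)/δ(ω) = (A^F/A^δ)·e^{i(θ^F−θ^δ)} is formed from per-frequency
  harmonic fits and b(0) is the hydrodynamic drag coefficient of the
  cantilever extrapolated to zero sample distance.

* **Tabletop MRE** (magnetic resonance elastography) — wrapped phase movies
  of shear waves in a cylindrical sample are unwrapped, Fourier-transformed
  in time, azimuthally averaged, and fitted with the z-infinite-cylinder
  solution u(r) = U₀·J₀(k*·r) to obtain the complex wavenumber
  k* = k′ + ik″, converted to wave speed and penetration rate

  c = ω/k′,  a = −ω/(2π k″),

  and to the complex shear modulus G* = ρ/(1/c − i/(2πa))².

* **Image morphometrics** — F-actin fibril anisotropy (nematic orientation
  tensor), stress-fibril counting along cross-sections, lipid-droplet
  segmentation and size classing, nuclear/cytoplasmic intensity ratios,
  cell volume from refractive-index tomograms, and the Brillouin
  longitudinal modulus M = ρ·(λν_B/2n)².

Every analysis stage has a matching generator in `adipomech.synthetic`
that inverts its measurement equation from an explicit ground-truth
parameter bundle, so the whole pipeline is verifiable by parameter
recovery — no experimental data required.

## Worked example

Generate a noisy synthetic force curve at a known modulus and run the full
indentation pipeline:

```python
from adipomech import synthetic as syn, indentation as ind

curve, truth = syn.gen_force_curve(
    syn.ForceCurveSpec(young_modulus=1000.0, noise_sd=25e-12, seed=42))
fit = ind.analyze_curve(curve)
print(f"apparent Young's modulus: {fit.apparent_young_modulus:.1f} Pa")
print(f"contact point:            {fit.contact_point*1e6:.3f} um")
print(f"max indentation:          {fit.max_indentation*1e6:.3f} um")
print(f"residual RMS:             {fit.residual_rms*1e12:.1f} pN")
```

```
apparent Young's modulus: 999.6 Pa
contact point:            1.999 um
max indentation:          0.921 um
residual RMS:             25.1 pN
```

The fit recovers the 1 kPa ground truth to 0.04% from a curve carrying
25 pN of force noise; the residual RMS equals the injected noise level, and
the contact point lands on the generator's 2 µm baseline length.

The same pattern runs end-to-end for MRE:

```python
from adipomech import synthetic as syn, mre

spec = syn.MRESpec(frequency=800.0, wave_speed=3.0, penetration_rate=2.0)
acq, truth = syn.gen_mre_movie(spec)
fit = mre.invert_acquisition(acq)
print(f"c = {fit.wave_speed:.3f} m/s, a = {fit.penetration_rate:.3f} m/s, "
      f"G' = {fit.g_storage:.0f} Pa, G'' = {fit.g_loss:.0f} Pa")
```

```
c = 2.998 m/s, a = 1.999 m/s, G' = 7588 Pa, G'' = 3841 Pa
```

i.e. the wave parameters written into the 64 × 64 × 8 phase movie are
recovered to 0.1% and the moduli to ≈ 0.1–0.2%.

Command-line equivalents (`adipomech simulate`, `adipomech fit-indentation`,
`adipomech microrheology`, `adipomech mre-invert`, `adipomech imaging …`,
`adipomech summarize`) write tidy CSV tables plus a `run_config.yaml` that
makes every output directory reproducible.

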