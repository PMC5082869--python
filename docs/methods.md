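# Methods

This note documents the models, parameter choices and numerical decisions
behind `pseudohe`, and what its synthetic-data tests do and do not
demonstrate about real acquisitions.

## Pipeline model and ordering

The pipeline realizes the processing chain of a two-channel (DRAQ5 +
eosin) fluorescence instrument with optional grid-projection structured
illumination:

1. **Normalization.** Camera frames are unsigned 16-bit; they are converted
   to float64 by dividing by the fixed full scale 65535, never by a
   per-image maximum. Per-image scaling would destroy the radiometric
   consistency between tiles that mosaicking and channel balancing rely on.
2. **Flat-field correction.** Each frame is divided, pixelwise, by a
   calibration image of a uniform fluorescent sample for the same channel,
   so a frame identical to the calibration maps to all-ones. The
   calibration is floor-clamped before use (see *Numerical choices*).
3. **Optical-section reconstruction** (SIM mode only). Three frames with
   the grid at phases 0, 2π/3, 4π/3 are combined as
   `S = (√2/3)·√[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]`. For
   `Iₙ = I₀ + m·cos(φ + θₙ)` this returns exactly `m` at every absolute
   phase φ; the √2/3 gain is chosen for that unit-gain property — the
   demodulator's overall constant is otherwise arbitrary because it is
   absorbed by the balance coefficients downstream. The phase mean is kept
   as the widefield companion. Reconstruction runs per tile, before
   mosaicking, because the stain conditioning operates on assembled,
   intensity-corrected mosaics. No stripe-artifact suppression or
   apodization is applied.
4. **Mosaicking.** Stage positions are trusted (no registration
   refinement). Overlap seams are blended with separable linear feathering
   whose per-axis ramps are `a_i = (i + ½)/L` on one tile and `1 − a_i` on
   its neighbor, an exact partition of unity — uniform tiles therefore
   assemble into an exactly flat mosaic.
5. **Channel conditioning.** Each mosaic is compressed as
   `scale · I^γ`, clipped to [0, 1]. Clipping rather than renormalizing
   preserves the color of unsaturated pixels in the RGB step. Gammas are
   restricted to the instrument's operating range [0.65, 1] (defaults 0.85
   for DRAQ5, 0.75 for eosin).
6. **Channel balance.** When A/B are not supplied they are estimated:
   foreground = pixels above the channel's Otsu threshold (whole-image
   means would be biased by tissue-free background), each coefficient
   scales the foreground mean of the compressed channel to 0.5 (an
   arbitrary but fixed mid-scale target), subject to the scaled 99.9th
   percentile staying ≤ 1, and finally clamped to A ∈ [0.8, 3],
   B ∈ [1.5, 5] — the instrument's reported operating ranges. Explicit A/B
   always win over the estimator.
7. **RGB mapping.** Each plane is
   `1 − D5·(1 − c_D5) − E·(1 − c_E)` with default unit colors
   `c_D5 = (0.24, 0.21, 0.62)` and `c_E = (0.88, 0.27, 0.66)`; negative
   values (possible only for saturated double-stained pixels) are clipped
   to 0, which keeps single-stain colors exact. Export multiplies all
   planes jointly by 65535 (hue-preserving) into a 16-bit RGB TIFF; an
   8-bit PNG preview and a green/magenta fluorescence composite
   (DRAQ5 → magenta, eosin → green) are optional side outputs.

Widefield (non-SIM) acquisitions skip step 3; the single frame passes
through unchanged after normalization and flat-fielding.

## Optical-sectioning theory

The modulation of a projected grid of normalized frequency `ν = f·λ/NA`
decays with defocus as the first-order Bessel envelope

    attenuation(z) = |2·J₁(u·T)/(u·T)|,   T = ν(1 − ν/2),
    u = c_u · k · z · n · sin²(α/2),      k = 2π/λ,  sin α = NA/n,

normalized to 1 at focus. The half-width at half-maximum of this curve is
reported as the optical-section thickness. HWHM is found by bracketing on
the first lobe and Brent root-finding to 10⁻³ μm; purely tabulated curves
(no analytic evaluator) are solved on their linear interpolant instead.

Two ambiguities of a fluorescence implementation are resolved explicitly:

- **Wavelength placement.** The grid is formed at the excitation
  wavelength but imaged at the emission wavelength. A convention flag
  selects which enters ν: `"emission"` (default) uses the emission-band
  center in both ν and u; `"excitation"` uses the LED wavelength in ν and
  the emission center in u. With the emission convention the wavelength
  cancels to first order (`u·T ∝ f/NA`), making the two channels' section
  thicknesses nearly equal — the behavior of the reference dual-color
  instrument, whose channels section at 18.8/18.7 μm despite a 150 nm
  wavelength difference. Emission centers default to the arithmetic
  centers of the collection bands (575 nm for eosin from 530–620 nm,
  722.5 nm for DRAQ5 from 665–780 nm); the emission-filter centers
  (595/730 nm) can be set as an alternative preset via
  `ChannelOptics.lambda_em_center_nm`.
- **Defocus constant `c_u`.** The classic paraxial normalization
  (`c_u = 4`) predicts ~44 μm sections for this configuration, more than
  twice the reference instrument's published values, and the instrument's
  exact computation (effective illumination aperture, defocus-coordinate
  convention) is not recoverable from its description. `c_u` is therefore
  treated as an instrument constant, calibrated once per wavelength
  convention against the published channel pair (emission: 9.3665, giving
  18.72/18.78 μm; excitation: 11.0883, giving 19.31/18.16 μm) and held
  fixed. The emission convention is the default because it reproduces both
  values and their near-unity ratio most closely. Changing `c_u` rescales
  every HWHM by the same factor; all *relative* statements (monotonicity
  in grid frequency, channel ratios, the widefield ν → 0 divergence) are
  independent of it.

Lateral resolution is not modeled.

## Synthetic tissue phantom

The phantom emulates the contrast of a stained fresh-tissue surface, not
its histology: non-overlapping elliptical nuclei (major axis
9 ± 1.5 μm, aspect 0.6–0.95, jittered orientation, ≥ 1 px separation)
carry signal only in the DRAQ5 plane; a smoothed-Gaussian stromal texture
(8 μm correlation length, mid-level 0.45) fills the eosin plane, zeroed
inside nuclei (eosin-negative nuclei appear as dark holes, as in real
two-channel data) and inside a few gland lumina empty in both channels.

The acquisition forward model collapses depth to one in-focus plane plus
one out-of-focus layer — sufficient to exercise the sectioning contract
without volume rendering. Per tile, channel and phase:

    Iₙ = V · g · [ S_focus·(1 + m·cos(2πfx + φₙ))
                 + S_defocus·(1 + m·a(z)·cos(2πfx + φₙ)) ] + noise

with V a radial-quadratic vignetting profile (strength 0.15), g = 0.35 a
digital gain leaving 16-bit headroom, m = 0.6 the grid modulation depth,
and `a(z)` the theoretical attenuation at the layer's offset (default
40 μm, where a ≈ 0.12). `S_defocus` is a Gaussian-blurred (8 μm) copy of
the in-focus plane at relative intensity 0.25. Noise is shot noise at a
photon budget of 10 000 per full-scale pixel plus Gaussian read noise
σ = 0.001; frames are rounded to 16 bits, with an error if more than 1% of
pixels saturate. The matching flat-field calibration (V times a constant,
0.8 of full scale) is emitted with each acquisition. All randomness
derives from a single seed through split generator streams, so identical
spec + seed is bit-identical. Default acquisition geometry: 512×512 scene
at 0.635 μm/px (the instrument's pixel pitch), cut into 2×2 tiles with
16 px overlap — large enough to exercise feathered mosaicking and give
stable region statistics, small enough that the full end-to-end suite runs
in seconds.

**What phantom tests show — and don't.** Passing end-to-end tests
demonstrates that the pipeline inverts this forward model: vignetting is
removed exactly, the demodulator recovers in-focus amplitude, the
defocused layer is carried at its theoretical attenuation, and the
rendered colors match the analytic pseudo-color of the truth planes. Real
tissue adds effects the phantom deliberately omits: scattering and depth-
dependent stain penetration, stage-position error, grid-pattern
imperfections and residual stripes, chromatic focus offsets, detector
fixed-pattern noise, and genuine 3-D structure. Results on the phantom
bound the algorithmic error only.

## Numerical choices

- **Calibration floor clamp.** Raw calibrations are clamped from below at
  min(1st percentile of positive values, half the median) before division.
  The percentile guards dead pixels; the half-median cap keeps the guard
  from clipping the dim corners of a genuine illumination profile, which
  would otherwise bias flat-fielding by ~1% there.
- **Post-compression and post-flat-field clipping.** Compressed channels
  are clipped to [0, 1] (the RGB mapping assumes stain ≤ 1); flat-fielded
  mosaics are clipped likewise, and the run report records the clipped
  fraction so silent saturation is visible.
- **End-to-end verification at unit gamma.** The full-pipeline recovery
  test renders at γ = 1 with the balance coefficients that invert the
  known forward-model scale. With γ < 1, the compressive power law
  amplifies the demodulator's rectified noise floor on zero-stain regions
  (x^γ has unbounded slope at 0), which tests the noise model rather than
  the pipeline; the nonlinearity itself is verified exactly by closed-form
  unit tests. The out-of-focus suppression factor is estimated by
  least-squares regression of the sectioned mosaic on the known in-focus
  and defocus planes — on the eosin channel for the noisy acquisition
  (the DRAQ5 defocus regressor is nearly collinear with its sparse
  in-focus plane, making that channel's noisy estimate ill-conditioned)
  and on both channels in a noise-free variant.
- **Degenerate inputs.** All-zero channels are rejected by the balance
  estimator; constant images fall back from Otsu to all-positive pixels;
  SIM frame sets require exactly the three canonical phases; a mosaic must
  receive every layout cell exactly once; nucleus packing aborts with an
  error after a bounded number of rejection-sampling attempts.

## Known limitations

- The axial-response constant `c_u` is calibrated to one published
  instrument, not derived ab initio; absolute HWHM values for other
  instruments inherit that convention.
- The balance estimator is a reproducible stand-in for what is, on the
  real instrument, a partly manual adjustment; its Otsu-foreground /
  mid-scale-target rule is documented but not canonical.
- No registration refinement, exposure equalization between tiles,
  stripe-artifact removal, or absorptive (Beer–Lambert-style) color
  mapping; the linear white-minus-stain mapping can clip saturated
  double-stained pixels.
- Widefield and SIM paths share all conditioning code, but nothing
  corrects widefield images for out-of-focus haze — that is the physics
  the SIM mode exists for.
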