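# Methods

This note documents the models, parameters and design choices behind
`msiperf`.  Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Spectral system model

The instrument's measured band table — 16 effective wavelengths with peaks
404–957 nm and FWHM 12–84 nm — is shipped verbatim as
`spectral.canonical_bands()` and is authoritative throughout the package.
`effective_spectrum()` implements the generic derivation (emitter × colour
filter × transmission, peak at the product argmax, FWHM by linearly
interpolated half-maximum crossings, plateau centers for flat-topped
products) and is validated against a dense-grid half-crossing oracle on
Gaussian and boxcar fixtures.  The real LED and filter curves are not
public, so `gaussian_emitter()` provides parametric stand-ins; we do not
claim that any particular 14-LED/RGB-filter configuration regenerates the
canonical table *through* the engine — the broad, overlapping green/amber
bands (FWHM up to 84 nm between 532 and 600 nm) would make any such
construction contrived.

The relevance threshold that decides which emitter×channel overlaps count as
bands is not published; the package uses 5 % of the emitter's strongest
product (configurable).

Emitter and readout-channel assignments in the canonical table are this
package's own: two dual-band emitters (450 nm B + 503 nm G; 580 nm G +
590 nm R) account for 16 bands from 14 LEDs, and the 863 nm band is read
through the blue channel (NIR leakage of the dye filters) so that the
811/863 and 532/863 pairs can share an exposure slot.

## Tissue phantom

Two-layer modified Beer–Lambert forward model per band (peak λ, layer l):

    R(λ) = exp(−(ε_mix(λ) · C_tHb · L_l + G)),   ε_mix = SO₂·ε_HbO₂ + (1−SO₂)·ε_HHb

with band depth class: peak < 620 nm → superficial layer, ≥ 620 nm → deep
layer (the penetration-depth argument; the threshold is a repo decision).

Parameters (units, defaults, rationale):

| parameter       | unit  | default            | why |
|-----------------|-------|--------------------|-----|
| C_tHb baseline  | mM    | U(0.06, 0.10)/subject | physiological microvascular hemoglobin content |
| SO₂ deep / sup  | –     | U(0.55, 0.70) / U(0.78, 0.84) | resting muscle vs. well-perfused skin; keeps StO₂ mode ≈ 0.8 |
| path L_sup / L_deep | mm | 0.6 / 5.0         | green sampling depth ≪ NIR; the deep parameter senses ~5 mm |
| scatter loss G  | –     | 0.25               | wavelength-independent coupling/scatter offset; mid-range baseline reflectance |
| texture         | –     | ±20 % (thb), ±5 % (SO₂), low-frequency | smooth tissue heterogeneity so markers see distinct values |

The extinction table is a coarse, hard-coded rendition of the hemoglobin
spectra (units 1/(mM·mm)) carrying exactly the orderings the pipeline needs:
strong green absorption, HHb ≫ HbO₂ in the red, an isosbestic crossing at
800 nm, HbO₂ > HHb above ~810 nm.  It is synthetic: absolute radiometry,
scattering spectra, melanin and water are not modelled.

### Occlusion protocol and trajectories

Default protocol 2/2/5/2/5 min (baseline, venous occlusion, reperfusion,
arterial occlusion, reperfusion), 600 frames and one reference block per
minute, 16 min total.  Occlusion phases ramp linearly to their per-subject
target (venous: hemoglobin pooling up to +30…60 %, mild desaturation;
arterial: deep/superficial desaturation of 40–70 %/40–60 % at constant
hemoglobin); reperfusion relaxes exponentially (τ ≈ 0.6–1.0 min).  The
trajectory *shapes* are invented — only their qualitative course (lower
saturations during occlusions only; hemoglobin rise specific to the venous
phase) mirrors the study narrative, and expected excursion magnitudes are
configuration, not claims.

### Reference images

Reference parameter images (THI, NIR PI, StO₂ ∈ [0,1]) are affine in the
underlying state (THI in C_tHb, NIR PI in deep SO₂, StO₂ in superficial
SO₂), with slopes/intercepts chosen once so the default population stays
inside the value ranges a clinical HSI reference produces on this protocol
(THI 0.031–0.907, NIR PI 0.400–0.797, StO₂ 0.274–0.881, StO₂ mode ≈ 0.8);
the containment is asserted in the test-suite.  The reference device's
proprietary post-processing is not modelled (identity hook).

A second reference mode, `affine-rr`, defines the reference as an affine
function of the noise-free reflectance ratio.  It makes the downstream
linear calibration exact by construction and is used to validate the
pipeline itself (noise-free test RMSE at the quantisation floor); it is not
the default because real reference devices do not compute an affine
function of the MSI ratio.

### Sensor model

Channel DN = Σ active-band reflectance × on-time × gain + dark (1.3 DN,
the instrument class's measured background) + Gaussian noise, clipped and
rounded to 10 bits.  Auto-gain puts a white target's active-channel mean at
80 % of full scale (the sensor's level-control target, tuned for 45 mm);
other distances scale the gain by 45/d, so 35 mm runs brighter and 55 mm
darker, which is what makes distance-dependent metrics non-trivial.  Noise
σ is set so the frame-deviation SNR metric is expected at the configured
target (default 30 dB): for Gaussian noise that metric sits
E[−20·log₁₀|Z|] = 10(γ+ln 2)/ln 10 ≈ 5.52 dB above 20·log₁₀(mean/σ).
Noise has a per-pixel and a frame-global component; the global one carries
the scalar (frame-mean) SNR, the pixel one the spatially resolved SNR.
Measurements whose marker disks contain full-scale pixels are excluded as
sensor overrides and logged.

## Calibration pipeline

* Markers: 8 per measurement on a jittered grid, radius from a configured
  reference-object diameter (default 6 px at 64×64); means over pixels whose
  centers fall inside the disk, masked pixels excluded.
* Split: best-of-N seeded random 70/30 splits by minimal two-sample KS
  statistic between calibration and test reference values (N = 1000
  candidates by default; the original procedure states only that the KS
  distance was minimised — candidate search keeps it reproducible without
  combinatorial optimisation).  Split size = round(0.7·N) to the nearest
  integer.
* Fit: closed-form OLS (cross-checked against scikit-learn's
  LinearRegression in the tests).
* Evaluation: RMSE; R² = 1 − SS_res/SS_tot on held-out references (may be
  negative); RPD = population SD / RMSE.  The population-SD convention makes
  the worst-case identity exact: a constant predictor at the evaluated set's
  own mean yields R² = 0.00 and RPD = 1.00 to machine precision.  RMSE = 0
  is reported with RPD = ∞.
* Cross-validation: seeded shuffled fivefold; metrics averaged over folds.
* Group tests: per-measurement MAE over its (dependent) markers first —
  16 independent MAE values per participant under the default design — then
  two-sided Mann–Whitney U per distance pair and sex.  For groups of ≤ 8
  each the U null distribution is enumerated exactly over label assignments
  (valid under ties); larger groups use the tie-corrected normal
  approximation.  No multiple-testing correction is applied, matching the
  original analysis.

## SNR metric

SNR = (1/N) Σ 20·log₁₀(v̄/|vᵢ−v̄|) over per-frame mean pixel values (scalar)
or per pixel over the frame axis (map), log base 10 (decibel convention;
the source formula writes "log" unqualified).  Terms with |vᵢ−v̄| below
10⁻⁶ × full scale are undefined and excluded (counted); all-identical
frames raise a degenerate-signal error.  Whether the instrument's per-band
scalar uses per-frame spatial means or the pixel mean of the map is not
fully specified; the scalar here uses frame means and the map provides the
other reading.  The per-term spread of the metric is ≈ 9.6 dB, so the
scalar estimate has sd ≈ 9.6/√N dB; the dataset's static SNR acquisition
defaults to 200 frames (the bench characterisation uses 1000) so the
estimate resolves the configured target to well under 1 dB.

## Problem sizes

Default in-package runs use 64×64 px images (tests 24–48 px) and render the
last sequence pass (3 frames) per acquisition block — the only frames the
quantitative path consumes — while the manifest records the nominal
600 frames/min protocol arithmetic.  These sizes are the package's
desk-scale defaults; full-frame (960×540) rendering works through the same
config surface.

## What passing tests do and do not show

The phantom reproduces the study's *structure* (design counts, protocol
timing, value ranges, noise level, distance gain) and the *orderings* of
hemoglobin optics, so green/NIR ratio monotonicity, round-trip identities,
split balance and metric identities are meaningful checks of the analysis
machinery.  It does not reproduce tissue scattering, glare/specular
artifacts, motion, melanin variation or the reference device's
post-processing, so absolute error levels on synthetic data say nothing
about clinical accuracy.  One emergent parallel is worth noting: the
superficial-oxygenation ratio performs close to its worst-case baseline on
the phantom for the same structural reason advanced for real tissue (broad
green bands, little saturation contrast along the superficial path).

## Known limitations and quirks

* Channel/emitter assignments of the canonical bands are invented (only
  peaks/FWHM are instrument values).
* The KS split optimises over random candidates, not all splits.
* One printed p-value in the source material ("p = 2.05") is impossible and
  treated as a typo; the package reproduces the test procedure, not that
  number.
* White/dark references are applied per band image; whether the instrument
  stores them per band or per frame is unspecified.
* Trajectories are piecewise linear/exponential; no hyperemic overshoot,
  no pulsatile component.
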