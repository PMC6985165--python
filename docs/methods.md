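# Methods

This note documents the models implemented in `crypsis`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a user auditing results should know
about.

## Spectral processing

All spectra live on a canonical 300–800 nm grid at 1 nm steps (the range of
the reflectance measurements the pipeline is designed for; a uniform fine
grid keeps trapezoid integration stable). Ingestion clips negative
instrument readings to zero and logs the count; reflectance is stored as a
proportion of the white standard, with values above 1 permitted.

Smoothing is loess — locally weighted quadratic regression with tricube
weights — with a default span of 0.2 of the points, exposed in the config.
A local quadratic reproduces constants and linear ramps exactly and, on a
noisy ramp (σ = 0.02, 501 points), cuts residual variance against the true
curve by well over 5×. Smoothing precedes within-sample averaging by
default; the ordering is configurable because either order is defensible
and the choice is not dictated by the data model.

`resample` is linear interpolation and refuses to extrapolate: a grid
outside a spectrum's support is an error, never a silent fill.

## Receptors and visual systems

Receptor sensitivities are built from the Govardovskii A1 alpha-band
template, the field-standard absorbance template, peak-normalised to 1; a
Gaussian template (σ configurable) is available for closed-form validation.
Beta bands, ocular media and polarisation sensitivity are out of scope.

The fish receiver models a trichromatic reef predator (Picasso triggerfish):
cone peaks 420/480/520 nm, integration 340–700 nm, cone ratio 1:2:2 (S:M:L),
Weber fraction ν = 0.05. The stomatopod receiver carries the 12 chromatic
channels of *N. oerstedii*; the default peak wavelengths are placeholders
evenly spanning 315–700 nm, because the published sensitivity curves are
available only graphically — measured curves supplied as spectral tables
take precedence, and only the abundance-free Weber contrast is computed for
this receiver (its peripheral-vs-midband abundances are unknown; equal
abundances are assumed where a noise model is formally required).

Underwater light follows Beer–Lambert attenuation of a smooth daylight-like
surface spectrum. The default diffuse attenuation K(λ) has its minimum near
480 nm and rises toward the UV and strongly beyond 600 nm, reproducing the
spectral narrowing and blue-shift of coastal tropical water; it satisfies
K(700) > K(480) by construction. No radiative-transfer modelling is
attempted.

## Colourimetry

Quantum catch is the trapezoid integral of R·S·I over the receiver's range.
Weber contrast is (qˢ − qᵇ)/qᵇ per receptor, positive = lighter.

Von Kries adaptation divides each catch by the catch from the adapting
background under the same illuminant, so a uniform rescaling of the
irradiance cancels exactly. Normalised catches are projected into Maxwell's
triangle as x = (n_L − n_S)/√2, y = √(2/3)·(n_M − (n_L + n_S)/2). The
grouping in y is chosen so that equal catches map to the origin and the
three pure-receptor points lie at radius √(2/3); the alternative grouping
(dividing the whole bracket by 2) would place achromatic points off-centre,
contradicting the interpretation of radial distance as saturation.

The RNL distance uses log receptor signals Δfᵢ = ln(qᵢᵃ/qᵢᵇ) by default:
observed separations in this problem reach tens of JNDs, far outside the
small-contrast regime where the linear form is valid. The linear form is
available (`signal_form="linear"`) for validation; the two agree to 0.1% at
0.1% contrast. Receptor noise is eᵢ = ν·√(η_ref/ηᵢ) with η_ref the most
abundant class — ν is the Weber fraction *of the most abundant class*, the
standard convention; for ν = 0.05 and η = (1,2,2), e = (0.0707, 0.05, 0.05).
Under the log form the distance is a norm of noise-weighted Δf differences:
zero exactly for uniform intensity changes, symmetric, and satisfying the
triangle inequality (property-tested on 1000 random triples). The
implementation is the explicit trichromat formula; tests verify it against
an independent matrix-form evaluation (the GLS projection orthogonal to the
achromatic direction) to 1e-10, including the worked value ΔS ≈ 10.74 for
Δf = (0,0,ln 2).

Decision thresholds are carried as constants: 1 JND (indistinguishable)
and 3 JND (possibly indistinguishable).

## Discriminability statistics

The JND distance matrix between all animal and background samples feeds a
two-step procedure:

1. **Statistical separation.** A two-group PERMANOVA with Anderson's
   distance-based pseudo-F. p = (1 + #{F* ≥ F}) / (1 + n_perm) under
   Monte-Carlo label permutation (default 999 permutations); when the number
   of distinct assignments is ≤ 10,000 the exact enumeration is used
   instead. The homogeneity assumption is checked by a multivariate
   Levene-type test: principal-coordinate embedding of the distance matrix
   (negative eigenvalues handled by Anderson's correction, squared distances
   clipped at zero), per-sample distance to the own-group spatial centroid,
   ANOVA F with a permutation p. The result flags the known type-I-error
   hazard — the smaller group being more dispersed than the larger.
   Degenerate matrices (all points identical) return F = 0, p = 1 by
   definition.

2. **Perceptual separation.** Group centroids are per-receptor geometric
   means of quantum catches — the geometric mean is the natural centroid
   under the log-ratio structure of the RNL model — and the statistic is
   the RNL distance between centroids. Groups are resampled with
   replacement (default 1000 times) and the 95% CI is the 2.5/97.5
   percentile of the bootstrap distribution. The reported mean is the
   plug-in statistic on the full groups; the percentile interval is widened
   (rarely, and only marginally) to contain it, so the invariant
   ci_low ≤ mean ≤ ci_high always holds.

The verdict: *camouflaged* if the PERMANOVA is not significant (α = 0.05),
or if the CI crosses 1 JND and the mean is below 3 JND; *discriminable* if
significant with the CI entirely above 1 JND; the remaining cell
(significant, CI crossing 1, mean ≥ 3) is reported as *ambiguous* rather
than silently binned — the published rule is silent there.

Calibration is tested by simulation: the null rejection rate at α = 0.05
over 1000 two-group simulations (999 permutations each) must fall in
[0.035, 0.065], and the bootstrap CI must cover a known template separation
in 92–98% of 500 replicates (n = 20/group).

## Pattern analysis

Regions of interest are analysed on the image's green channel (fish double
cones, the presumed luminance/pattern channel, peak near 500 nm), gamma
decoded from sRGB to linear by default (a flag skips decoding for images
stored linearly). The masked region is mean-subtracted (masked-out pixels
filled with the mean, i.e. zero), zero-padded to a power-of-two frame and
Fourier transformed; energy is binned into octave annuli of spatial period
[s/√2, s√2) for s = 2, 4, …, min(H,W)/2, normalised by the masked pixel
count so the energies sum to the pixel variance (Parseval, verified to 5% on
noise textures; exact for full-frame inputs). Pattern contrast is the total
energy, pattern size the peak-energy scale (ties broken toward the larger
scale and logged; a region with no spatial variation is flagged degenerate),
total reflectance the mean masked intensity. A minimum of 64×64 masked
pixels is enforced.

Effect sizes replace the original linear-mixed-model machinery with an
equivalent and more transparent paired design: variables are
log(x + 1e-6)-transformed and, within each photo, the animal value is paired
with the mean background-type value. Pairing within photos removes any
per-photo additive effect on the log scale — exactly what a photo random
intercept absorbs — while leaving the quantity of interest, the
standardised mean difference, unchanged. Cohen's d for repeated measures is
d_av: mean paired difference over the average of the two conditions'
across-photo SDs (d_z, normalising by the SD of differences, is available
via config). |d| magnitudes are reported; |d| < 0.8 is a match. At least
3 paired photos are required; a comparison with zero spread and a non-zero
mean difference has no defined standardised effect and is reported as
NaN/no-match by the pipeline.

## Synthetic data

The generator emulates the *structure* of the study system, not any real
measurement:

- **Reflectance classes** are baseline + Gaussian peaks + a sigmoid
  long-wavelength plateau, with per-sample lognormal jitter on amplitudes
  (between-individual variation that preserves non-negativity) and mild
  per-point multiplicative noise. Templates encode the documented
  qualitative shapes: purple, UV/short-reflecting meral-spot colours that
  are lighter than seagrass but darker than rubble; a pale UV-reflective
  ring; dark green-peaked seagrass with a red edge; bright substrates
  rising toward long wavelengths. Sandy body colouration shares the
  substrate spectral family and differs mainly in overall intensity — a
  chromatic match under the log-form RNL model — while the green body
  colour differs from seagrass by a supra-threshold saturation offset
  (template separation ≈ 2.6 JND), so scene presets carry honest
  match/mismatch ground truth (the noiseless-template centroid JND is
  written into every scene's ground-truth record).
- **Scene sample sizes** follow the study design: 30 and 24 meral-spot
  samples for the two collection habitats, 13 rings, 8–10 animals per body
  colour class, 10 background samples per type; depths 0.5–10 m with 1 m as
  the reference analysis depth.
- **Textures** are band-limited noise (log-Gaussian frequency band around
  1/period) with specified RMS contrast and mean, signal in the green
  channel. Photos apply a shared lognormal luminance multiplier (sd 0.10)
  to all regions — the between-photo effect the paired analysis removes —
  plus per-region lognormal jitter on period/contrast (sd 0.35) and
  luminance (sd 0.15), since real substrate patches vary in grain and
  brightness between photos. Without that variability the discrete peak
  scale would have zero spread and standardised effects would be undefined.

What passing tests on this generator do **not** show: performance on real
spectrophotometer noise (correlated, wavelength-dependent), on real
photographs (uncontrolled lighting geometry, camera processing,
segmentation error), or the correctness of the placeholder stomatopod peak
wavelengths. The generator contains no radiative-transfer water model and
no hyperspectral image synthesis.

## Problem sizes and determinism

Defaults: 999 permutations, 1000 bootstrap resamples, α = 0.05, d threshold
0.8. The simulation studies use 1000 null PERMANOVA runs, 500
bootstrap-coverage replicates and 100 end-to-end scene replicates per
preset; the acceptance script uses 500/300/50 per preset respectively —
sizes at which the Monte-Carlo error is a small fraction of the tested
tolerances. All generators take explicit seeds (numpy `Generator`
throughout); identical config + seed gives byte-identical tabular output.

## Known limitations

- The 12 stomatopod peak wavelengths are placeholders (see above); Weber
  contrast patterns are qualitative until measured curves are supplied.
- The dispersion test permutes distances-to-centroid rather than refitting
  centroids per permutation; for two groups of moderate size this is the
  standard Levene-permutation approximation.
- Percentile bootstrap CIs (not BCa); adequate at the tested coverage band.
- No achromatic RNL channel: luminance comparisons are handled by the
  pattern module, not by a luminance JND.
- Two-group comparisons only; no nested or stratified permutation schemes.
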