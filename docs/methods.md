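# Methods

## The analysis model

The package treats one tangential section as a non-negative intensity field
on a µm-calibrated pixel grid (`PlanarImage`), with a boolean analysis mask
for valid tissue. Module structure is defined operationally, not
biophysically: after local normalization and smoothing, the masked pixels
are ranked and cut into six equal-count intensity classes, and "M2+ patch"
/ "M2− interpatch" mean nothing more than membership in the top-2 / bottom-2
sextiles. All downstream statistics are conditional on that partition.

### Delineation

* **Local normalization** divides each pixel by the mean intensity over a
  surrounding disc of radius 100 µm (default), computed as a mask-aware
  normalized convolution: the mean runs over disc ∩ mask, so tissue edges
  are not diluted by padding. This is a high-pass operation; the output is
  invariant to any global rescaling of the input.
* **Circular blur** replaces each pixel by the disc mean at 30 µm radius
  (same masked convolution).
* **Sextile partition** places quantile boundaries at ranks `i·N/6` of the
  sorted masked intensities. Ties at a boundary all fall to the lower
  quantile — a deterministic rule that keeps the partition reproducible
  across platforms; tied pixels are the only departure from exact
  equal-count classes. A partition is refused when fewer than six distinct
  values exist or when the total intensity spread is below 1e-9 relative
  (an effectively constant image has no modules).

Disc membership is by pixel centre within the radius, inclusive. Both
filters are implemented by FFT convolution of the masked image and the mask
with a binary disc kernel; the suite verifies them against explicit
per-pixel disc enumeration to 1e-9 relative error.

### Registration

Sections are related to the L1 reference frame by planar homographies
(8 degrees of freedom) fitted to ≥ 4 blood-vessel landmark pairs with the
normalized direct linear transform (least squares beyond 4 pairs; exact at
4 in general position). Transforms act on physical µm coordinates so
sections may differ in pixel size. Intensity images are resampled by
inverse mapping with bilinear interpolation; label images and masks travel
nearest-neighbour so classes never blend. The fit reports its residual RMS
in µm; no acceptance threshold is imposed — it is the caller's decision.
Layer labels come from a configurable section-index table (default: L1 =
sections 1–2, L2-4 = 3–7, L5 = 8–12, L6 = 13–16, "unknown" beyond).

### Quantification

* **ROI optical density**: mean signal intensity per sextile within
  rectangular ROIs (default 550 × 400 µm, three per section per sample
  class); a sextile absent from an ROI is reported missing, not zero.
* **Radial profiles**: annuli of 50 µm width starting at the core
  exclusion radius (250 µm for axon signal, 300 µm for point patterns —
  the saturated injection core is uninterpretable). Per annulus and class,
  density = signal sum (or point count) ÷ class area in the annulus. Both
  class curves share one normalization constant — their joint maximum — so
  the peak of the pair is 1 and the curves stay mutually comparable.
  Statistics are computed on raw bins; any smoothing (3-bin moving
  average) is display-only.
* **Interpatch preference estimate** `rho_hat`: mean over annuli of the
  interpatch/patch density ratio, using annuli where both classes are
  present. Distance-matched annuli cancel the radial decay, so with a
  multiplicative module effect the per-bin ratio estimates ρ directly.
* **Anisotropy**: intensity-weighted second central moments of pixels at or
  above an intensity quantile (default: top decile), optionally excluding
  the injection core; aspect ratio = √(λ_major/λ_minor). The top-decile
  default matters: at looser thresholds the moment pool is dominated by
  far-field background whose spread is isotropic and set by the frame, and
  the ratio is biased toward 1 (measured on planted a = 1.4: threshold 0.5
  gives 1.16, threshold 0.9 gives 1.39). The estimator is rotation- and
  intensity-scale-invariant.
* **KS comparison**: two-sample Kolmogorov–Smirnov on per-ROI mean optical
  densities, patch sample vs interpatch sample, pooled over ROIs and
  subjects. Exact p-value when both samples have ≤ 25 observations,
  asymptotic otherwise.

## Statistical design of the comparison

Two design choices keep the KS test's independence assumptions honest:

1. **Disjoint ROI sets per class.** Patch and interpatch values come from
   different ROIs. Taking both class means from the same ROI would pair
   the samples through shared acquisition noise, shared normalization
   discs, and the shared local decay level, and a paired KS test is
   miscalibrated.
2. **Randomized class-to-ROI assignment.** The 2×3 ROIs sit on a ring
   around the injection centre. Because the decay field is anisotropic,
   ROI position carries a small deterministic bias; ring positions at 60°
   spacing coincide modulo the ellipse's 180° symmetry, so any fixed
   alternating assignment hands both samples an identical bias multiset
   and couples them (measured: null rejection 0.010 instead of the
   theoretical 0.031). The assignment is therefore randomized per subject
   (seeded, reproducible), which restores exchangeability.

The axon signal is passed through the same local-mean normalization used
for delineation before densities are measured. This removes the
injection's radial decay, so ROIs at different distances estimate the same
quantity and the pooled samples are comparable; without it, distance
differences between ROIs dominate both samples jointly.

**Discreteness of the exact KS test.** With n = m = 12 sampling units
(4 subjects × 3 ROIs per class), the statistic D takes values k/12 and the
rejection region at α = 0.05 is D ≥ 7/12, whose exact null probability is
0.0314. That number — not 5% — is the true size of the test at this
design; no implementation can reject 5% of true nulls here, and the
asymptotic p-value yields the same rejection region. The validation study
therefore checks the simulated null rejection rate against the exactly
computable size 0.0314 (2000 simulated studies; measured 0.0295, within
binomial error), plus validity (rate ≤ α). Power at a planted ρ = 4 is
100/100 studies at the reduced scene scale.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the tissue preparation:

| parameter | default | meaning |
|---|---|---|
| field size | 2560 × 2560 µm | analysed cortical territory |
| pixel size | 5 µm | acquisition scale at ~10× |
| module spacing | 120 µm | dominant period of the patch mosaic; gives 4–8 modules per ~260 × 360 µm point image |
| ρ (interpatch preference) | 4.0 | interpatch/patch axon density at matched distance |
| anisotropy a | 1.4 | long-axis (elevation) / short-axis (azimuth) decay-length ratio |
| decay length | 500 µm | e-folding of axon density with elliptical distance |
| noise σ | 0.2 | log-normal multiplicative speckle (unit mean) |
| core radius | 150 µm | saturated injection core (value clamps at 2·max(ρ,1)) |
| cells / dendrites | 4000 / 1000 expected | point-pattern sizes, interpatch preference 1.6 / 3.0 |

The module field is white Gaussian noise band-pass filtered with a
difference of Gaussians (σ₂ = 2σ₁; peak wavelength π√(6/ln 4)·σ₁), z-scored
and sextiled — quasi-periodic and non-crystalline like the real mosaic,
with no placement heuristics. The observed M2 channel is a positive affine
rendering of the latent field. Point sets are exact inhomogeneous Poisson
samples obtained by thinning uniform candidates against the field maximum.
Serial sections are produced by perturbing the four field corners by
Gaussian offsets (scale `distortion_scale_um`) and fitting the induced
homography; landmark tables are exact correspondences under it. RNG
streams are split per sub-generator, so e.g. changing the landmark count
does not perturb the axon field; every generator is a pure function of
(parameters, seed).

What the generator does **not** emulate: laminar 3-D morphology,
individual axon trajectories (densities only), vignetting or stitching
artifacts, staining gradients beyond what local normalization removes,
landmark localization error from vessel-diameter ambiguity, or real
injection-core geometry (a circle stands in for the core contour).
Passing validation on these scenes shows the estimators are correct under
the planted model, not that real tissue satisfies the model.

## Validation studies and sizes

Run by the test suite and `scripts/acceptance.py`:

* filter/grouping oracle equivalence on 48² masked random images
  (brute-force disc enumeration, 1e-9 relative);
* sextile conservation on a 512² continuous field;
* homography recovery: noiseless < 1e-6 µm over 200 probe points; mean
  residual RMS over 100 replicates with 2 µm landmark jitter ≈ 2.3 µm
  (theory: σ√(1 − 8/24) ≈ 1.63 µm per replicate before the χ spread);
* segmentation Dice vs planted patches ≥ 0.8 (measured ≈ 0.83, noiseless
  default scene) — the residual mismatch is the normalization+blur
  pipeline re-ranking boundary pixels relative to the latent field's
  sextiles;
* planted ρ ∈ {1, 2, 4} recovered through full delineation within 15%
  (measured 1.00 / 1.84 / 3.50 over 10 seeds; attenuation comes from
  module-boundary misclassification, which mixes classes);
* KS calibration and power as above, at a reduced scene (1280 × 1280 µm at
  10 µm/pixel, 275 × 200 µm ROIs on a 400 µm ring) chosen so thousands of
  full studies run at desk cost;
* anisotropy a ∈ {1.0, 1.3, 1.4} recovered within ±0.1, rotation-invariant
  within ±0.02.

## Known limitations

* Module classes are relative (rank-based), so a field with genuinely no
  modular structure still yields a partition; the degenerate-input guard
  catches only constant images. Interpretation requires the downstream
  statistics.
* `rho_hat` is attenuated by segmentation error (≈ 8–13% at default
  conditions); it is a lower bound on a planted multiplicative preference.
* The exact KS test at 12+12 sampling units cannot have size 5% (see
  above); reported p-values are valid but conservative at fixed α.
* Landmarks must be supplied; there is no automatic vessel detection or
  matching, and no elastic (non-projective) warping.
* Apical-dendrite identification is morphological and manual upstream;
  dendrite points enter as pre-classified tables.
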