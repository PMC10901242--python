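# Methods

This note records how `nirsmap` implements each analysis stage, what the
synthetic data generator does and does not demonstrate, and the
numerical conventions the tests rely on.

## Preprocessing

Raw spectrometer counts are converted to relative reflectance
`Rrel(λ)` in five steps (`nirsmap.preprocess`):

1. divide by the measurement of a 99% diffuse reflectance standard and
   multiply by a phantom-derived scale factor (`calibrate`);
2. truncate to 600–1000 nm;
3. resample linearly onto the uniform 1 nm grid (401 samples);
4. zero-phase lowpass filter along wavelength: 4th-order Butterworth,
   cutoff 0.05 π rad/sample, applied forward-backward (`filtfilt`), so
   the magnitude response is squared and the phase is exactly zero;
5. normalize so `Rrel(600) = 1`.

Derivatives use second-order central differences (`np.gradient`),
one-sided at the band edges.

Because a Butterworth filter is not a projection, conditioning is not
exactly idempotent: re-filtering re-attenuates any energy near the
cutoff. The idempotency tests therefore use inputs band-limited far
below the cutoff, where the shape is preserved to machine-level
tolerances up to one global renormalization constant.

## Optical indices and contact filtering

`nirsmap.indices` evaluates six scalar indices per conditioned spectrum
(`R' = dRrel/dλ`, sums over the 1 nm grid, endpoints inclusive):

| Index | Definition | Role |
|---|---|---|
| COI  | `Rrel(764)/Rrel(730)` | contact quality; < 0.93 → rejected |
| LOI0 | `Σ_{660..690} \|R'(λ) − R'(952)\|` | lesion contrast |
| LOI8 | `R'(601) − R'(609)` | lesion contrast |
| SOI1 | `Σ_{600..1000} \|R'(λ) − R'(661)\|` | substrate contrast |
| SOI3 | `Rrel(650)/Rrel(930)` | substrate contrast |
| SOI4 | `Rrel(630)/Rrel(600)` | ratio-search winner |

`search_ratio_indices` scores every ordered pair of integer wavelengths
(401 × 400 candidates) as a single-feature classifier by tie-corrected
Mann–Whitney AUC, vectorized with chunked rank computations.

## Classification

One feature vector per contact-filtered spectrum (default features:
LOI0, SOI1, LOI8, SOI3, SOI4). Hearts — never individual spectra — are
split into train and test groups; within the training hearts, 5-fold
cross-validation grouped by heart fits five models, and the deployed
predictor averages their probabilities. Five model families are
supported: logistic regression, kNN, gradient boosting
(`HistGradientBoostingClassifier`), RBF SVM, and random forest
(default). Class imbalance is countered with inverse-frequency class
weights normalized to mean 1; kNN, which has no weight parameter, gets
the equivalent Bayes posterior reweighting of its vote fraction. The
random forest uses `min_samples_leaf=20`: with per-heart random
effects, unregularized trees memorize heart signatures and fail to
generalize across hearts.

## Mapping

`nirsmap.mapping` turns per-point probabilities into maps:

1. homography (physical mm → reference-image pixels) by normalized DLT
   on ≥ 4 control points;
2. scattered linear interpolation (Delaunay-based) onto a uniform grid
   (default 0.5 mm); paired maps share a grid extent derived from the
   pooled point cloud;
3. concave boundary: alpha shape implemented as a circumradius cutoff
   on the Delaunay triangulation (alpha in mm; `None` picks the
   smallest alpha producing one connected region containing every
   point);
4. zero-phase separable 2-D Butterworth lowpass (order 4, cutoff
   0.1 π) as a *normalized masked convolution* — values (zero-filled
   outside the mask) and the mask are filtered identically and divided,
   so undefined cells carry no weight and do not bleed inward.

## Map comparison

Metrics on a shared mask (`nirsmap.compare`): windowed SSIM (Gaussian
11 × 11, σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1, averaged over
windows fully inside the mask), Frobenius normalized inner product,
RMS difference, and Dice between thresholded predictions (undefined
when both predictions are empty). Cohort Dice means divide the sum of
*defined* per-heart values by the number of hearts, so an undefined
heart contributes zero to the numerator but stays in the divisor; a
defined-only mean is reported alongside.

## Synthetic data generator

The forward model (`nirsmap.synthetic`) is semi-empirical:

    reflectance(λ) = A · (λ/600)^(−b) · exp(−Σᵢ aᵢ · Gauss(λ; cᵢ, wᵢ))

with Gaussian absorption bands near 560, 630, 760 (hemo/myoglobin-like)
and 970 nm (water-like). Ablation raises scattering (A × 1.30,
b − 0.10) and shifts band strengths (+0.09 at 630 nm, −0.03 at
760 nm). Poor contact adds an absorber at 764 nm that drives COI below
0.93; in blood, poor-contact paths additionally see blood absorbers at
577/760 nm. Counts are reflectance × lamp shape × 0.99 / phantom
factor with 1% multiplicative detector noise. Contact angle scales
intensity by cos(angle) and — by default — leaves morphology untouched;
`angle_effect` lets tests break that assumption.

Variance components: per-acquisition detector noise; per-point tissue
jitter (shared between the paired PBS/blood passes, because it belongs
to the tissue location); per-heart random offsets. Contact failures
are 70% site-driven (shared between media) and 30% per-acquisition.

Sessions lay out 9 lesion ellipses (≈5.0 × 3.8 mm semi-axes) along an
arc adjacent to a circular vein on a 60 × 80 mm field, sample ~800
points per heart outside the vein, acquire each point in both media,
and relate physical coordinates to a 460 × 380 reference image through
a fixed ground-truth homography with exact control points.

### What the synthetic study shows — and what it does not

It demonstrates, end to end, that the pipeline recovers what the
generator encodes: contact rejection near the simulated failure rate,
cross-heart classifier generalization (test AUC ≥ 0.9 under the
default configuration; chance when lesion effects are zeroed),
paired-medium map equivalence (SSIM ≥ 0.7, inner product ≥ 0.8), and
lesion geometry recovery (prediction-vs-truth Dice ≥ 0.6 at p = 0.5).
It does **not** validate the biology: the absorption model is a
caricature, effect sizes were calibrated so single-index AUCs land in
the 0.7–0.9 range rather than measured from tissue, and real published
headline metrics cannot be reproduced without the original dataset.

## Numerical conventions

- Wavelength grid: `np.arange(600, 1001)`, indices `λ − 600`.
- AUC: tie-corrected rank statistic; equal to exhaustive pair counting.
- Contact angle: catheter axis = Rz(yaw) Ry(pitch) Rz(roll) applied to
  e_z; roll is about the catheter's own axis, so the angle equals pitch
  for a flat sample and is clipped to [0°, 90°].
- Heart split: deterministic — sorted heart ids, last `n_test_hearts`
  become the test group.
- All randomness flows from one `numpy.random.Generator` seeded by the
  pipeline seed; identical configurations reproduce identical results.

## Limitations

- The generator's band set and noise model are minimal; no instrument
  drift, stray light, or wavelength miscalibration is simulated.
- Lesion truth is binary inside sharp ellipses (an optional linear
  boundary ramp exists but defaults to off), so Dice values against
  truth are optimistic relative to histology-defined boundaries.
- Registration uses noiseless synthetic control points by default;
  `cp_noise_sd` enables noisy-registration experiments but no
  acceptance-level claim is made about them.
- SSIM is computed only over windows fully inside the mask, which
  discards a boundary band of width 5 cells; very small maps may have
  few valid windows.
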