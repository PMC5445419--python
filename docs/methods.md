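# Methods

This note records the models, parameter choices and numerical
conventions behind `fishpol`, and what the synthetic-data tests do and
do not establish about real images.

## Image model and conventions

Images are single-channel 2D grids of nonnegative intensities
(maximum-intensity projections). Coordinates are 0-based (row, col);
pixel (r, c) covers the unit square centred on the continuous point
(r, c), and all subpixel positions, polygons and cut lines live in
that continuous frame (shapely stores (x, y) = (col, row)). Point
sources are isotropic 2D Gaussians evaluated at pixel centres — not
integrated over pixel area — and every stage (scene generator, PSF
fitting, unit placement, average image) shares this one convention
through a single renderer, truncated at 6σ (omitted tail < 1e−8 of the
integral).

## Synthetic scenes

The generator emulates a FISH experiment on one elliptical cell per
frame:

* **mRNA channel** — constant background plus `n_spots` unit Gaussians
  (amplitude `unit_amplitude`, width `unit_sigma`), positions uniform
  inside the cell mask. Posterior enrichment is two-step: each spot
  picks the posterior half with probability f (Bernoulli), then lands
  uniformly in that half, giving exact per-spot labels and a
  Binomial(n, f) posterior count.
* **protein channel** — piecewise-uniform over the cell with posterior
  intensity share `protein_posterior_fraction`.
* **noise** — optional Poisson on (background + signal), then additive
  Gaussian read noise. Both default on; oracle tests switch both off.
* **geometry** — the nucleus is a point anchor offset along the
  polarity axis; the aggregation centre sits on that axis beyond the
  cell (anterior side).

Defaults (free parameters of the study conditions, chosen once as
plausible for confocal smFISH-style data): 128×128 px frame, cell
semi-axes 36×20 px, 40 spots, amplitude 120, σ = 1.5 px, background
10, read noise SD 2, Poisson on. Spots are rejected and resampled
within 3σ of the image border (configurable off) so photometric
identities are exact; an optional minimum pairwise spot distance
produces the well-separated "sparse regime" used by oracle tests.

What the generator does *not* emulate: irregular cell shapes,
cell–cell contacts, out-of-focus haze, PSF anisotropy or spatial
variation, autofluorescence texture, camera gain structure. Tests
passing on these scenes therefore validate the estimators'
correctness under the stated model, not robustness to every real-image
artefact.

## Unit calibration

1. **Background**: scalar estimate (median outside the cell mask, else
   global median) subtracted and clipped at zero.
2. **Detection**: 8-neighbourhood local maxima above `k_sigma` (default
   5) times a robust noise scale, minimum separation 3 px. The scale is
   the Gaussian-consistent MAD; on clipped background-subtracted
   images (> 25 % of pixels exactly zero) it switches to the one-sided
   quantile deviation (P84.13 − median), which equals one σ for
   half-clipped Gaussian noise — the plain MAD deflates badly there.
3. **PSF fit**: least squares of B + A·exp(−r²/2σ²) on an 11-px window
   (trust-region, bounded, ≤ 300 function evaluations). Windows with
   zero dynamic range, non-convergent fits, or fits with A ≤ 0 or σ
   outside (0, window) are marked not accepted.
4. **Unit derivation**: accepted fits are filtered to σ ∈ [0.8, 3.0]
   px, then both parameter distributions are thresholded from above:
   each iteration removes the top 2 % quantile of whichever
   distribution (amplitude and/or width) still fails the unimodality
   criterion. Trimming both distributions, not just the amplitude, is
   required in practice: overlapping spots produce a heavy upper tail
   in fitted σ that amplitude trimming alone never removes, and the
   loop would exhaust its support. The unit is the mean of the
   surviving amplitudes and widths; at least 10 survivors are required.

Unimodality criteria: Sarle's bimodality coefficient
(g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) below 0.555 (the uniform
distribution's value; default), or a single interior mode of a
Gaussian KDE with Silverman bandwidth (`criterion="kde_modes"`). A
sample whose full range is within 5 % of its mean is treated as
unimodal outright: such a distribution is already "fine" for
calibration, and moment-based criteria are numerically meaningless on
near-degenerate samples (a handful of slightly edge-truncated fits
dominates the skewness).

Calibration pools candidates across all images of an experiment.

## Count estimation

* **Linear**: Σ(background-subtracted pixels in ROI) / I_u with
  I_u = 2π·A_u·σ_u². Pixel membership is by pixel centre. For an
  anterior/posterior pair the two masks partition the cell pixels by
  the signed side of the bisecting line (ties → anterior), so the two
  counts sum exactly to the whole-cell count.
* **Reconstruction**: greedy-stochastic. Each step places one unit PSF
  at the residual's masked argmax, perturbed per axis by a seeded
  uniform jitter in [−1, +1] px (jitter 0 makes the rebuild
  deterministic); the placement is kept only if the SSD over the mask
  decreases by more than `stop_tol` (default 1e−4) × the initial SSD,
  and the first rejection ends the loop. The residual may go negative
  — over-placement penalizes itself through the SSD. Unit amplitude is
  fixed at A_u (no per-spot refitting). The rebuild is repeated
  (default 10 reps, counter-derived seeds) for a mean ± SD per-ROI
  count and an average placement image.

Degenerate inputs: a zero image yields an empty trace (not an error);
a unit wider than the mask's smallest extent is an error; placements
of a pair-ROI estimate are assigned to halves by the same line-side
rule as pixels.

## Geometry

* Semi-axes come from the polygon's exact (shoelace) second-order area
  moments: for a uniform ellipse the coordinate-covariance eigenvalues
  are (a²/4, b²/4), so a and b are twice the square roots of the
  eigenvalues. Chord-based axis measures were the alternative; moments
  are insensitive to vertex spacing and need no landmark choice.
* Eccentricity ε = √(1 − b²/a²), errors outside a ≥ b ≥ 0, a > 0.
* Bisection cuts through the nucleus centroid perpendicular to the
  nucleus→aggregation direction. Non-convex outlines whose cut makes
  more than two pieces are assigned piecewise by centroid side, with a
  warning. Externally supplied anterior/posterior polygons (the manual
  path) take precedence over the programmatic cut.
* A pixel belongs to exactly one half; centres exactly on the line go
  to the anterior. **Known limitation**: when the cut is exactly
  aligned with the pixel grid *and* passes through a column (or row)
  of pixel centres, that whole line of pixels — the widest strip of
  the cell — lands in the anterior, biasing its count by roughly half
  a pixel-width of cell intensity (≈ +1.4 units under the default
  scene). Any oblique cut, the generic case for real cells, removes
  the effect; the cohort-level tests therefore use an oblique polarity
  axis (0.3 rad).

## Statistics

* Box summaries are distribution-free order-statistic confidence
  intervals for the median at 50 % and 99 % (binomial method; the
  largest l with F_Bin(n,½)(l−1) ≤ (1−level)/2 gives [x₍l₎, x₍n+1−l₎]),
  with points beyond the 99 % interval flagged as outliers and
  conventional quartiles emitted alongside for comparison.
* Anterior vs posterior: Welch's unpaired t-test is the default
  presentation; the paired per-cell test is available
  (`paired=True`) and is the *calibrated* variant for this design.
  The two halves of a cell share its total, so their counts are
  strongly anti-correlated (r ≈ −0.95 under the generator), the
  unpaired statistic understates the variance of the difference by
  about √2, and its type-I error runs near 0.18 at nominal 0.05; the
  paired test is nominal. The pipeline-level calibration tests use
  the paired variant for this reason.
* No multiple-testing correction is applied across stream positions by
  default (Bonferroni by flag).
* Pearson correlation of mRNA vs protein posterior fractions is
  computed both per cell and across stream-position group means (the
  group-mean variant has only as many points as positions, typically
  3, and is reported with its n).

## Determinism and problem sizes

All randomness flows from one master seed through
`numpy.random.SeedSequence`; per-cell and per-repetition seeds are
counter-derived (each < 2³¹), so cohorts are reproducible regardless
of evaluation order. The test suite runs its statistical calibration
studies at deliberately modest sizes — 64×64 px cells, 40 spots,
30-cell cohorts, 100 replicate cohorts for power and 500 for type-I
error — chosen so the full suite completes in a couple of minutes
while keeping the binomial uncertainty of the measured rates well
inside the asserted bands.

## Known limitations

* The unit is a fluorescence denomination, not a molecule count; no
  attempt is made to decompose units into single transcripts.
* The pixel-centre PSF convention slightly misstates the photometry of
  very narrow PSFs (σ ≲ 0.7 px) compared to pixel-integrated models;
  all internal stages are self-consistent, but units calibrated
  elsewhere with an integrated-PSF model are not interchangeable.
* The reconstruction's fixed-amplitude placements make no attempt at
  joint amplitude/position optimization; heavy overlap beyond ~2σ
  spacing increases its variance (the repeated-rebuild averaging is
  the mitigation).
* Grid-aligned cuts through pixel-centre lines bias the half counts
  (see Geometry above).
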