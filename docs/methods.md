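# Methods

## The problem and the approach

Figure–ground segmentation in visual cortex shows up as two associated
signatures: *foreground enhancement* (the behaviorally segmented
foreground explains a region's representational geometry better than
chance) and *background suppression* (filtering the background out of
the stimuli *raises* the correlation between a stimulus model and the
region's geometry, because to that region the background was never more
than noise).

Explicit computational models of scene segmentation do not exist, so the
package implements a *pre-filtering* strategy: a single fixed stimulus
model is held constant while the stimuli themselves are parametrically
manipulated, and the manipulation step that correlates best with a
region's representational dissimilarity matrix (RDM) is read as that
region's preferred content.  All statistics operate on RDMs
(representational similarity analysis): the model RDM entries are
`1 − Pearson r` between descriptor vectors, brain/observer RDMs are
`1 − Pearson r` between response patterns, and model–brain agreement is
Spearman's ρ over the condensed upper triangle (n stimuli give
n(n−1)/2 dissimilarities).

## Stimuli, masks, regions

A stimulus is a grayscale image inside the circle inscribed in its
frame, surrounded by uniform gray (default 0.5), with a pixels-per-degree
scale (the reference experiment showed a 20°, 500-px aperture, i.e.
25 px/deg; synthetic stimuli keep the 20° convention at their own pixel
size).  The behavioral foreground mask is the largest 8-connected patch
labeled foreground across all available manual segmentations, ties
broken by enumeration order (first map, then first component — the
selection must be deterministic).  Masks are downsampled by exact box
averaging and re-binarized at coverage ≥ 0.5, which is unbiased for
area-average resampling.  `isolate_region` keeps one region and sets its
complement (and the surround) to the background gray, so foreground plus
background minus gray reconstructs the intact image inside the aperture.

## Parametric filtering

Three procedures, four steps each, applied to one region only:

* **contrast** — alpha blending toward the background gray,
  `p ← α·p + (1−α)·gray`, with α ∈ {0.75, 0.5, 0.25, 0}.  The endpoint
  α = 0 removes the region exactly (it equals isolating the complementary
  region).  The four α values are a package default (the procedure is
  "graded fading to uniform gray"); they are configurable.
* **lowpass / highpass** — radially symmetric 5th-order Butterworth
  gains, `G_lp = (1+(f/f_c)^10)^-1/2` and `G_hp = (1+(f_c/f)^10)^-1/2`
  (with `G_hp(0) = 0`), cutoffs sampled linearly on a log axis from 0.05
  to 25 cycles/degree inclusive (ratio (25/0.05)^{1/3} ≈ 7.94 between
  consecutive cutoffs).  Cutoffs are converted to cycles/pixel through
  the stimulus scale; cutoffs above the Nyquist frequency are applied
  as-is (near-all-pass for the lowpass branch) with a logged warning, so
  the printed sampling range stays faithful at any image size.

Filtering is done on the **full framed image** in the frequency domain
and the filtered pixels are then composited into the targeted region.
Filtering the masked region alone would attribute mask-boundary ringing
to the filter; with compositing, pixels outside the targeted region are
bit-identical to the intact stimulus at every step.

**RMS control.**  After compositing, the targeted region is affinely
rescaled so its RMS contrast (population SD of its intensities) equals
the intact region's value, exactly, before clipping to [0, 1].  The
affine map is `out = m₀ + s·(x − m_f)` with `m₀` the intact region mean,
`m_f` the filtered region mean and `s` the ratio of intact to filtered
RMS: the fixed point is the intact mean, which both restores mean
luminance (the highpass branch removes DC) and makes the all-pass limit
an exact identity.  Clipping can perturb the RMS afterwards (≤ ~1e−3 in
practice); both pre- and post-clip values are recorded on every
`FilteredStimulus`.  A region whose intact contrast is zero is returned
unchanged with a warning — filtering a uniform patch is undefined.

Step ordering follows filtering strength: descending α, descending
lowpass cutoff, ascending highpass cutoff.

## The fixed model

Four untrained descriptor families built on edge position, size and
orientation — the feature channels with well-known physiological
counterparts:

| descriptor | construction | dims (defaults) |
| --- | --- | --- |
| `spectral_summary` | log-Gabor energies, 4 scales (0.05–0.35 c/px) × 8 orientations, averaged on a 4×4 grid | 512 |
| `dense_gradient` | signed gradient-orientation histograms (8 bins) on an 8×8 grid | 512 |
| `pyramid_gradient` | unsigned edge-orientation histograms (8 bins) over pyramid levels 0–2, energy-normalized | 168 |
| `local_binary_pattern` | rotation-robust uniform LBP codes, histogram folded over intensity inversion | 6 |

The exact parameterizations in the literature vary by implementation;
the pipeline's claims depend on the RDM geometry the descriptors induce,
not on one canonical configuration, so the defaults above are recorded
in `FeatureVectorSet.params` and every descriptor is deterministic given
pixels plus params.  Descriptors are computed on the full framed image,
gray surround included.  Two implementation choices matter for the test
suite: the Gabor bank zeroes DC and the Nyquist row/column, which makes
a 90° image rotation an exact permutation of orientation and grid
blocks; and the LBP histogram merges bins `k` and `P−k` (intensity
inversion complements every code), making it sign-symmetric.

**Fusion.**  Each descriptor RDM is min–max normalized to [0, 1]
(per filtering step — each filtered image set is its own model
instantiation), and the four are combined by a weighted sum fitted with
5-fold cross-validation: the condensed dissimilarities are partitioned
into five seeded, disjoint, exhaustive folds; per fold, ordinary least
squares (with intercept, weights unconstrained) of the target entries on
the four model entries over the 80% training entries; Spearman ρ between
target and prediction on the held-out 20%; the reported ρ is the mean
over folds.  Folding *entries* (the default) makes the 80/20 split
exact; folding *stimuli* is available via `fold_unit="stimuli"` (train
on pairs fully inside the training stimuli, test on pairs fully held
out).

**Uncertainty.**  SEs come from bootstrap resampling of the stimuli
(default 1000 iterations): resample stimulus indices with replacement,
index the RDMs, drop pairs whose two members are the same resampled
stimulus (their dissimilarity is zero by construction, an artifact),
refit, and take the SD of the bootstrap ρ distribution.  The noise
estimate is the Spearman correlation between the two subjects' RDMs with
the same stimulus bootstrap — an effective ceiling for any stimulus
model.  Subjects are aggregated by entrywise averaging of their RDMs
before fitting.

## Inference

All permutation p-values use the add-one rank convention
`p = (1 + r)/(1 + n_perm)`, which never returns zero and is exact under
exchangeability.

**Foreground enhancement.**  Per permutation, the foreground masks are
re-assigned to stimuli by a uniform random permutation (fixed points
allowed — nothing forbids self-assignment, and excluding it would break
exactness).  The shuffled-mask foreground is isolated and its RMS
contrast matched to the behaviorally segmented counterpart of the same
stimulus, so every permutation preserves the multiset of mask sizes
(hence the fovea-to-periphery bias) and the contrast distribution; then
the full descriptor → fusion pipeline is re-run against the target RDM.
One-tailed p against the observed (true-assignment) ρ.

**Background suppression.**  For each filtering step, the observed
statistic is the difference of bootstrap means (step − intact); the null
pools the two bootstrap distributions and re-splits them at random
(without replacement) into groups of the original sizes, 10,000 times.
Two-tailed p, Bonferroni m = 13 per region (12 steps plus the
intact-vs-segmented comparison; the factor is configurable and echoed in
every output).  A significant positive difference is reported as
`increase` (suppression), negative as `decay`, otherwise `flat`.

**Control-voxel null.**  Draws voxel sets matching the ROI's size
(without replacement within a draw) from a pool outside the ROIs, builds
each subject's null RDM, and accepts a draw only when the two subjects'
null RDMs correlate within the ROI's noise band (noise estimate ± its
bootstrap SE) — matching the null's signal-to-noise ratio to the ROI's.
Each accepted draw contributes ρ(model, subject-mean null RDM); the
observed value is ρ(model, subject-mean ROI RDM).  One-tailed p,
Bonferroni m = 27 (3 intact/segmented descriptions + 12 + 12 steps).
If 10⁶ draws cannot produce the requested number of valid permutations
the procedure aborts with a diagnostic naming the band — an unattainable
band is an analysis error, not something to paper over.

## Correlation images

Per region, the best-correlating lowpass and highpass images (argmax ρ
over the four steps, ties toward the less-filtered step) are averaged
pixelwise, and each pixel's deviation from the background gray is scaled
by the region's best α.  Scaling the deviation (blending toward gray)
rather than multiplying raw intensities is deliberate: raw
multiplication would darken toward black, whereas the contrast
manipulation being summarized fades toward gray.  The two regional
composites are merged by the mask.  Images are built per stimulus, with
an across-stimuli mean as an optional summary.

## Synthetic observers

The generator replaces the source datasets (natural photographs with
manual segmentations; two subjects' voxel patterns) with desk-scale
equivalents whose ground truth is known:

* **Stimuli** — a wobbly-ellipse foreground (low-order angular
  harmonics around a random ellipse) textured with band-limited noise,
  over an independently textured background, inside the aperture on
  mid-gray.  Foreground areas are drawn and rejection-enforced between
  10% and 60% of the aperture with centers clustered near the middle,
  mimicking the fovea-to-periphery bias of photographs.  Defaults:
  n = 60 stimuli, 128 px (the validation studies use 64 px; see below).
* **Observers** — the descriptor matrix of the image version the
  observer is selective for (intact, isolated foreground, or isolated
  background; each descriptor block z-scored and scaled to equal total
  variance), pushed through a fixed seeded random projection to
  `n_voxels`, per-voxel standardized, plus independent Gaussian noise
  per subject.  `noise_sd` is therefore in units of the per-voxel signal
  SD.  Using the model's own descriptor family as the observer signal is
  intentional — it makes positive controls achievable at small n, the
  same role the reference validation gave a network simulation.  A
  model-mismatched observer (`signal="pixel_pca"`) is provided for
  robustness checks.

What the synthetic data do **not** emulate: natural image statistics
(1/f spectra, object semantics), retinotopy, hemodynamics, voxel
correlations, or subject idiosyncrasies.  Passing the validation studies
shows the *procedures* are correct and calibrated — it does not certify
effect sizes on real fMRI data.

One observer-geometry caveat worth knowing: because foreground masks
shape both the isolated-foreground signal and every region-filtered
image, strongly filtered steps still share mask-silhouette information
with the observer.  Step-wise ρ profiles on synthetic observers are
therefore not monotone everywhere; the validation verdicts use the
background-contrast endpoint (region removed), where the
suppression/decay contrast is unambiguous.

## Validation studies and problem sizes

`prefilt.validation` runs each study from scratch;
`scripts/acceptance.py --seed N --out results/acceptance.json` executes
all of them and writes the measured numbers.  The chosen desk-scale
conditions:

* filter analytics: closed-form gains, plus a 128-px full-field grating
  at the cutoff frequency (measured attenuation vs 1/√2);
* RMS control: 50 stimuli × 2 regions × {lowpass, highpass} at the
  second cutoff (0.397 cpd), max pre-clip |ΔRMS|;
* model recovery: n = 50, noise-free target = 0.4/0.3/0.2/0.1 weighted
  sum of the normalized descriptor RDMs of random features; null: 100
  independent random targets;
* enhancement power: foreground-selective observer, n = 60, noise_sd
  0.3, 200 permutations; calibration: whole-image observer with masks
  drawn from an independent generator run (the true assignment is then
  exchangeable with shuffles, so the null is exact by construction),
  20 runs × 99 permutations at n = 30;
* suppression oracle: 10 seeded runs per observer mode, n = 60,
  1000-iteration bootstraps, 10,000-iteration difference permutations,
  verdict at the background-contrast endpoint with m = 13;
* control-voxel: 40 stimuli, 60-voxel ROI, 600-voxel pools, 200 valid
  permutations; the positive-control pool shares the ROI's SNR recipe
  with an unrelated latent, the negative-control pool is generated from
  the ROI's own latent;
* correlation-image limits: series with cutoffs pushed to the all-pass
  ends (10⁻⁴ and 10³ × px/deg cpd) and α series containing 1.0, checked
  pixelwise against the intact stimulus.

The inference studies run at 64 px rather than the 128-px generator
default; descriptor geometry, not resolution, carries the signal, and
the studies' statistical structure is resolution-independent.

## Numerical choices and degenerate inputs

* Randomness: one top-level integer seed; every consumer derives a named
  substream (CRC-tagged `SeedSequence`), so enlarging one analysis never
  shifts another's draws.
* RDMs require ≥ 3 stimuli and positive row variance (the offending
  stimulus is named in the error); normalization refuses constant
  off-diagonals.
* Cross-validation refuses folds smaller than 10 dissimilarities.
* Mask downsampling refuses empty results; mask selection refuses inputs
  with no foreground patch.
* Butterworth highpass at f = 0 is defined by its limit, 0.
* Ties in the correlation-image argmax go to the less-filtered step.

## Known limitations

* The 13- and 27-fold Bonferroni families are the most consistent
  reading of the procedure they correct (12 steps + intact comparison;
  3 descriptions + 24 steps); both are configurable and echoed in every
  report.
* Whether RMS matching in the enhancement null should rescale the whole
  segmented image or only the masked region is ambiguous; the region is
  rescaled (the complement is uniform gray and contributes no contrast
  of its own).
* Descriptor parameterizations are simplified canonical forms, not
  re-implementations of any specific MATLAB release; absolute ρ values
  on real data will differ from published tables even at full scale.
* Real-data runs (full 334-stimulus, 7-ROI analyses) use the same
  dataset-directory layout but require the external downloads; nothing
  in the test suite depends on them.
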