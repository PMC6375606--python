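# Methods

`aortafinder` localizes the ascending aorta (AA) and proximal descending
aorta (PDA) on transverse cine cardiovascular MR series and converts the
detection confidence into an automated quality-control (QC) gate. This
note documents the model, its assumptions, the tunable parameters, the
synthetic phantom used for training and validation, and the numerical
choices made where the design was genuinely open.

## Pipeline

For each scan the pipeline runs five stages:

1. **Body segmentation and standardization.** The thorax cross-section is
   segmented from the dark background on the detection frame: Gaussian
   smoothing (σ = 5 px on the acquisition grid), Otsu threshold, largest
   connected component, morphological closing (disk, radius 10 px), convex
   hull. Image and mask are then interpolated to a standard 480×392 grid
   (bilinear for intensities, nearest for the mask) and the pixel spacing
   is rescaled by the true per-axis zoom factors so millimetre geometry is
   preserved. Because Otsu thresholding is invariant to affine intensity
   rescaling, segmentation does not depend on scanner gain; because the
   subsequent reference frame is anchored to the body, nothing downstream
   depends on where the body sits in the field of view.

2. **Candidate detection by phase-coded circular Hough transform (CHT).**
   Strong Sobel edges (Otsu threshold on the gradient magnitude) cast
   complex votes: for every radius r on a one-pixel ladder spanning
   6–36 mm, a unit vote `exp(iφ(r))` with the linear, invertible code
   `φ(r) = 2π (r − r_min) / (r_max − r_min + Δ)` is cast r millimetres
   along the gradient direction, both along and against it so that rims
   with locally inverted contrast still vote toward their centre. The
   accumulator is smoothed (σ = 2 px) and magnitude-normalized to 1.
   Local 8-neighbourhood maxima with magnitude > 0.1 inside the body-core
   ellipse — centred on the intensity-weighted centroid with (AP, LR)
   axes 0.6 and 0.7 times the anterior-posterior body extent — become
   candidate ROIs; the radius is read back from the accumulator phase at
   the peak. Peak centres are refined to sub-pixel precision by a
   separable parabolic fit: at a 9 mm vessel a single-pixel (0.8 mm)
   centre error alone costs ≈ 0.06 Dice, so integer peaks would put a
   visible ceiling on localization agreement. Concentric and overlapping
   candidates are kept; the classifier sorts them out.

3. **Feature extraction.** Each candidate is described by the 18-vector
   A–R documented in `features.py`: body-frame coordinates and boundary
   depth (A–C), intensity moments and Shannon entropy of the disc (D–H),
   disc-template correlation (I), dominant gradient orientation at the
   ROI scale (J), overlap with circles fitted to the motion-periodicity
   map (K), Hough peak strength and radius (L, M), and maximally stable
   extremal region statistics (N–R).

4. **Random-forest classification.** Candidates are labelled against
   annotated circles by Dice overlap (> 0.75 makes a candidate a positive
   for that vessel; everything else is "not aorta"), and a bagged
   ensemble of unpruned Gini-split trees with 6 features sampled per
   split is trained with empirical class priors. Posteriors are the
   average of per-tree leaf distributions. Out-of-bag (OOB) observations
   — each bootstrap bag contains on average 1 − (1 − 1/n)ⁿ ≈ 63.2% of
   the rows — give an internal error estimate and permutation feature
   importances.

5. **Selection and QC.** Per scan, the candidate with the highest AA
   posterior and, independently, the one with the highest PDA posterior
   are selected. Their posterior product is the QC score; scans below
   the threshold (default 0.75, the F1-optimal point; 0.95 is the strict
   preset, and the boundary value passes) are flagged for human review.
   A rule-based baseline from the pre-learning literature is included
   for comparison: the AA must be strictly bigger, anterior, and to the
   subject's right of the PDA, with centres ≥ 18 mm apart.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `preprocess.sigma_px` | 5 px | smoothing before Otsu body threshold (acquisition grid) |
| `preprocess.close_radius_px` | 10 px | closing element for the body mask |
| `preprocess.standard_shape` | 480×392 | standard grid |
| `preprocess.ellipse_factors` | (0.6, 0.7) | search-ellipse axes as fractions of AP body extent (AP, LR) |
| `preprocess.detection_frame` | 0 | cine frame used for static processing |
| `cht.r_min_mm`, `cht.r_max_mm` | 6, 36 mm | radius search range |
| `cht.min_magnitude` | 0.1 | candidate threshold on normalized peak magnitude |
| `cht.smooth_sigma` | 2 px | accumulator smoothing |
| `features.mp_threshold` | 0.3 | minimum non-DC power fraction at the cardiac frequency |
| `features.mser_delta_frac` | 0.01 | MSER intensity step (fraction of window max) |
| `features.mser_max_variation` | 0.5 | maximum relative area change for stability |
| `forest` n_trees / mtry | 1000 / 6 | ensemble size and features per split |
| QC threshold | 0.75 | posterior product below which a scan is reviewed |
| label threshold | 0.75 | Dice above which a candidate is a training positive |

## Design choices on open points

- **Radius decoded from the unsmoothed votes.** The smoothed accumulator
  locates peaks; the radius is read from the raw vote phase at the peak
  cell. Smoothing mixes neighbouring phases, and near the bottom of the
  radius ladder the mix is one-sided (no votes exist below r_min), which
  would bias a 7 mm vessel's decoded radius upward by almost a
  millimetre — enough to drop its Dice against truth below 0.9.
- **Accumulator smoothing σ = 2 px.** Smoothing flattens the sharp
  coherent peak of a true circle more than the already-diffuse vote
  background, so after normalization a small σ *raises* the relative
  background and floods the 0.1 threshold with spurious maxima (σ = 1
  yields 60–110 candidates per clean phantom). σ = 2 restores candidate
  counts to the 20–35 range while keeping sub-pixel localization; the
  value is a config key.
- **Ellipse factor assignment.** Only the product "0.6 and 0.7 times the
  AP extent" is fixed by the design; we assign 0.6 to the AP (row) axis
  and 0.7 left–right, configurable via `ellipse_factors`.
- **Detection frame.** All static processing runs on frame 0. For the
  phantom this is also the frame where the pulsatile radius equals its
  time average, which makes the annotation exactly consistent with the
  detection frame.
- **Entropy binning.** 256 bins over the frame's min–max range; the
  entropy formula fixes only the histogram normalization.
- **ROI support for intensity features.** The rasterized candidate disc
  (pixel centre within the radius, Euclidean in millimetres), not the
  bounding square.
- **MSER stability rule.** Bright-on-dark extremal regions are tracked
  through descending level sets (step 1% of the window maximum); a
  region is kept when its relative area variation between neighbouring
  levels is ≤ 50%, is a local minimum along its component chain, and the
  region has ≥ 9 px. `MSERnotOverlap` is normalized by the ROI disc
  area exactly as defined, so it can exceed 1 for a large best-matching
  region — preserved deliberately.
- **Motion-periodicity map on the acquisition grid.** The per-voxel FFT
  runs on the original grid (spatial interpolation adds no temporal
  information); the circles fitted to the map are then mapped onto the
  standard grid before the Dice feature is computed. A voxel is marked
  periodic when the 1 cycle/series harmonic dominates the non-DC
  spectrum and carries > 30% of its power; the marked set is reduced to
  its 4-neighbourhood boundary.
- **Degenerate inputs.** Constant ROIs take skewness/kurtosis/entropy 0;
  a zero-variance correlation patch and a gradient-free orientation
  window are flagged as 0; an empty motion map or MSER set yields K = 0
  and (N, O, P, Q, R) = (0, 0, 0, 1, 0). Dice of two empty masks is 0 —
  "absent vs absent" is bookkept through the explicit not-visible
  sentinel, never through mask overlap.
- **Split ties.** Tree induction delegates to scikit-learn's exact
  Gini splitter (midpoint thresholds); OOB error and permutation
  importance are computed by this package from the recorded bags.
- **Selection conflicts.** If one candidate maximizes both the AA and
  PDA posteriors the result carries a `conflict` flag; the geometry
  makes this anatomically impossible, so it is surfaced rather than
  silently resolved.

## The synthetic phantom

The generator emulates exactly the structure the detector exploits, with
defaults chosen as a realistic transverse bSSFP acquisition: 240×196
matrix, 1.6×1.6 mm pixels, 50 frames per cardiac cycle; an elliptical
mid-intensity body (AP×LR diameters 190×280 mm) on a dark background;
bright AA (15 mm mean radius, anterior-right) and PDA (9 mm,
posterior-left) with in-phase sinusoidal radius modulation (8% amplitude,
one period per series, the breath-hold assumption); circular distractors
(pulmonary trunk, superior vena cava, a left pulmonary branch, spinal
canal); additive Gaussian noise (SD 3% of the vessel intensity). Artefact
grades map onto the observer IQ scale: none → 3, moderate blur → 2,
strong blur → 1, wrong slice (vessels absent, off-anatomy structures,
not-visible annotations) → 0. Cohort generation jitters vessel centres by
±10 mm and radii by ±20%, rejecting draws that violate the anatomical
invariants (AA bigger, anterior, right, ≥ 18 mm from the PDA, everything
inside the body).

What the phantom does **not** emulate: Rician noise statistics, bSSFP
banding, flow and ghosting textures, anatomical shape variability beyond
circles, neighbouring-structure contact, and multi-slice geometry.
Passing the phantom study therefore demonstrates that the implementation
is internally correct and that the method recovers the structure it
assumes — not clinical-grade performance on patient data.

## The phantom study

`experiments.phantom_detection_study` generates 200 phantoms (IQ mix
5/15/40/40% for IQ 0/1/2/3, i.e. 20% with graded artefacts), trains the
forest on the first 100 and evaluates the held-out 100: per-vessel
detection confusion at posterior operating thresholds (0.18 AA, 0.09
PDA), accuracy restricted to usable scans (IQ ≥ 2), Dice statistics over
the true positives of that same usable subset (all-TP statistics are
reported alongside: heavily blurred IQ-1 vessels carry an outward
rim-radius bias of roughly +1 mm that a 0.9-Dice bar on a 9 mm vessel
cannot absorb), OOB error, the Mann-Whitney comparison of QC scores
between corrupted (IQ < 1) and usable scans, and the ROC AUC of the QC
score for the IQ ≥ 1 partition. These problem sizes (200 scans, 50
frames, 1000 trees) are the package's desk-scale study conditions; the
run takes roughly ten minutes on one CPU core.

## Known limitations

- The MSER detector quantizes stability analysis to 1% intensity steps;
  very low-contrast regions between steps are missed.
- The radius estimate inherits the ±½-ladder-step (±0.4 mm) resolution
  of the phase code; no post-hoc radius refinement is applied.
- The rule-based baseline resolves ties by summed Hough magnitude, one
  of several plausible conventions for the heuristics it reproduces.
- Scan-level true negatives depend on per-vessel operating thresholds
  that are data-dependent config keys, not universal constants.
- The QC gate separates severely corrupted scans from usable ones; it is
  not sensitive to one-point IQ differences among usable scans.
- On the phantom the QC ROC is essentially perfect because the unusable
  class (wrong slice, vessels absent) is categorically different from
  usable scans; clinical image quality is a continuum, so a QC AUC
  measured on phantoms overstates what the gate achieves on real data.
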