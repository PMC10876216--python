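# Methods

This note documents the models, estimators and numerical choices behind
`gazeprox`, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Gaze preprocessing

**Geometry.** The screen model is planar: a displacement of *d* pixels maps
to centimetres via the physical panel size (back-solved from the screen's
angular extents — 1920 px ↔ 45°53′, 1200 px ↔ 29°38′ at 60 cm) and then to
visual angle as the chord angle 2·atan(d/2L). Coordinates are 0-based
pixels, origin top-left, y down. The deg↔px round trip is exact to floating
precision; both full-screen extents reproduce the stated angles.

**Binocular combination.** The working trace is the midpoint of the valid
eyes; monocular samples fall back to the single valid eye. A sample is
*binocular-valid* (for attendance QC) only when both eyes are valid and
on-screen. Whether the original velocity computation used monocular or
averaged traces is not specifiable from published descriptions of the I-VT
filter; the midpoint is this package's choice and is the only place the
distinction matters.

**I-VT filter.** Angular velocity at sample *i* is a centred difference over
a 20 ms window (positions at t±10 ms, clamped at the edges). Samples below
30°/s form fixations; runs shorter than two samples are dropped (zero
duration). Tracking gaps up to 75 ms are linearly interpolated before
velocity computation — the standard I-VT gap-fill — while longer gaps break
fixations. Adjacent fixations merge when separated by ≤75 ms *and* ≤0.5°;
merged centroids are sample-count weighted. No minimum-duration discard is
applied by default (`min_duration_ms` is available). The first fixation has
no preceding saccade; its amplitude is `None` and it is unclassifiable in the
scan-mode taxonomy.

**Attendance and frame mapping.** Attendance is the fraction of video frames
containing ≥1 binocular-valid sample; recordings under 65% are flagged for
exclusion. Each frame receives the centroid of the fixation active at the
frame's temporal midpoint; frames covered by saccades, blinks or off-screen
gaze stay missing and are excluded from every downstream average (no
imputation). The stimulus frame rate is configurable; 25 fps is the default.

## The referent density and the Proximity Index

**Estimator.** Per frame, pooled reference gaze points are smoothed with a
Gaussian KDE whose bandwidth adapts to local density: a per-axis Silverman
pilot (h_j = σ_j·n^(−1/6)) evaluated at the data points yields Abramson
factors λᵢ = (f_pilot(xᵢ)/g)^(−1/2), g the geometric mean of pilot
densities. This pilot+Abramson family is used rather than a diffusion-type
estimator; both are adaptive-bandwidth families and a fixed-bandwidth switch
(`adaptive=False`) is provided for testing and comparison. Kernels are
truncated at the screen bounds by renormalizing the discrete surface to
integrate to 1 globally (not per-kernel): the PI depends only on f/f_max, so
only relative density matters.

Two deliberate departures from a textbook KDE:

* **Duplicate weighting.** Exactly repeated coordinates (common under finite
  tracker quantization) are collapsed to weights, and *n* in the bandwidth
  rule counts distinct coordinates. Duplicating every point therefore leaves
  the surface invariant instead of artificially sharpening it.
* **Bandwidth floor.** Pilot bandwidths are floored at one grid cell so that
  degenerate, near-coincident point sets still put well-sampled mass on the
  evaluation grid.

**Grid.** Default resolution is one cell per 4×4 px block (480×300 cells for
the full screen); sub-fixation precision is noise, and the 100-level
quantization dominates the score's resolution anyway. Analyses in the test
suite use coarser grids (8–32 px) to keep simulations fast; the PI is stable
across these resolutions except in the zero-noise degenerate limit discussed
below.

**Scoring.** Levels are linear: l_k = k·f_max/100. Density at a gaze point
is evaluated by bilinear interpolation between cell centers (removing
grid-cell aliasing at contour boundaries; point-in-polygon contour tests
would differ only at boundaries). PI = k/100 for the highest k with
f(gaze) ≥ l_k, ties counting as inside (a relative tolerance of 1e−9 makes
analytic ties land inside despite floating-point rounding). One consequence
of bilinear evaluation: a gaze point at the *true* mode of a very peaked
surface scores slightly below 1 unless it coincides with a cell center,
because the interpolated chord undercuts the peak. In the zero-noise limit
test this caps leave-one-out PI near 0.9 rather than 1.0; with realistic
gaze scatter (tens of pixels) the effect is negligible.

**Usability gating.** Frames with fewer than `min_points_per_frame`
(default 10) reference points are unusable and yield missing PI. Mean PI
averages available frames only.

**Reference stability.** The subsampling analysis draws bootstrap subsamples
of the reference pool at each candidate size, rebuilds sub-references, and
correlates a held-out probe set's mean-PI vector (scored on the
sub-reference) with its scores on the full reference. The smallest size whose
mean agreement reaches 0.95 is reported as the smallest stable sample. The
0.95 criterion is this package's operationalization of "stable"; when no
probe set is supplied, the last quarter of the group is held out. Agreement
is only informative when the probes are heterogeneous enough for their
mean-PI vector to have spread.

## Scan modes

Focal = duration > 180 ms AND preceding saccade < 5°; ambient =
duration < 180 ms AND preceding saccade > 5°. Both inequalities are strict,
so boundary cases (exactly 180 ms or 5°), mixed cases (long fixation after a
long saccade and vice versa) and first fixations are *unclassified* and enter
neither proportion; proportions are normalized by the total fixation count.

## Salience evaluation

The channel pipeline is a deliberately simple center-surround model:
difference-of-Gaussians contrasts at three scale pairs (σ = 1/4, 2/8, 4/16 px)
for intensity and for red/green and blue/yellow opponency; Gabor energy at
0°, 45°, 90°, 135° for orientation; |frame difference| for flicker; and a
matched-shift residual for motion — energy in direction *d* is
relu(|I_t − I_{t−1}| − |I_t − shift_d(I_{t−1})|), high exactly where content
moved by the shift (default 8 px) in that direction. Graph-based activation
and normalization schemes are intentionally *not* reproduced; the analysis
surface here is the AUC comparison, and externally computed map stacks
(e.g. true GBVS output) can be loaded through `load_salience_stack`.

AUC per frame is the Mann-Whitney rank statistic of map values at fixated
locations against all grid pixels (mid-rank ties; a constant map scores 0.5
by construction). An optional shuffled-fixations negative sampler is
provided. Group comparison pairs per-frame group means in a Wilcoxon
signed-rank test; because the effect-size convention r = Z/N appears in the
applied literature alongside the conventional r = Z/√N, both are reported,
explicitly labeled, with Z signed positive when series A exceeds B.

## Scene features

Visual complexity is the Canny edge-pixel count (Gaussian-derivative
gradient, double threshold with hysteresis; thresholds default to a
median-based automatic rule, 0.67×/1.33× the median intensity). The raw edge
map is thinned to one-pixel curves before counting, since non-maximum
suppression retains both pixels of a perfectly symmetric step's tied
gradient maximum — the measure is edge *length*, not edge-band area. Frames
are processed at full resolution.

Annotations (label, onset_s, offset_s) are rasterized onto the frame grid:
interval events mark frames whose midpoints they cover; the hard-cut channel
is a point event coding 1 on the first frame at or after the cut instant.
Speech channels (monologue vs directed speech) are mutually exclusive, as
are contradictory social-complexity codes. Social complexity (0–3 visible
characters) is an annotation input — it cannot be recovered without the
stimulus — and frames with zero characters are conventionally excluded from
content analyses downstream.

## Inference

**PLS correlation.** Blocks A (n×a) and B (n×b) are z-scored; the
cross-correlation matrix R = BᵀA/(n−1) is decomposed R = UΔVᵀ. Latent
scores are La = A_z·V, Lb = B_z·U; the latent correlation per component is
corr(La_k, Lb_k). Missing phenotype entries are median-imputed by default
(the method is configurable; mean imputation is also provided), and age or
any other covariate can be regressed out of both blocks first.

* *Permutation test* (default 1000): rows of **B only** are permuted —
  breaking the A–B pairing while preserving each block's internal
  correlation — and the k-th permuted singular value is compared to the k-th
  observed one without re-sorting. p = (1 + #{δ* ≥ δ})/(n_perm + 1), never
  exactly zero. Permuting A instead, or both, gives the same null for this
  statistic; one-sided exceedance on singular values is standard.
* *Bootstrap stability* (default 1000): rows resampled with replacement;
  resampled saliences are aligned to the original by an orthogonal
  Procrustes rotation computed from the stacked [U; V] block (resolving sign
  and rotation indeterminacy) before taking 5th–95th percentile intervals.
  A loading is "stable" when its interval excludes zero; plots draw unstable
  loadings gray.

**Sliding windows.** Recordings are age-sorted per group; contiguous blocks
of 20 (default) advance one recording at a time, and any window containing
two recordings of the same subject is skipped and logged — repeat visits a
year apart would otherwise correlate within a window. Windows are paired
across groups by index; per-window mean ages are reported so users can audit
the age matching.

**Dispersion.** Group gaze coherence on a frame is the mean pairwise
Euclidean distance between the gaze coordinates present on it; window
dispersion averages frames with ≥2 points. The between-group contrast
disp(A) − disp(B) is tested per window by randomly reassigning the pooled
individuals to two groups of the original sizes (default 100 permutations),
two-sided with the +1 correction. Two-sided is the package default since the
direction of a group difference is not known a priori. Pairwise
recording-to-recording distances are precomputed once per window pair, so
each permutation is an index-select.

## Synthetic data

The generator emulates the *structure* of a free-viewing study of a short
animated social scene: a scripted timeline of weighted attention foci between
hard cuts; a small rendered video (colored background, texture blobs shifted
by scripted background motion, bright discs at foci) whose cuts and clutter
are recoverable by the scene-feature detectors; gaze cohorts whose subjects
dwell on scripted foci (probability `on_script`) or a subject-persistent
idiosyncratic focus, with isotropic Gaussian scatter truncated at the screen
edges; frame-aligned ~150 ms blink blocks so the dropout rate equals the
expected attendance loss; yearly repeat visits; and a phenotype matrix whose
12 variables load on a latent factor correlated with mean PI at a planted
level, with optional age confound and missingness.

Default study conditions: 500-frame scenes at 25 fps on the 1920×1200 screen,
20 subjects per group, 300 Hz sampling, reference-group scatter 90 px with
92% on-script dwells, ~8% dropout — chosen so a full pipeline run stays in
the minutes range on one core. The gaze model is *not* a cognitive
simulation: dwell timing is a truncated-normal renewal process, saccades are
instantaneous jumps, smooth pursuit, calibration drift and head motion are
absent, and salience plays no causal role in where synthetic subjects look.
Passing tests therefore validate the estimators' behavior under known ground
truth, not the psychological claims one would test on real cohorts.

Problem sizes used by the heavier checks (the package's own defaults for
desk-scale validation): permutation-calibration at 200 null simulations
(windows of 20 recordings × 30 frames; PLS nulls at n = 100 with 12
B-variables and 199 permutations); latent-factor recovery at n = 166 with
1000 permutations and 1000 bootstraps; the developmental-divergence scenario
at 55 subjects × 2 visits per group over 100 frames at 60 Hz, width-20
windows with 100 permutations each.

## Known limitations

* The PI's boundary behavior depends on the density evaluation rule
  (bilinear interpolation vs polygon tests); differences are confined to
  contour boundaries and the degenerate zero-noise peak case above.
* The adaptive KDE is quadratic in distinct points per frame and linear in
  grid cells; very fine grids with large cohorts are slow. Leave-one-out
  scoring rebuilds the reference per member (no shortcut exists because the
  pilot and the Abramson factors change with the retained set).
* The salience channels are a simplified conspicuity model; absolute AUC
  levels are not comparable to published full GBVS numbers, only the
  relative comparisons the package performs.
* Sliding windows require enough recordings that a window's age span stays
  below the repeat-visit spacing, otherwise most windows are skipped.
* `group_compare`'s Wilcoxon branch and the paired AUC comparison assume
  aligned observations; no correction for multiple windows/channels is
  applied beyond what the user requests.
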