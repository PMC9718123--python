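# Methods

This note records the conventions, parameter choices and modelling decisions
behind `synovolume`, and what the phantom-based tests do and do not
demonstrate about real data.

## Coordinate and measurement conventions

- All indices are 0-based.  Slice ranges are inclusive on both ends
  (`count = last − first + 1`), matching how readers name anatomical first
  and last slices.
- Volumes are reported in mm³ and derived strictly from header voxel
  spacing (`dx·dy·dz`); no resampling, registration or bias-field
  correction is applied — volumes are consumed on their native grid.
- A voxel belongs to a polygon ROI iff its **center** lies inside or on the
  polygon.  One convention everywhere (ROIs, phantom ground truth) keeps
  rasterization ties from leaking into reliability statistics.
- Axis roles (slice axis, axial vs sagittal) are metadata supplied by the
  caller or file reader, never inferred from image content.

## Effusion-synovitis segmentation

The interactive reader session is replaced by a replayable, parameterized
equivalent: a `ThresholdSpec` (absolute intensity, empirical quantile of the
slice range, or Otsu restricted to the range) plus an explicit list of
rejected regions.  This makes every reader action serializable and testable.

- Supra-threshold is **inclusive** (`I ≥ t`) for ES.
- Region growing is 2-D within each slice, because the volume is defined as
  per-slice effusion area summed over the assessed slices; in-plane
  connectivity defaults to 8 (4 available).  Connected components come from
  `scipy.ndimage.label`; the test suite checks them against an exhaustive
  BFS flood-fill oracle.
- The Otsu variant uses a 256-bin histogram over the observed min–max of
  the slice range, maximizing between-class variance over interior bin
  edges.  Ties break toward the lower split; because empty bins create
  exact plateaus of the objective, the tie rule is applied within a 1e-9
  relative tolerance of the maximum so it is stable under floating-point
  reordering.
- `min_area_mm2` flags (never deletes) components below an area floor, so a
  scripted run can reproduce a reader rejecting sub-millimetre noise
  speckles without silent data loss.  The default is 0 (off).
- `V_Eff = Σ_s A_s · dz`, `V_Norm = V_Eff / N` with `N` the slice count of
  the patella range.  Padding the range with empty slices leaves `V_Eff`
  unchanged and strictly decreases `V_Norm` — the property that motivates
  normalizing for inconsistent patella coverage.

## Hoffa-synovitis measurement

- Four fat-pad ROIs on sagittal slices `i−3, i−1, i+1, i+3` around the
  patellar-center slice `i`; offsets are configurable but default to that
  scheme.
- The threshold is `μ_ref + k·σ_ref` from a reference ROI of at least 25
  voxels (sample mean, unbiased n−1 SD).  The reference-derived threshold
  is the minimal parameterization of "sample a homogeneous reference
  region"; `k` (default 2.0, unitless) is deliberately exposed to the
  calibration harness rather than fixed.
- Exceedance is **strict** (`I > t`) for HS, unlike the inclusive ES
  convention; an ROI sitting exactly at the threshold contributes zero.
  Both conventions are asserted by tie-case tests.
- `X_Hoff` is the volume of supra-threshold ROI voxels.  It is a
  threshold-exceedance measurement, not a calibrated synovitis volume, and
  should be interpreted as such.
- The reference ROI is caller-provided; the package does not auto-locate
  anatomy (no patella-center or fat-pad detection).
- `calibrate_hoffa` grid-searches `(k, offset set, ROI-area floor)` for the
  Spearman-correlation maximizer against ordinal grades, recording the full
  trace; grid points with constant `X_Hoff` across the cohort have
  undefined correlation and are recorded as NaN and skipped.  Ties break
  toward smaller `k`, then smaller summed `|offsets|`.

## Validation statistics

- **Spearman** is Pearson on midranks (via `scipy.stats.spearmanr`);
  constant inputs are an error rather than a silent NaN.
- **ICC** is computed from the two-way ANOVA mean squares of the balanced
  subject × rating table.  Two models are offered and both are reported in
  practice because intra/inter labels are frequently ambiguous in the
  literature: ICC(2,1), two-way random effects with absolute agreement (the
  default), and ICC(3,1), two-way mixed effects for consistency.  Zero
  between-subject variance returns NaN with an explanatory warning.  The
  single-outlier sensitivity analysis removes the subject with the largest
  absolute between-rating difference and reports both ICCs plus the removed
  ID.
- **AUC**: a single-predictor logistic model is fitted (statsmodels), but
  the AUC itself is computed by midrank (Mann–Whitney) pair counting on the
  predictor scale, with ties counted ½.  For a monotone predictor this
  equals the AUC of the fitted probabilities whenever the fitted slope is
  non-negative, and it remains defined under complete separation, where the
  logistic likelihood has no finite maximizer (the fit failure is recorded
  as a warning).  P-values against AUC = 0.5 use the Mann–Whitney normal
  approximation with tie correction — an approximation, documented as such.
- **Bootstrap CIs** are percentile intervals (the minimal reading of
  "bootstrap resampling"), default 500 replicates at the 95% level,
  resampling cohort rows with replacement; single-class resamples are
  redrawn and counted; a statistic undefined on more than half the
  resamples aborts.  Intervals are bit-reproducible for a fixed seed.

## Phantoms and the cohort simulator

The phantoms are minimal geometric scenes, not anatomy: their purpose is an
exact, independently recomputable ground truth.

- Ground truth is defined on the noiseless image by voxel-center
  membership — the same convention as ROI rasterization — so recovery
  errors isolate algorithmic behavior from convention mismatch.
- Noise is additive Gaussian by default; at the signal-to-noise of
  fluid-sensitive sequences the difference from Rician is immaterial for
  thresholding behavior, and Gaussian keeps the oracles simple.  A Rician
  option exists for realism.
- Default spacing is 0.5×0.5×1.5 mm axial and 0.4×0.4×3.0 mm sagittal —
  plausible MR values chosen for the phantom, not tied to any specific
  acquisition protocol.
- The "separable" axial preset keeps fluid–background contrast ≥ 4× the
  noise SD, which guarantees Otsu recoverability; the sagittal phantom
  plants an exact integer count of hyperintense voxels per ROI (fractions
  that do not digitize to an integer are rejected).

`simulate_cohort` produces a desk-scale analog of a nested case-control
progression study:

- Group sizes are exact (default 97/52/52/100 of n = 301).  Groups are
  assigned first and apply weak multiplicative lifts to true volume
  (defaults: +25% for radiographic progressors, +5% for pain progressors),
  chosen so that case-control AUCs land in the modest 0.55–0.60 range
  rather than being trivially separable.  This inverts the
  "group probability given volume" direction of causality; the induced
  joint distribution is equivalent for the battery's purposes and permits
  exact group counts.
- Ordinal grades are drawn from the 111/131/53/6 (effusion) and
  139/135/24/3 (Hoffa) frequency patterns of a 301-knee progression cohort;
  grade-to-volume means are monotone (2 000/6 000/12 000/20 000 mm³ for
  effusion — the scale of suprapatellar effusion volumes — and
  50/250/700/1 400 mm³ for the Hoffa exceedance measure) with lognormal
  scatter (σ_log = 0.45).
- Each knee's effusion volume is digitized through an actual axial phantom
  spec (ellipsoid semi-axes solved from the target volume); the returned
  specs can be rendered individually.  The cohort's measurements apply a
  two-reader error model (multiplicative biases 1.00/1.03, lognormal noise
  CV 6%, optional additive term) to the digitized truth rather than
  rendering and re-segmenting 301 image volumes — reader error and
  segmentation error are validated separately, and this keeps the full
  battery runnable in seconds.
- The reliability subset (default 30 knees) is weighted toward a uniform
  grade distribution; it is re-read by reader 1 (intra-reader) and read by
  reader 2 (inter-reader).

## What the tests show — and do not

Passing the phantom battery demonstrates: exact bookkeeping (volumes,
partitions, edits), oracle-exact statistics, threshold monotonicity,
sub-percent ES recovery under separable contrast, exact HS exceedance
counting, calibrated bootstrap coverage, and a correctly wired end-to-end
battery.  It does **not** demonstrate performance on real knee MRI: real
effusions are not ellipsoids, real backgrounds are not uniform (cartilage,
bone marrow and vessels all produce bright confounders that phantom
speck-rejection does not emulate), intensity inhomogeneity and partial
volume effects are absent, and reader variability is richer than a
two-parameter error model.  Published correlations, ICCs and AUCs for such
measures come from real cohorts with expert ordinal reads and are outside
what synthetic data can reproduce.

## Problem sizes

Default test-time sizes: 64×64×24 axial and 80×80×32 sagittal phantoms; 20
phantoms per recovery/monotonicity sweep; 200 random slices for the
flood-fill equivalence; 500 random cohorts (n ≤ 30) for the AUC oracle; 200
outer replications × 500 bootstrap replicates at n = 300 for coverage; 100
seeded cohort runs for the permutation comparison.  These sizes give stable
pass/fail behavior on a single CPU while keeping the whole suite fast.
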