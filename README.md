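# synovolume

Semi-automated quantification of knee **effusion-synovitis (ES)** and
**Hoffa-synovitis (HS)** volumes on MRI, with a full validation toolkit and
synthetic phantom generators.

Inflammation of the knee synovium in osteoarthritis shows up on non-contrast
fluid-sensitive MRI in two places: as hyperintense fluid/synovial thickening
in the suprapatellar bursa (effusion-synovitis), and as hyperintense signal
within Hoffa's infrapatellar fat pad (Hoffa-synovitis).  Research studies
usually grade both on ordinal 0–3 scales (e.g. MOAKS), which is subjective
and coarse.  `synovolume` implements the continuous, volumetric alternative:
scriptable reader workflows that segment and measure both features in mm³,
plus the statistics needed to validate such measures against an ordinal
standard, across readers, and against case-control status.

It is aimed at imaging researchers building or validating quantitative
synovitis biomarkers, and at anyone who needs a reproducible, replayable
stand-in for an interactive segmentation session.

## The measurements

**Effusion-synovitis**, on axial stacks over the patella slice range of
`N` slices:

- an intensity threshold `t` is resolved (an absolute value, an empirical
  quantile of the range, or an Otsu split restricted to the range),
- supra-threshold voxels (`I ≥ t`) are grown into connected regions slice by
  slice (8- or 4-connectivity in-plane), and reader edits are replayed as an
  explicit rejection list,
- `V_Eff = Σ_s A_s · dz` — the accepted effusion area per slice summed over
  the assessed slices times the slice thickness — and
  `V_Norm = V_Eff / N`, which corrects for inconsistent patella coverage
  across scans.

**Hoffa-synovitis**, on sagittal stacks: four polygonal fat-pad ROIs are
drawn on slices `i−3, i−1, i+1, i+3` around the patellar-center slice `i`; a
homogeneous reference region gives a threshold `μ_ref + k·σ_ref` (default
`k = 2`), and

- `X_Hoff = Σ_j |{v ∈ ROI_j : I(v) > μ_ref + k·σ_ref}| · v_voxel`,

the volume of ROI voxels *strictly* exceeding the reference-derived
threshold.  A calibration harness scans `(k, slice offsets, ROI-area floor)`
for the Spearman-correlation maximizer against ordinal grades.

**Validation battery**: Spearman rank correlation against ordinal grades
(criterion validity); intraclass correlation coefficients ICC(2,1) /
ICC(3,1) from two-way ANOVA mean squares, with a single-outlier sensitivity
re-analysis (reader reliability); and case-control AUC from a
single-predictor logistic model with percentile-bootstrap 95% confidence
intervals, 500 replicates by default (clinical validity), over three
case definitions of the four progression groups (primary: group 1 vs 2–4;
radiographic: 1–2 vs 3–4; pain: 1,3 vs 2,4).

**Phantoms**: axial stacks with an ellipsoidal fluid pocket of exactly known
digitized volume, sagittal stacks with planted hyperintense ROI fractions,
and a cohort simulator (default 301 knees, groups 97/52/52/100) with a
two-reader error model — every measurement above can be exercised against
exact ground truth.

## Worked example

Generate a noisy axial phantom (contrast-to-noise 4) and segment it:

```
$ synovolume phantom axial --contrast-to-noise 4 --seed 3 --out-dir demo/
$ cat demo/ground_truth.csv
true_fluid_voxels,true_volume_mm3,range_first,range_last
5380,2017.5,7,16

$ synovolume es --volume demo/axial.nii.gz --range 7:16 \
      --threshold-mode otsu --min-area 1.0 --reject-flagged \
      --knee-id demo --out demo/es.csv
demo: threshold=112.083 v_eff=2011.50 mm^3 v_norm=201.15 mm^3/slice
```

The Otsu threshold resolved within the patella range (112.08, between the
background mean 40 and fluid mean 200) recovers 2011.5 mm³ against a true
digitized fluid volume of 2017.5 mm³ — a 0.3% error; `--min-area 1.0
--reject-flagged` replays a reader rejecting sub-millimetre noise speckles.

Simulate a 301-knee cohort and run the validation battery from Python:

```python
from synovolume import simulate_cohort, run_validation_battery

_, cohort, _ = simulate_cohort(n=301, seed=42)
table = run_validation_battery(cohort, bootstrap_replicates=500, seed=42)
print(table[table.measure == "v_eff_mm3"].to_string(index=False))
```

```
  measure          analysis    value   n  p_value  ci_lower  ci_upper
v_eff_mm3 spearman_vs_grade 0.832048 301      NaN       NaN       NaN
v_eff_mm3  icc_intra_reader 0.982242  30      NaN       NaN       NaN
v_eff_mm3  icc_inter_reader 0.985529  30      NaN       NaN       NaN
v_eff_mm3       auc_primary 0.600617 301 0.004782  0.528088  0.660290
v_eff_mm3  auc_radiographic 0.557091 301 0.086775  0.494905  0.617665
v_eff_mm3          auc_pain 0.598993 301 0.002981  0.540259  0.661043
```

The simulated effusion volume correlates strongly with its ordinal grade
(r = 0.83), reader reliability is high (ICC ≈ 0.98 on the 30-knee repeat
subset), and the case-control AUCs are modest (0.53–0.60) because the
simulator plants deliberately weak progression-group effects.

The same workflows are exposed as `synovolume es | hs | validate | phantom |
batch`; `batch` takes a JSON run configuration, isolates per-knee failures,
and writes a timestamped log from which `timing_report` summarizes per-knee
wall-clock time.

## Layout

- `synovolume.image_core` — volumes, slice ranges, masks, polygon ROIs,
  NIfTI/DICOM I/O, rasterization and volume arithmetic
- `synovolume.es_segmentation` — thresholds, per-slice region growing,
  reader edits, `V_Eff`/`V_Norm`
- `synovolume.hs_quantification` — slice scheme, reference sampling,
  `X_Hoff`, calibration harness
- `synovolume.validation_stats` — Spearman, ICC, AUC, bootstrap, cohort table
- `synovolume.phantom` — axial/sagittal phantoms and the cohort simulator
- `synovolume.cli` / `synovolume.batch` — command-line interface and batch runs

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
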