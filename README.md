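# tractmetrics

Tract-specific quantitative analysis of white-matter bundles on voxel
grids, built for studies where focal lesions (as in multiple sclerosis)
make per-subject tractography unreliable and a cohort-derived probability
template is the alternative. The package covers the quantitative half of
such a study — everything downstream of registration and segmentation:

* **Probabilistic template construction.** Individual binary tract masks
  `v_i`, warped to a common space upstream, are averaged voxel-wise into a
  probability map `ω` (voxel value = fraction of the cohort whose tract
  occupies it). A binary template is obtained by thresholding `ω` over a
  grid of cutoffs (1%…99% in 1% steps) and keeping the threshold that
  maximizes the mean Dice similarity coefficient
  `DSC = 2|A∩B| / (|A|+|B|)` against the individual masks.
* **Probability-weighted volumetry.** Tract volume `V = r·Σᵢ ωᵢ` and
  tract lesion volume `V_L = r·Σᵢ vᵢ·ωᵢ` (with `v` the binarised lesion
  mask and `r` the voxel volume in mm³), reported in mL; head-size
  normalisation via a user-supplied scaling factor.
* **Compartment diffusivity.** Tract voxels overlapping lesions form the
  *lesional* compartment, the rest the *non-lesional* (normal-appearing)
  compartment; each of AD, RD, MD and FA is summarised per compartment by
  the probability-weighted mean `D̄ = Σᵢ Dᵢωᵢ / Σᵢ ωᵢ`.
* **Method agreement.** When two or more segmentation methods measure the
  same subjects: Pearson's r, Bland–Altman bias and ±1.96 SD limits of
  agreement, inter-subject variability CV% = SD/mean·100, paired Wilcoxon
  signed-rank, one-way ANOVA with Tukey HSD post-hocs, Dice summaries.
* **Synthetic phantoms.** A generator of cohorts with known ground truth
  (jittered tube tracts, middle-biased spherical lesions, diffusivity
  maps with configured lesional contrast), so every stage is testable
  end-to-end without any imaging data.

All volumes are NIfTI-1 (`nibabel`), pre-aligned upstream; grid mismatch
is an error, never silently resampled.

## Worked example

```sh
# 1. simulate a 10-subject phantom cohort (writes NIfTI + truth.csv + manifest.csv)
tractmetrics simulate --out cohort/ --seed 42

# 2. build the probability template from the tract masks and pick the
#    Dice-optimal binarisation threshold
tractmetrics build-template \
    --masks cohort/sub-001_tract.nii --masks cohort/sub-002_tract.nii \
    --masks cohort/sub-003_tract.nii --masks cohort/sub-004_tract.nii \
    --masks cohort/sub-005_tract.nii --masks cohort/sub-006_tract.nii \
    --masks cohort/sub-007_tract.nii --masks cohort/sub-008_tract.nii \
    --masks cohort/sub-009_tract.nii --masks cohort/sub-010_tract.nii \
    --out-prob template_prob.nii --out-bin template_bin.nii --curve dsc_curve.csv
# -> optimal threshold 0.31, mean DSC 0.7961, template volume 10.66 mL

# 3. per-subject metrics with each method
tractmetrics metrics --manifest cohort/manifest.csv --out metrics_individual.csv
tractmetrics metrics --manifest cohort/manifest.csv --mode template \
    --template template_prob.nii --out metrics_template.csv

# 4. agreement between the two methods
tractmetrics compare --metrics metrics_individual.csv \
    --metrics metrics_template.csv --out report.csv --plots plots/
```

The `build-template` line prints the threshold at which the binarised
template best matches the individual masks (here 0.31 with mean DSC 0.80
— high because phantom tracts are mildly jittered copies of one tube) and
the probability-weighted template volume. `metrics_*.csv` hold one row
per subject: tract/lesion/compartment volumes in mL, the 12 weighted
diffusivity means (AD/RD/MD in 10⁻³ mm²/s; this run recovers cohort-mean
lesional AD 1.451 vs non-lesional 1.162, the configured default phantom
contrast 1.46 vs 1.17 up to sampling noise), with empty cells
where a subject has no lesional tissue. `report.csv` has one row per
metric and method pair with r, Bland–Altman bias and limits, CV% per
method, and Wilcoxon/ANOVA/Tukey p-values.

The same flow is available as a library (`tractmetrics.generate_cohort`,
`build_probability_template`, `optimize_threshold`,
`compute_tract_metrics`, `paired_method_comparison`, …); see the module
docstrings and `docs/methods.md`.

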