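# Methods

## Scope and model

`tractmetrics` implements the quantitative layer of a tract-specific
imaging analysis. Its inputs are per-subject 3D volumes already resampled
to a common voxel grid by upstream tools (registration, tractography,
lesion segmentation, tensor fitting are all out of scope): binary tract
masks from individual tractography, probability-weighted tract templates
or atlases, binarised T2 lesion masks, binary anatomical exclusion masks,
and scalar diffusivity maps (AD, RD, MD in 10⁻³ mm²/s; FA dimensionless).

Everything rests on three formulas over a voxel grid with voxel volume
`r` (mm³), tract weights `ω_i ∈ [0,1]` and lesion indicators `v_i ∈ {0,1}`:

* weighted tract volume `V = r Σ ω_i`,
* weighted lesion volume `V_L = r Σ v_i ω_i`,
* weighted scalar mean `D̄ = Σ D_i ω_i / Σ ω_i`.

`r` is interpreted as the voxel *volume*, not its linear size — the only
reading with correct units; outputs are mL (÷1000). A binary tract mask
is the degenerate `ω ∈ {0,1}` case, so tractography-based and
template-based analyses flow through identical code.

The lesional/non-lesional partition is voxel-wise: tract voxels under the
lesion mask keep their weight in the lesional compartment and are zeroed
in the non-lesional one. Two exact identities follow and are enforced by
tests: compartment weighted volumes (and weight sums) add up to the
whole-tract values, and the whole-tract mean is the weight mixture of the
compartment means. A fibre-wise partition (lesional/proximal/distal along
streamlines) would need streamline geometry, which voxel masks do not
carry; it is out of scope.

The anatomical exclusion mask (e.g. thalamus, which abuts the anterior
end of the optic radiation) is applied to the tract map *before* any
metric is computed.

## Template construction and threshold choice

The probability template is the voxel-wise mean of the individual binary
masks; by linearity its weighted volume equals the mean individual mask
volume exactly, which doubles as a self-check. Binarisation uses the
threshold maximizing mean Dice against the individual masks over a
1%–99% grid in 1% steps (configurable). Details that the formula alone
does not fix:

* **Inclusive thresholding.** A voxel exactly at the threshold survives
  (`ω ≥ t`): zeroing is defined for voxels *below* the cutoff. An
  `inclusive` flag allows `ω > t` for sensitivity analysis.
* **Tie-break.** Equal mean DSC at several thresholds resolves to the
  lowest — the larger, more inclusive template.
* **Empty inputs.** Dice of two empty masks is defined as 1.0 (identical
  sets); subjects with an empty mask contribute DSC 0 against any
  nonempty template, with a warning, rather than being dropped.
* **Common-space comparison.** Dice is computed in the space the masks
  arrive in. A pipeline that warps the thresholded template back to each
  subject's native grid before comparing can feed those warped masks in;
  the optimisation itself is unchanged.
* **Implementation.** The sweep sorts template values once per mask, so
  `|T(t)|` and `|T(t) ∩ M|` are read off by binary search rather than
  binarising 99 times; the test suite pins this against an independent
  literal re-binarisation sweep, exact to 1e-12.

## Agreement statistics

For two or more methods measuring the same per-subject quantity:
Pearson's r with two-sided p; Bland–Altman bias (mean of `x − y`), sample
SD (n−1), and limits of agreement at ±1.96 SD (multiplier configurable);
inter-subject CV% = sample SD/mean × 100; paired Wilcoxon signed-rank;
one-way ANOVA with Tukey HSD post-hocs; Dice mean/SD/min/max when masks
are supplied. Hypothesis tests are delegated to `scipy.stats`;
Bland–Altman, CV% and Dice summaries are computed directly. Normality is
not auto-tested — both the parametric and rank-based results are always
reported and the analyst picks per metric, the usual practice in
method-comparison work. Degenerate cases return NaN rather than raising:
zero-variance Pearson, zero-mean CV, and Wilcoxon with all-zero
differences. No multiple-testing correction is applied across the metric
battery.

## The phantom generator

The phantom reproduces the *statistical* structure of a lesioned-tract
cohort, not anatomy:

* **Tract**: a fixed analytic arc (anterior→posterior with a lateral
  bow) dilated to a tube of radius 3 voxels on a 40×48×40 grid of 2 mm
  isotropic voxels (defaults; ≈1300–1400 tract voxels ≈ 11 mL — a
  deliberately downsampled bundle that keeps the full test suite under a
  minute per stage). Each subject's tract is the tube displaced by a
  smooth random field: a global shift plus 3 sinusoidal modes per axis,
  marginal SD 1 voxel. Zero jitter collapses the cohort to identical
  tracts and a {0,1} template.
* **Lesions**: Poisson(3) spheres per subject, radii U(1.5, 3) voxels,
  centres placed along the tube at a Beta(3,3)-distributed arc position
  (concentrating them in the middle third, the periventricular segment
  where MS lesions cluster) with 2-voxel perpendicular scatter.
* **Diffusivity**: per subject, a non-lesional baseline per metric drawn
  from realistic white-matter values (AD 1.17 ± 0.034, RD 0.63 ± 0.038,
  MD 0.81 ± 0.030 ×10⁻³ mm²/s, FA 0.38 ± 0.031 across subjects), plus a
  fixed lesional offset inside lesions (AD +0.29, RD +0.19, MD +0.22,
  FA −0.01 — diffusivities rise, anisotropy falls), plus i.i.d. Gaussian
  voxel noise (SD 0.02) everywhere; NaN outside a brain ellipsoid. RD is
  clamped to ≤ AD and FA to [0,1] after noise; at the default noise these
  projections sit ~19σ from ever acting, so recovery stays unbiased.
* **Determinism**: one RNG stream per cohort seeded explicitly; the seed
  is stored in each subject's truth record.

What the phantom does *not* emulate: anatomical tract shape, lesion
texture and confluence, partial-volume and CSF contamination, spatially
correlated noise, registration error, atrophy. Passing tests therefore
certify the arithmetic and the statistical machinery under known truth —
not robustness to real-data artefacts, which live upstream of this
package anyway.

### Recovery tolerances

Binary-mask volumetry is exact counting, so recovered volumes must equal
truth to float precision. A compartment's weighted mean differs from its
configured value only by averaged voxel noise, giving the CLT tolerance
`4·σ_noise/√n` for a compartment of `n` voxels (per check ≈ 6×10⁻⁵
two-sided failure probability, so ≥95% of checks passing is a loose
bound). For the qualitative lesional-contrast check (AD/RD/MD higher,
FA not higher in lesions), a subject qualifies as *sufficiently lesioned*
at ≥50 lesional voxels: the FA offset is only −0.01, and 50 voxels is
where it exceeds ~3.5σ of the lesional-mean noise, i.e. the smallest
compartment in which the direction of so subtle an effect is reliably
estimable at all.

## Numerical and I/O conventions

* Grids must match exactly (absolute tolerances: 1e-6 mm on voxel dims,
  1e-4 on affine entries, equal shapes and space tags); mismatch raises,
  nothing is resampled. Voxel indices are 0-based; affines are carried
  for I/O round-trips only.
* NIfTI-1 via nibabel; masks written uint8, scalar maps float32. On
  read, masks must be exactly {0,1}; probability maps within 1e-6
  outside [0,1] are clamped with a warning (float32 round-trip slack),
  beyond that rejected.
* Diffusivity units are normalised internally to 10⁻³ mm²/s; a manifest
  column `diffusivity_units: mm2/s` rescales AD/RD/MD by 1000 on load.
* CSV: UTF-8, comma-separated, header row; NaN metrics emit empty cells.
* Pipeline robustness: per-subject failures are logged and skipped; a run
  aborts when more than half the cohort fails, or immediately on a
  template/subject grid mismatch (naming the subject).

## Problem sizes

Defaults are sized for interactive use: the phantom grid is 40×48×40
(76 800 voxels), cohorts of 8–20 subjects, 99-point threshold sweeps, and
200 replicate subjects for recovery checks; the acceptance script runs in
a few seconds and the full test suite in under a minute on one CPU. All
sizes are configuration, not constants — larger grids and cohorts only
cost time.

## Known limitations

* No registration/resampling: misaligned inputs are rejected, not fixed.
* The template↔subject comparison happens in whichever space the inputs
  share; native-space Dice requires upstream inverse warping.
* Whole-tract means apply no exclusion beyond NaN voxels (no extra CSF
  or lesion-fill criterion).
* A single user-supplied scaling factor serves for both skull-size and
  brain-volume normalisation variants.
* The agreement battery treats methods symmetrically; it does not model
  repeated measures beyond pairing (no mixed-effects).
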