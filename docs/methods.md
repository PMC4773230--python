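# Methods

## Volumes, calibration and geometry

CT volumes are held as 3-D HU arrays in slice–row–column order with the
slice index increasing toward the head; all geometry is in millimetres.
DICOM series are read per-file with the rescale slope/intercept applied
(missing rescale tags are a hard error — no silent default calibration) and
slices sorted by position along the slice normal; mixing series in one
directory is an error. NIfTI input is reoriented to canonical RAS before
transposition into the internal order. HU values are clamped to the 12-bit
range [−1024, 3071] on construction; out-of-scan padding therefore maps to
−1024 and stays inside the lung threshold window rather than falling outside
it unexpectedly. No resampling is performed on read: all volumes are
expressed as voxel counts × voxel volume in the native grid.

## Lung segmentation

Candidates are all voxels with HU in the closed interval [−1024, −200].
Both endpoints are inclusive; the same convention is used everywhere
downstream so the candidate set and the CaM denominator coincide exactly.
The refinement that replaces interactive vessel/bronchus editing is fully
deterministic, in this order:

1. **Exterior air removal** — candidate components (26-connectivity) that
   touch any face of the grid are deleted.
2. **Morphological opening** with an anisotropy-aware ball of radius
   `opening_radius_mm` (default 1 mm), which detaches thin vessel/airway
   bridges. Opening is anti-extensive, so the output remains a subset of the
   candidates.
3. **Small-component filtering** — components smaller than
   `min_component_voxels` are dropped; the default corresponds to 1 cm³ at
   the volume's spacing, which suppresses airway fragments.
4. **Airway removal (optional, default on)** — remaining components that
   reach the top slice with a mean attenuation below −950 HU (air, not
   parenchyma at roughly −850 HU) are treated as the trachea/main-bronchus
   tree and deleted.

If nothing survives, segmentation fails loudly ("no lung found"). The whole
procedure is deterministic given (volume, parameters), which is what makes
repeat scoring of the same volume exactly reproducible.

## CaM densitometry

Within the lung mask, voxels are classed by attenuation: normal
[−1024, −700], ILD (−700, −500], consolidation (−500, −200]. The cut points
are the standard densitometric thresholds (normal parenchyma ≈ −800 to −900
HU; −700 HU separating normal lung from ground-glass/reticular density;
−500 HU separating ground-glass from consolidation). Interval membership at
the cuts is a convention: the half-open partition is chosen because it makes
the three class counts sum exactly to the lung total, so the two algebraic
forms of the fibrosis percentage —
`100·(total − normal)/total` and `100·(ild + consolidation)/total` — agree
to machine precision. The cut values are configurable; the membership rule
is fixed. The fraction is computed over the whole 3-D volume (per-slice
profiles are a diagnostic output only) and reported to 0.1% in rendered
text, with full precision retained in machine-readable output.

## Warrick visual score

Severity points per abnormality (ground-glass 1, irregular pleural margins
2, septal/subpleural lines 3, honeycombing 4, subpleural cysts 5) and extent
points per segment count (0→0, 1–3→1, 4–9→2, >9→3) are fixed lookup tables;
total = severity + extent ∈ [0, 30]. Segment identifiers are validated
against an 18-segment bronchopulmonary atlas (10 right, 8 left with the
apicoposterior and anteromedial-basal segments fused), the common convention
that gives "more than nine segments" a concrete universe. Findings are
ingested from a flat CSV of (study, reader, abnormality, segment) rows and
aggregated to sets, so duplicate rows are harmless. Dual readers combine by
component-wise mean; consensus adjudication is represented as data (a third
assessment supplied by the caller), not computed.

## Statistics

- Sample SD uses the n−1 denominator; IQR bounds are the 25th/75th
  percentiles with linear interpolation.
- Two-sample *t* test (pooled variance) for continuous variables; χ² without
  continuity correction for categorical ones (correction available by flag).
- Pearson r with the t-transform p-value on n−2 df.
- Multivariate OLS with intercept; SEs from the unbiased residual variance;
  per-covariate partial correlation `r_partial = t/√(t² + df)`,
  df = n − k − 1, signed by t; adjusted R² = 1 − (1−R²)(n−1)/(n−k−1). Rank
  deficiency raises an error naming the collinear columns (detected from
  vanishing QR diagonals) rather than silently dropping one — mirroring the
  practice of excluding a collinear covariate explicitly.
- ICC variant: two-way random effects, absolute agreement, single measure
  (ICC(2,1)) from the mean-squares decomposition — the standard choice for
  inter-reader agreement. A grid constant across subjects and raters has no
  between-subject variance and is an error.
- Bland–Altman limits: mean difference ± 1.96 × SD of paired differences.
- Missing data are complete-case per analysis and n is reported with every
  statistic; p-values are two-sided and never used to drop covariates
  automatically.

## Synthetic phantoms

A phantom is exterior air (−1000 HU) around an elliptic-cylinder soft-tissue
body (40 HU) containing two ellipsoidal lungs. Lung voxels are fibrotic with
probability equal to the design fraction — optionally weighted toward the
pleura (subpleural pattern) or the lung bases (basal pattern), renormalised
so the mean probability stays on the design value — and draw HU from
Normal(−600, 50) if fibrotic, Normal(−850, 40) otherwise, clamped to
[−1024, 3071]. A global HU shift parameter stands in for inspiration-level
effects. Ground truth is counted on the emitted volume: the realized
fibrotic fraction is (geometric-lung voxels with HU in (−700, −200]) /
(geometric-lung voxels with HU in [−1024, −200]), so scoring the phantom
with its own lung mask reproduces the realized fraction identically, and
any discrepancy under the pipeline's own segmentation is attributable to
edge voxels. The realized fraction sits slightly below the design fraction
(≈ 2% relative) because the Normal(−600, 50) tail below −700 HU counts as
normal; this is a property of the HU model, not a bug, and the recovery
tests budget for it.

The phantoms model only what a threshold densitometer can see — the HU
distribution and its coarse spatial weighting. They contain no airway or
vessel trees, no reconstruction-kernel noise texture and no honeycomb
microstructure, so passing tests demonstrate correctness of the scoring
pipeline, not robustness to real anatomical confounders.

## Synthetic cohorts

Cohorts are drawn from a Gaussian copula. Marginals (means/SDs with scale
bounds for continuous variables, prevalences for binaries) default to an
SSc-ILD-like preset: age 60.68 ± 10.74 y, disease duration 11.15 ± 7.96 y,
mRSS 10.22 ± 7.37, Borg 2.59 ± 1.62, VAS 29.24 ± 17.64 mm, HAQ-DI
0.84 ± 0.35, DLco 71.59 ± 14.39%, FVC 80.69 ± 18.63%, CoVR total
13.22 ± 6.98, CaM fibrosis 12.68 ± 7.99%, 83.7% female, 43.7% diffuse
subtype, anti-topoisomerase-I 32.5%, anti-centromere 43.6%. The continuous
transforms are affine + clamping to each scale's bounds (mRSS also rounded
to integer); clamping-induced mean bias is below 5% of each target SD at
these settings (verified at n = 10⁵). The preset correlation targets are
the univariate structure among the imaging, physiologic and patient-centred
measures (CaM–CoVR 0.718, CaM–FVC −0.556, CaM–DLco −0.670, CaM–HAQ 0.597,
Borg–VAS 0.627, HAQ–Borg 0.546), remaining pairs 0.

Two numerical points deserve emphasis:

- **PSD repair.** The preset target matrix with zeros elsewhere is not
  positive semidefinite (the CaM row alone has squared norm > 1), so it is
  projected to the nearest correlation matrix (Higham alternating
  projections) before sampling. The achieved ("effective") pairwise
  correlations — reported by `calibrate_copula` — are therefore smaller than
  the raw preset values. The preset is a demonstration of the correlation
  *pattern*, not ground truth, and recovery tests compare samples against
  the effective targets.
- **Latent calibration.** Clamping and binary thresholding attenuate Pearson
  correlations, so each pairwise latent correlation is calibrated by root
  finding on a common-random-number Monte-Carlo estimate (4 × 10⁵ draws,
  fixed internal seed — part of the model, independent of the sampling
  seed) so that the post-transform correlation hits its target to ≈ 0.001.

The copula reproduces marginals and pairwise correlations only: it does not
model subtype-conditional shifts (e.g. higher mRSS in diffuse disease), so
subtype-stratified tables from synthetic cohorts show similar groups. The
CoVR total is generated as one marginal and split into extent/severity at
the preset mean ratio (capped so both stay in [0, 15]).

## Pipeline, configuration and problem sizes

The run configuration is versioned YAML; unknown keys are a hard error.
All randomness flows from a single seed; logging goes to standard error
with stage tags, and a machine-readable manifest (inputs, parameters,
versions, seed, stages) accompanies every run. Numeric outputs are
byte-identical across re-runs of the same configuration.

Default problem sizes were chosen so the full validation battery runs on a
laptop: repeat-reliability experiments use twenty 40×64×64 phantoms
(~110 k lung voxels each); design-fraction recovery uses 136×200×200
phantoms (~10⁶ lung voxels); cohort-recovery checks use n = 5000 samples
against Fisher-z 99% sampling intervals and n = 10⁵ for marginal-bias
checks.

## Known limitations

- The deterministic airway rule is a surrogate for interactive editing; on
  real data near the hilum it will differ from an expert's mask.
- Thresholds are attenuation-only; texture-based ILD classification and
  zone-of-maximal-involvement scoring are out of scope.
- Printed partial correlations from small clinical tables are treated as
  descriptive; the package recomputes them from its own fits rather than
  targeting published values whose degrees of freedom are not recoverable.
- Contrast-enhanced protocols, multi-frame enhanced-CT DICOM objects, lobe
  separation and longitudinal change modelling are not supported.
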