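# fibroscore

Quantitative scoring of interstitial lung disease (ILD) on chest HRCT in
systemic sclerosis (SSc), for imaging researchers and rheumatology groups who
want a reproducible, scriptable alternative to workstation-bound densitometry.

The package implements two complementary scores and the statistical layer
that relates them to lung physiology and patient-centred measures:

- **CaM (computer-aided method).** The lung is isolated by thresholding: all
  voxels with attenuation in [−1024, −200] HU, cleaned by deterministic
  removal of exterior air, morphological opening and small-component
  filtering. Within the lung, voxels are classed by attenuation as normal
  parenchyma [−1024, −700] HU, ILD (ground-glass + reticular) (−700, −500] HU,
  or consolidation (−500, −200] HU. The percent pulmonary fibrosis is

  ```
  fibrosis % = 100 × (V_lung − V_normal) / V_lung
  ```

  where `V_lung` is the total lung volume (HU in [−1024, −200]) and
  `V_normal` the normal-attenuation volume (HU in [−1024, −700]).

- **CoVR (conventional visual reader-based score, Warrick).** Readers record
  five abnormality patterns (ground-glass = 1, irregular pleural margins = 2,
  septal/subpleural lines = 3, honeycombing = 4, subpleural cysts = 5 severity
  points) and the bronchopulmonary segments involved per pattern (1–3
  segments → 1, 4–9 → 2, >9 → 3 extent points). Total = severity + extent,
  range 0–30; dual readers are combined by the mean or by a supplied
  consensus.

- **Cohort statistics.** Descriptives (mean ± SD, median/IQR), two-sample *t*
  and χ² subgroup comparisons, Pearson correlations, multivariate OLS with
  per-covariate partial correlations `r_partial = t/√(t² + df)` and adjusted
  R², the ICC(2,1) absolute-agreement intraclass correlation, and
  Bland–Altman 95% limits of agreement.

Because no patient data ship with the package, a first-class synthetic-data
module generates (a) chest-CT phantoms with two ellipsoidal lungs and known
fibrotic HU content and (b) patient cohorts drawn from a Gaussian copula with
SSc-ILD-like marginals and a calibrated correlation structure, so every
pipeline stage is testable end to end.

## Worked example

```python
from fibroscore.synthetic import PhantomSpec, generate_phantom
from fibroscore.segmentation import segment_lungs
from fibroscore.cam import cam_score

spec = PhantomSpec(design_fibrotic_fraction=0.13, seed=42)
volume, truth = generate_phantom(spec)
mask = segment_lungs(volume)
result = cam_score(volume, mask)
print(f"lung voxels: {mask.count()}")
print(f"fibrosis: {result.fibrosis_pct:.1f}%  (ground truth {100*truth.realized_fibrotic_fraction:.1f}%)")
print(f"lung volume: {result.total_lung_volume_ml:.0f} ml")
```

prints

```
lung voxels: 111424
fibrosis: 12.6%  (ground truth 12.6%)
lung volume: 111 ml
```

The phantom was built with a 13% design fibrotic fraction; the realized
fraction (12.6%) is slightly lower because a small share of fibrotic draws
from Normal(−600, 50) falls below the −700 HU cut, and the segmented-lung
score recovers it to within the segmentation edge voxels (here exactly, to
one decimal). The same pipeline runs on real data from a DICOM series or
NIfTI volume:

```
fibroscore segment --in series_dir/ --out mask.nii.gz
fibroscore cam --in series_dir/ --mask mask.nii.gz --out cam.json
fibroscore warrick --findings findings.csv --out scores.csv
fibroscore cohort-stats --in cohort.csv --report-dir reports/
```

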