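# petrad

Fully automatic biological-target-volume (BTV) segmentation and radiomics for
brain amino-acid PET, with longitudinal Δ% features, statistical feature
selection and discriminant classification of treatment response.

## The problem

On ¹¹C-methionine (¹¹C-MET) PET, brain metastases appear as hyperintense foci
against low cortical background. Radiomics studies need the metabolically
active tumour extent — the BTV — delineated reproducibly, but manual
contouring on low-resolution, noisy PET is operator-dependent. `petrad`
implements a fully automatic pipeline for this setting:

1. **Segmentation.** The volume is converted to body-weight SUV (g/ml). The
   global SUV maximum seeds a 26-connected region growing (≥ 40 % of the seed
   value) that yields a rough in-plane estimate; a *localized region-based
   active contour* (level set with a local Chan–Vese energy: at each contour
   point the mean SUV inside and outside the curve is compared within a ball
   of radius *r* = 5 mm, plus curvature regularization) refines it. Each
   refined slice initializes its neighbours; propagation stops at a
   *disease-free slice* (empty/tiny contour, or interior mean not convincingly
   above the slice background). Lesions are delineated iteratively in
   decreasing SUVmax order — the first BTV always contains the global maximum —
   until the next candidate seed falls below 2 g/ml; multiple lesions raise a
   warning (healthy foci above threshold may be false positives).
2. **Radiomics.** 108 features per lesion: 49 first-order SUV indices
   (min/max/mean, variance, skewness/kurtosis and bias-corrected forms, TLG,
   metabolic volume, histogram entropy, SULpeak, mesh surface area,
   asphericity `A = (S³/36πV²)^{1/3} − 1`, surface-restricted SUV statistics
   in four surface definitions, and eight product features) plus 59 texture
   features from nine parent matrices (co-occurrence, run length, NGTDM,
   size-zone, normalized co-occurrence, texture spectrum, texture feature
   coding, its co-occurrence, and grey-level dependence) built on a 64-level
   quantized grid with 26-voxel connectivity.
3. **Longitudinal change.** Per-feature
   `Δ(%) = 100 · (follow-up − baseline) / baseline`.
4. **Selection.** Correlation-matrix de-duplication (|r| > 0.9 keeps the
   group member with the best point-biserial correlation against the binary
   outcome), then thresholding at |r_pb| > 0.25 with per-feature ROC AUC and
   DeLong 95 % CI.
5. **Classification.** Two-class linear discriminant analysis (pooled
   covariance, empirical priors) under stratified k-fold cross-validation
   (k = 5); pooled out-of-fold sensitivity, specificity, precision, NPV,
   error, accuracy, and the ROC/AUC of the pooled posterior probability.

No clinical data ship with the package: the `phantom` module generates
ground-truthed synthetic inputs (blurred noisy spheres on the clinical
1.17 × 1.17 × 3.27 mm grid, and labelled feature cohorts with planted
effects), so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import petrad as pr

vol, truth = pr.sphere_phantom(radius_mm=8.0, peak_suv=6.0,
                               background=0.5, fwhm_mm=5.0)
lesions = pr.segment_all(vol)
m = lesions.masks[0]
dice = 2 * np.sum(m.voxels & truth.voxels) / (m.voxels.sum() + truth.voxels.sum())
print(f"lesions found: {len(lesions)}")
print(f"SUVmax: {m.suv_max:.2f} g/ml   volume: {m.volume_ml:.2f} ml   "
      f"Dice vs truth: {dice:.3f}")

fv = pr.extract_features(vol, m, sul_vol=vol)
for name in ("suv_mean", "suv_tlg", "suv_asphericity_2", "glcm_entropy"):
    print(f"{name:24s} {fv[name]:10.4f}")
```

prints

```
lesions found: 1
SUVmax: 5.98 g/ml   volume: 2.49 ml   Dice vs truth: 0.907
suv_mean                     3.9561
suv_tlg                      9.8636
suv_asphericity_2           -0.0012
glcm_entropy                 9.0721
```

One lesion is found (its SUVmax just below the simulated 6 g/ml peak because
of the 5 mm PSF), the automatic contour overlaps the true 8 mm sphere with
Dice 0.91, and the extracted vector carries all 108 registry features — the
near-zero asphericity and the TLG ≈ mean × volume are what a blurred sphere
should produce.

The same stages are available as a CLI:
`petrad phantom|cohort|segment|extract|delta|select|classify|run`
(see `petrad <cmd> --help`; `run` chains the stages from a YAML config and
writes per-stage manifests).

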