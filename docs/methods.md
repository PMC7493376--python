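# Methods

This note records the models, numerical choices and open-design decisions
behind `petrad`, and what the synthetic-data tests do and do not demonstrate.

## Quantitative units

Activity concentration (Bq/ml) is converted to the body-weight standardized
uptake value, SUV = activity / (injected dose / body weight), stored in g/ml.
Decay correction is assumed already applied by the scanner, as is standard for
reconstructed DICOM PET; `decay_correct` applies it explicitly when needed
(¹¹C half-life 20.4 min — the decay-reference convention is deliberately a
caller-visible flag rather than a hidden assumption). SUL rescales SUV by
LBM/weight with the James (1976) lean-body-mass formula (male
`1.10W − 128(W/H)²`, female `1.07W − 148(W/H)²`; W kg, H cm), the classical
convention in PET quantification. Grids use axis order (x, y, z) with z the
slice axis, 0-based indices, spacing in mm; no resampling to isotropic voxels
is performed, so the anisotropy of clinical brain PET (≈1.17 × 1.17 × 3.27 mm)
is carried through every computation.

## Automatic segmentation

**Seeding.** The global SUV maximum is the target seed; ties break at the
lowest linear index so results are reproducible. Already-segmented lesions
(dilated by one voxel) are excluded from later seed searches; voxel values are
never altered (no inpainting).

**Initialization.** 26-connected region growing at ≥ 40 % of the seed SUV —
the standard PET rough-delineation level; the result only initializes the
contour, so the exact fraction is uncritical (config: `region_grow_fraction`).
Its in-plane component and a 2-voxel-dilated bounding box define the working
region; a region touching the volume border raises a truncation warning.

**Localized active contour.** A level set on each slice evolves under the
localized uniform-modelling (local Chan–Vese) energy: for narrow-band points
the force is `(I − u)² − (I − v)²`, where `u`/`v` are the mean SUV inside/
outside the current curve restricted to a disk of radius `local_radius_mm`
(default 5 mm — about one PSF FWHM, so the statistics are local enough to
track blurred boundaries but average over noise), normalized by its band
maximum, plus `curvature_weight` (default 0.2) times the level-set curvature.
Time step 0.45, signed-distance reinitialization every 20 iterations, at most
300 iterations per slice; convergence is declared when fewer than 0.5 % of
narrow-band voxels change side over 10 consecutive iterations. All defaults
are config-surfaced (`LacParams`); none are claimed to reproduce any clinical
implementation exactly.

**Slice propagation and the disease-free stop.** The seed slice's refined
mask, dilated by one voxel, initializes the superior neighbour, and so on
(likewise inferiorly), letting the contour widen or tighten slice by slice. A
slice is *disease-free* — terminating propagation in that direction — when the
refined contour is empty, smaller than 2 voxels, or not convincingly hotter
than background. The intensity test ORs two conditions:

* absolute: interior mean < 1.5 × the slice background (median SUV outside the
  dilated initialization box);
* lesion-relative: interior mean < background + 0.4 × (seed SUV − background).

The relative test exists because residual PSF blur from an adjacent diseased
slice scales with lesion brightness: on high-contrast phantoms the blur tail
one slice beyond the true extent reaches ≈3 × background, so an absolute
multiple alone either admits tail slices (at 1.5×) or cuts genuinely dim
slices of low-contrast lesions (at larger multiples). 0.4 mirrors the
40 %-of-max initialization convention. Both factors are `LacParams` fields.

**Multi-lesion loop.** Segment, exclude, re-seed, and stop when the candidate
seed SUV < 2 g/ml (the conventional malignancy floor for this tracer); with
more than one lesion a warning is emitted since healthy foci above the floor
can be false positives. Every step is deterministic: identical inputs give
identical masks.

## Radiomics features

In-mask SUVs are binned into 64 equal-width levels between the lesion min and
max (the max maps to the top level; a constant lesion maps to level 1, and its
skewness/kurtosis are defined as 0 rather than NaN so constant phantoms stay
usable). Directional matrices pool the 13 unique distance-1 offsets of the
26-neighbourhood before normalization; only in-mask pairs/neighbourhoods
contribute. Entropies are log₂. Where the literature leaves an index form
ambiguous, the definition is fixed in the module docstrings
(`features/texture.py`, `features/intensity.py`, registry in
`features/registry.py`) and every family is verified against an independent
brute-force enumeration in the test suite; the non-obvious choices:

* *Normalized co-occurrence*: rows scaled to unit sum, then the matrix to unit
  sum, before the six indices.
* *Texture spectrum*: He–Wang ternary units on in-plane 3×3 neighbourhoods
  (their original 2D definition; all other families are 3D);
  black–white symmetry compares the spectrum to its intensity-inverted mirror
  (unit n ↔ 6560 − n).
* *Texture feature coding*: per voxel, the four opposite-neighbour pairs are
  classed flat/monotone/convex from their two first differences and summed to
  a 0–8 code — a function of level differences only, hence invariant to
  uniform level shifts and to in-plane 90° rotation; the coded map feeds 4
  histogram indices and 8 co-occurrence indices (the registry keeps exactly 8,
  the count consistent with the 108-feature total).
* *Dependence matrix*: dependence = 1 + number of equal-level 26-neighbours
  (tolerance 0).
* *NGTDM*: coarseness uses ε = 10⁻⁶ and is capped at 10⁶ (the cap value a
  constant lesion attains exactly).
* *Surface definitions 1–4*: mask voxels with (1) a face-connected background
  neighbour, (2)/(3) voxels removed by erosion with the 18-/26-connected
  structuring element, (4) voxels traversed by the marching-cubes isosurface.
  Asphericity 1/2/3 use the exposed-face area, the mesh area, and the
  26-surface voxel count × mean face area respectively. Product features use
  the mesh surface area and asphericity 2.
* *Mesh extraction*: marching cubes on the mask after isotropic 1 mm Gaussian
  smoothing — a binary isosurface overestimates a digitized sphere's area by
  ~14 % (staircase bias), while smoothing in voxel units would over-erode
  along the thick slice axis; 1 mm brings the r = 8 mm sphere's area within
  ~1 % of 4πr².
* *SULpeak*: maximal mean SUL in a 1 ml sphere centred on an in-mask voxel;
  the sphere may extend outside the mask (PERCIST convention) and is clipped
  to the grid. SUL-based indices are NaN (with a logged reason) when no SUL
  volume is supplied.

Δ% features follow `100 (post − base)/base` per feature; a zero baseline gives
NaN with a logged feature name, and such features are dropped from selection
when more than 20 % missing (pairwise-complete correlations otherwise).

## Feature selection

Both steps use absolute correlations: anti-correlated duplicates carry the
same information, and strongly negative feature–outcome association is as
useful as positive. De-duplication walks features in registry order, keeps the
best-|r_pb| member of each |r| > 0.9 group (ties keep the earlier feature), and
iterates to a fixed point, so survivors are pairwise ≤ 0.9 and the outcome is
independent of row order. Thresholding keeps survivors with |r_pb| > 0.25 and
reports each one's univariate AUC with a DeLong 95 % CI. Iteration order and
signed-vs-absolute choices are surfaced in `SelectionConfig` and the audit
trail. The 0.9/0.25 defaults are dataset-calibrated working points, not
universal constants.

## Classification

Two-class LDA with pooled within-class covariance (n − 2 denominator),
empirical priors, posterior threshold 0.5. When the pooled covariance is
near-singular (condition number > 10¹⁰ — unavoidable with small cohorts or
duplicated columns) a ridge of 10⁻⁶ · trace/p is added to the diagonal and
logged. Folds are stratified (class proportions within one member per fold)
and depend only on (labels, k, seed); k defaults to 5 with a `--k-sweep`
option. Metrics come from the *pooled* out-of-fold confusion matrix — pooling
also yields the single ROC/AUC (DeLong CI) per experiment — with per-fold
metrics retained in the report, since fold-averaging is the other defensible
aggregation.

## Synthetic data: what it shows and what it does not

PET phantoms rasterize analytic spheres/ellipsoids with 3× supersampling
(partial volume at boundaries), convolve with a Gaussian PSF (default FWHM
5 mm), and add Gaussian or scaled-Poisson voxel noise; ground truth is the
pre-blur indicator, i.e. segmentation is judged against the true biological
extent. Default lesions sit on the clinical grid with peak SUV 3–10 g/ml on a
0.5 g/ml background, the contrast regime of methionine-avid metastases.
Feature cohorts are class-conditional unit-variance Gaussians with planted
standardized mean effects and latent-factor correlated blocks.

Phantoms exercise partial volume, blur, noise and anisotropy, but not scatter,
reconstruction artifacts, heterogeneous uptake, irregular lesion shape or
patient motion; Gaussian cohorts have none of the skew or heavy tails of real
radiomics features. Passing tests therefore demonstrate correctness of the
algorithms under their stated model — Dice ≥ 0.9 across radii 6–15 mm at
≥ 5:1 contrast, exact oracle agreement of every texture family, recovery of
planted effects — not clinical performance, which the private-cohort results
this pipeline is designed for must establish separately.

Problem sizes in the test suite and acceptance script (64–80 voxel grids,
5 radii, 20 selection/classification replicates, 200 permutations) were chosen
as the smallest sizes at which the checked statistics are stable.

## Known limitations

* Single-timepoint pairs only for Δ%; no time-normalized rates.
* The LAC is slice-wise 2D with inter-slice coupling through initialization,
  not a full 3D level set.
* No IBSI-certified feature definitions; where conventions diverge, the
  registry docstrings are the normative definition.
* LDA only (no QDA/SVM baselines); no nested CV for threshold tuning.
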