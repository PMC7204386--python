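# Methods

## Problem setting

Neurodegeneration in Alzheimer's disease changes the shape of brain
structures years before dementia: gray and white matter and the temporal
and parietal lobes lose volume, cortical ribbons thin, and the eroded
surfaces of atrophic structures become more convoluted. `neuromorph`
quantifies these changes on segmented 3D masks with four per-structure
biomarkers, screens them with nonparametric three-class statistics
(healthy controls vs. mild cognitive impairment vs. Alzheimer's dementia),
and evaluates their joint discriminative power with a fixed-design random
forest. Because clinical imaging archives are access-restricted, every
stage is validated against synthetic voxel phantoms and synthetic cohorts
whose ground truth is analytic.

## Image-derived biomarkers

All metrics operate on binary masks on a 1 mm isotropic lattice. Scanner
data are typically anisotropic (e.g. 1.2 × 0.93 × 0.93 mm), so volumes are
first resampled with B-spline interpolation. Labels cannot be interpolated
directly — spline blending of label ids manufactures ids that never
existed — so each label is interpolated as an indicator field and the
output voxel takes the argmax (ties to the lowest id). Resampling happens
before parcellation-based masking; the choice is recorded in the output
config.

**Volume** V = n · (voxel volume), with n the voxel count of the mask.
**Normalized volume** NV = n / ICV, where the intracranial volume is the
summed voxel counts of gray matter, white matter and CSF. The definition
is deliberately additive: if segmentation masks overlap, the overlap is
counted once per mask and a warning is emitted, rather than silently
unioning.

**Discrete compactness** DC = (n − A/6) / (n − n^(2/3)), where A is the
number of voxel faces exposed to background under 6-connectivity
(A = 6n − 2·(face-adjacent pairs)). The numerator counts contact faces in
units of whole voxels; the denominator is the contact count of the most
compact arrangement of n voxels, a solid cube. DC is exactly 1 for solid
cubes, exactly 0 for face-disconnected scatter, and is invariant to
translation and lattice-exact rotation. For n = 1 the expression is 0/0;
a lone voxel has no contacts, so DC = 0 by convention. Face counts require
an isotropic lattice (enforced); the face-area factor then cancels and
both n and A can stay as plain counts.

**Sum-of-angles tortuosity** TR is measured on the centerline skeleton:
the mask is thinned with 3D topology-preserving medial-axis thinning
(Lee's method), the skeleton voxels form a 26-connectivity graph over
their physical centers, and the graph is decomposed into maximal simple
paths terminating at endpoints (degree 1) or junctions (degree ≥ 3), each
edge in exactly one path. For an ordered path P_0…P_{N−1} the in-plane
turning angle at P_k is the angle between the difference vectors
(P_k − P_{k−1}) and (P_{k+1} − P_k); angles are summed for k = 1…N−3 and

    TR = Σ angles / Σ |P_k − P_{k−1}|   [rad/mm],

with both sums aggregated over all paths of a structure (short paths
contribute length but no angles; the eligibility cutoff is N ≥ 4,
matching the summation window). Torsion is deliberately excluded — for
tubular structures measured from images it adds noise without
discriminative value — so the per-point total angle reduces to the plane
angle. Aggregating over branches keeps TR the structure-level ratio
"total turning / total length"; a single-path mode falls out naturally
when the skeleton is unbranched.

Two deliberate interpretation points. First, the turning angle is
computed from consecutive difference vectors (the discrete tangent), the
standard sum-of-angles formulation; a published variant states the
operands as two-column coordinate arrays, which is not internally
consistent and is not what an angle between consecutive triads can mean
geometrically. Second, the k = 1…N−3 window drops the last interior angle
of each path (a torsion-era convention); the `all_interior_angles` config
flag enables the N−2 variant for sensitivity analysis, default off. Under
the default window, path reversal can change TR by at most the dropped
angle over the path length — the property tests assert exactly that bound.

Useful exact properties: scaling coordinates by s leaves the angle sum
unchanged and multiplies length by s, so TR(s·P) = TR(P)/s; for a densely
sampled curve the angle sum converges to the total curvature ∫κ ds, so an
arc of radius r has TR → 1/r and a helix with radius r and rise c per
radian has TR → r/(r² + c²).

### Skeleton smoothing and discretization bias

Voxel skeletons are stair-stepped: each lattice step turns by 45–90°, so
the raw angle sum of a digitized smooth curve is dominated by quantization
(a voxelized 20 mm-radius arc measures ≈ 0.31 rad/mm against a true 0.05).
`smooth_path` applies a centered moving average with a symmetric,
end-shrinking window, endpoints preserved exactly; window 1 (the default)
is the identity, so the published formula applies to raw skeletons unless
smoothing is explicitly configured and logged. For phantom validation we
use window 11 at 1 mm spacing — a ~10 mm smoothing scale, comfortably
above the quantization wavelength and below the smallest radius of
curvature of interest (≥ 20 mm) — which recovers the arc phantom's
curvature within ~10%. Rankings across radii (the quantity screening
actually uses) are preserved under any fixed window: measured TR is
strictly monotone in true curvature in the discretization-bias report
(`voxelize_and_measure`). Comparative use across subjects processed with
one config is therefore sound even where the absolute value carries
discretization bias.

Components below 27 voxels (a 3³ cube) are removed before skeletonization,
mirroring the isolated-dot cleanup of atlas-based parcellation pipelines.

## Statistical screening

Each feature is tested with a Kruskal–Wallis omnibus test across the three
classes (midranks, tie correction, chi-square approximation with 2 df) and
with two-sided Mann–Whitney U tests for the three class pairs. The
post-hoc tests run unconditionally so the screening table always reports
every pairwise column. Significance uses strict p < 0.05 and raw
(uncorrected) p-values by default, with Holm or Bonferroni available
across each feature's pairwise family. The Mann–Whitney p-value is exact
by enumeration for combined samples ≤ 12 without ties, otherwise the
normal approximation with tie and continuity correction — at the design's
n = 40 per class the approximation is accurate to well below the decision
threshold.

`screen_features` removes an entire feature *block* (e.g. the plasma
markers) when none of its members reaches omnibus significance; the image
block and the cognitive surrogate are protected pass-throughs. With three
truly null features tested at α = 0.05 the block survives by chance in
≈ 14% of cohorts — the calibration tests assert the drop rate accordingly
rather than demanding unanimity.

## Classification harness

The feature vector is assembled from named blocks: five image metrics
(V, NV, DC, CT, TR) × six structures (GM, WM, RTL, LTL, RPL, LPL) = 30
image columns; the post-screening biochemical pair {tau_csf, abeta42_csf};
and MMSE as the single cognitive surrogate. CDR defines the class labels
and is never a feature. Column order is deterministic (metric-major,
fixed structure order). The six standard combinations have 24, 30, 26,
32, 27 and 33 columns; the with/without-tortuosity pairing of those
combinations is the harness's headline comparison and is emitted as a
delta table.

The forest is fixed by design: 150 trees, maximum depth 8, minimum split
2, Gini impurity (1 − Σ p_j²), bootstrap resampling per tree, √(n_features)
candidates per split (the conventional default where the design is
otherwise silent), and a required seed. Evaluation is stratified 10-fold
cross-validation on the training cohort (120 subjects, 40 per class →
folds of 12 with 4 per class) reported as mean ± SD, followed by a single
fit on the full training set evaluated on the untouched holdout (30
subjects, 10 per class) as a 3×3 confusion matrix in fixed HC/MCI/AD
order, plus normalized Gini feature importances. Stratification is implied
by the balanced design even though not stated by it.

## Synthetic data

**Tube phantoms** sweep a tube of radius ≥ 2·spacing along a parametric
curve (line, arc, helix, sinusoid) and voxelize it directly on the
isotropic lattice (decoupling metric validation from resampling). Each
phantom carries its analytic expectation: TR from the closed-form mean
curvature (the sinusoid's by quadrature of the exact curvature integrand,
which has no elementary antiderivative), volume from π r² L.

**Compactness phantoms** pit the faces of a solid cube at seeded,
pairwise non-adjacent face-interior sites; each pit removes one voxel and
adds four exposed faces, so DC decreases strictly with pitting level while
n stays near-constant. Fragmentation triggers a bounded seeded retry.

**Cohorts** draw class-conditional Gaussian features with declared
standardized mean shifts per disease stage (HC → MCI → AD). Directions
follow the disease: V, NV, DC, CT, MMSE and CSF beta-amyloid-42 decrease;
TR and CSF tau increase; the three plasma markers carry no effect, so the
screening stage should remove that block. The default shift is 0.8 SD per
stage — a moderate, clinically plausible separation that leaves class
overlap (holdout accuracy well below ceiling) while keeping ≥ 0.9 power
for the screening tests at n = 40 per class. Per-structure baselines are
scaled slightly (×1.0…1.5) so image columns are not exchangeable. MMSE is
truncated to [0, 30]; NV baselines keep the value inside (0, 1) without
clipping in practice. Default sizes are 40/class training and 10/class
holdout. Generation is bit-reproducible from (spec, seed).

What the cohorts do *not* emulate: correlations between biomarkers (all
features are conditionally independent given class), skewed or
heavy-tailed marginals, measurement noise shared across structures, age
and sex confounding, and the segmentation errors upstream of real
morphometry. Passing recovery tests therefore demonstrates that the
pipeline detects and exploits class-conditional location shifts of the
declared directions — not that it would achieve any particular accuracy
on clinical data.

## Numerical choices and edge cases

- Angle computation clips cosines to [−1, 1] before arccos; triads with a
  zero-length segment are skipped rather than raising.
- TR · skeleton length reproduces the angle sum to 1e−9 (reported fields
  are kept consistent, not recomputed independently).
- DC is validated against [−1e−6, 1 + 1e−6] and warns outside [0, 1]
  rather than clamping.
- Kruskal–Wallis on fully constant data returns (H = 0, p = 1).
- Resampling maps output voxel centers to exact physical positions;
  output shape is round(extent / target) per axis, preserving physical
  extent to within one voxel.
- An empty mask is an error for metrics; a requested label absent from a
  volume yields an empty mask plus a logged warning (a skipped row in the
  extraction command, unless `--strict`).

## Problem sizes used in validation

The test and acceptance workloads are sized for a single CPU: null
calibration uses 2000 Kruskal–Wallis replicates at 3 × 40 and 10–20
random-forest seeds on 120 × 30 noise tables; effect recovery uses 20
seeded cohorts comparing the image-only combinations with and without
tortuosity (the pairing with the largest expected gain); phantom suites
use tubes of radius 3 mm and lengths 20–63 mm. These sizes give stable
medians and rates without burning time on redundant replication.

## Known limitations

- The skeleton-based TR of blob-like (non-tubular) structures depends on
  the medial axis the thinning produces; it is a reproducible descriptor
  of surface convolution rather than a curvature of any single anatomical
  curve.
- Raw (unsmoothed) TR on voxel skeletons is dominated by quantization and
  should be used comparatively, under one fixed config.
- The moving-average smoother shortens paths slightly near high-curvature
  ends (endpoints are pinned), biasing TR of short, strongly curved paths
  downward.
- Holm correction is offered per feature across its three pairwise tests;
  no correction is applied across features, matching the screening
  protocol's raw-p reporting.
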