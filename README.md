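# neuromorph

3D voxel morphometry biomarkers for neurodegeneration studies: per-structure
**volume** (V), **ICV-normalized volume** (NV), **discrete compactness**
(DC) and **sum-of-angles tortuosity** (TR) from segmented brain masks, plus
the statistical screening and random-forest classification harness that
evaluates them — all validated on synthetic voxel phantoms and cohorts with
analytic ground truth.

It is written for neuroimaging researchers who have segmented structure
masks (NIfTI label volumes for gray/white matter and temporal/parietal
lobes) and tabular biomarkers (cortical thickness, CSF/plasma assays,
cognitive scores), and want to quantify shape change across the
healthy-control → mild-cognitive-impairment → Alzheimer's-dementia
spectrum.

## The biomarkers

For a structure mask of *n* voxels on a 1 mm isotropic lattice:

- **V** = *n* · voxel volume; **NV** = *n* / ICV, where the intracranial
  volume is the summed GM + WM + CSF voxel counts.
- **DC** = (*n* − *A*/6) / (*n* − *n*^(2/3)), with *A* the exposed voxel
  faces under 6-connectivity: exactly 1 for a solid cube, exactly 0 for
  face-disconnected scatter.
- **TR** = Σ plane angles / Σ path length (rad/mm) over the ordered paths
  of the medial-axis skeleton, angles summed for k = 1…N−3 per path;
  torsion excluded. A densely sampled arc of radius r measures TR → 1/r.

Screening applies a Kruskal–Wallis omnibus test and pairwise two-sided
Mann–Whitney tests per feature (strict p < 0.05, raw p-values, post hocs
always reported). Classification uses a fixed random forest (150 trees,
depth 8, min split 2, Gini) with stratified 10-fold CV on 120 training
subjects and a 30-subject holdout confusion matrix, over six named feature
combinations (24–33 columns) paired with/without tortuosity.

## Worked example

```bash
python examples/02_tortuosity_phantoms.py
```

```
       curve  analytic TR  measured TR
        line       0.0000       0.0000
    arc r=40       0.0250       0.0364
    arc r=20       0.0500       0.0553
    arc r=10       0.1000       0.1285
```

Tubes of radius 3 mm are voxelized along curves of known curvature,
skeletonized, and measured with the sum-of-angles estimator (smoothing
window 11 to suppress lattice staircase angles). The straight tube
measures 0; curved tubes measure approximately the generating curvature
1/r, with the ordering across radii exact — residual discretization bias
is analyzed in `docs/methods.md`.

Other example scripts cover the shape descriptors
(`01_shape_descriptors.py`), cohort screening (`03_screening.py`) and the
classification suite (`04_classification.py`). The same pipeline is
scriptable from the shell:

```bash
neuromorph run-all --out runs/demo --seed 17     # simulate -> stats -> classify
neuromorph extract-features --volume subject.nii.gz --labels labels.json --out feat/
```

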