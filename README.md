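# condylometry

Volumetry of the mandibular condylar head from CBCT-like voxel data, with
3D cephalometric classification and two-level statistics for paired-condyle
cohorts.

The condylar head remodels throughout life and its volume correlates with
the vertical facial pattern: hyperdivergent subjects and subjects with a
post-rotation growth pattern tend to have smaller condyles. Quantifying
this on CBCT requires a chain of steps that this package implements as a
tested pipeline for orthodontic researchers:

1. **Geometry** — the Frankfurt horizontal is fitted through both porions
   (Po) and both lower orbital points (Or) by total least squares; the
   condylar **cut plane** passes through the pterygoid fovea (FP) parallel
   to Frankfurt and separates the head from the neck.
2. **Segmentation** — voxels in the bone-density window [226, 3071] HU are
   thresholded, the 26-connected component nearest the condylion seed is
   isolated, and voxels on the head side of the cut plane are counted:
   `V = N_voxels · s_x s_y s_z` (default spacing 0.49/0.49/0.5 mm).
3. **Cephalometrics** — ANB (signed, at nasion), the intermaxillary
   divergence angle (Ans–Pns vs. Go–Me, folded to [0°, 90°]) and the total
   gonial angle (Cd–Go vs. Go–Me, in [0°, 180°]), with classification into
   skeletal class (I: ANB ∈ [0°, 4°]), divergence type (normo: [40°, 42°])
   and growth pattern (normal: [115°, 125°]).
4. **Statistics** — the two condyles of a subject are correlated, so
   associations are estimated with random-intercept linear models
   `y_ij = β₀ + Σ β_c x_cij + b_i + ε_ij`, `b_i ~ N(0, τ²)`,
   `ε_ij ~ N(0, σ²)` (REML, Wald 95% CIs), in crude, sex+age-adjusted and
   sex-stratified form; rater reliability uses ICC(A,1)
   (single-measurement, absolute-agreement, two-way model) and study
   planning uses noncentral-t two-sample power.

Patient CBCT data are not distributable, so the package ships synthetic
generators with known ground truth: ellipsoid-head phantoms whose volume
above the cut is the closed-form cap
`V(h) = π a b (2c/3 − h + h³/(3c²))`, and a cohort simulator with the
random-intercept variance structure, a sex effect and linear
covariate–volume relationships.

## Worked example

```python
from condylometry import (PhantomSpec, make_phantom, segment_condylar_head,
                          PowerSpec, two_sample_power)

# a condyle-shaped phantom: ellipsoid head (7 x 7 x 9 mm semi-axes) on a
# neck, scanned at 0.49/0.49/0.5 mm voxels, cut at half-depth
vol, landmarks, truth = make_phantom(PhantomSpec())
seg = segment_condylar_head(vol, landmarks, side="R")
print(f"analytic head volume {truth['analytic_head_volume_mm3']:.1f} mm^3")
print(f"segmented volume     {seg.volume_mm3:.1f} mm^3 ({seg.n_voxels} voxels)")

# protocol power: 850 vs 650 mm^3, SD 250, 20 + 40 subjects
print(f"power {two_sample_power(PowerSpec(850, 650, 250, 20, 40)):.4f}")
```

prints

```
analytic head volume 1558.6 mm^3
segmented volume     1561.6 mm^3 (13008 voxels)
power 0.8193
```

The segmented volume is within 0.2 % of the analytic truth — the residual
is voxelization error at the scanner's spacing — and the planned design
has 82 % power to detect the expected sex difference.

The same chain is available from the shell:

```sh
condylometry simulate --phantom --seed 1 --out-dir demo
condylometry segment --volume demo/phantom.nii.gz --landmarks demo/landmarks.csv \
    --side R --out-json demo/seg.json
condylometry run-study --config study.toml --out-dir out   # full pipeline
```

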