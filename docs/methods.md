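# Methods

## Coordinate contract

All geometry lives in one world frame: RAS-oriented millimetres. A
`VoxelVolume` maps voxel index `(i, j, k)` to the world position of the
voxel *center* through `origin + orientation · diag(spacing) · (i, j, k)`;
landmark files must be expressed in the same frame as the volume they
annotate. NIfTI-1 is the primary on-disk format (its header stores the
affine in 32-bit floats, so geometric round trips are exact to single
precision; the raw+JSON dialect is exact to double precision).

## Planes and angles

The Frankfurt horizontal is defined by four landmarks (Po ×2, Or ×2),
which are never exactly coplanar in practice. It is fitted by total least
squares (smallest singular vector of the centered point matrix), which is
rotation-equivariant, reduces to exact interpolation for coplanar points,
and is unique whenever the points are not collinear. The normal is
oriented away from the mandible (menton on the negative side). The
condylar cut plane copies the Frankfurt normal, passes through the
pterygoid fovea of its side, and is re-oriented so the condylion lies on
the non-negative side; that orientation — not a "z-up" assumption — defines
"head side", so the chain is robust to patient orientation.

Three-dimensional angles are unsigned, but skeletal Class III requires a
signed ANB. The sign is taken from the anterior–posterior ordering of
points A and B along an anterior axis: the component of
N → mid(Ans, Pns) orthogonal to the Frankfurt normal, with a +x fallback
when those landmarks are absent. This reproduces the lateral-cephalogram
sign convention without introducing a 2D projection step.

The divergence angle uses the single mandibular line
mid(Go_R, Go_L) → Me. A per-side alternative (average of two angles) was
considered; the mid-gonion line was chosen because it is one well-defined
line, symmetric in the sides, and agrees with the per-side average to
first order for near-symmetric mandibles. Divergence is folded into
[0°, 90°] (line directions have no sign); the gonial angle is *not*
folded, because the clinically meaningful values are obtuse (≈120°) and a
folded angle would alias post-rotation and horizontal patterns. Coincident
required landmarks raise an error rather than returning NaN.

Classification reads the clinically normal ranges as closed central
intervals — ANB 2 ± 2°, divergence 41 ± 1°, gonial 120 ± 5° — with
boundary values assigned to the central class. The growth label uses the
mean of the two gonial angles when classifying a subject.

## Segmentation and volumetry

Bone is thresholded in the closed window [226, 3071] HU (inclusive at both
ends, matching the closed range clinicians select). Components use
26-connectivity; the component containing (or nearest to, within 25 mm)
the condylion seed is kept — the condylar head spans well under 25 mm, and
the radius prevents silently grabbing the skull base. The head is then the
set of component voxels whose *centers* lie on the non-negative side of
the cut plane (boundary kept), and the volume is the voxel count times the
voxel volume. No partial-volume weighting, smoothing or hole filling is
applied: voxel-center counting is deterministic, orientation-consistent,
and its error against analytic phantoms is measured directly (below).

## Phantoms and what they do (not) show

The phantom models the adult condylar head as an ellipsoid (semi-axes
default 7 × 7 × 9 mm) of 1200 HU on a 0 HU background, with a cylindrical
neck attached strictly below the cut plane. Because no neck voxel center
can survive the clip, the true head volume is the closed-form ellipsoid
cap `π a b (2c/3 − h + h³/(3c²))`, and any discrepancy is voxelization
error of the segmentation chain alone. Landmarks are emitted
co-registered: Cd at the apex, FP on the anterior neck at cut height,
Po/Or spanning a Frankfurt plane of known orientation, Me far inferior.

Two numerical choices matter at clinical voxel sizes. First, the grid is
offset by 0.26 voxel from the geometry's bounding box so no voxel-center
layer falls exactly on the cut plane, where inclusion would depend on
roundoff in the fitted normal. Second, for axis-aligned phantoms the
z-grid is registered so the cut plane bisects a voxel-layer gap; this
makes voxel-center counting a midpoint rule at the cut (second-order
accurate). Without that registration the cut contributes a bias of up to
(cross-section area) × (half spacing) ≈ 4 % for the default head — an
artifact of grid/plane alignment that oblique (rotated) cuts do not show.
With it, phantom volumes agree with the analytic caps to ≤ 0.7 % at
0.49/0.49/0.5 mm and converge as spacing shrinks.

The phantoms validate geometry and counting; they do **not** emulate
cortical/trabecular texture, partial-volume blur at real bone interfaces,
reconstruction artifacts, or landmark placement error. Passing phantom
tests therefore demonstrates correctness of the computational chain, not
clinical segmentation accuracy on patients.

## Cohort simulator

Each subject receives sex, age (N(30, 12²) years, clipped at 18),
and three cephalometric covariates drawn independently:
ANB ~ N(2°, 5²), divergence ~ N(41°, 4²), gonial ~ N(120°, 6²). The SDs
were chosen once so the central-class occupancies match the observed class
sizes in an orthodontic referral population (≈29 % Class I, ≈20 %
normodivergent, ≈60 % normal growth); covariate independence is a
simplifying choice — real vertical covariates are correlated — recorded
here so its consequences (below) are interpretable. Volume follows the
random-intercept model the analysis assumes:

    V = 701 + 141·[male] + Σ_c β_c(sex)·(x_c − center_c) + b_i + ε_ij,

with b_i ~ N(0, 180²), ε ~ N(0, 120²) mm³. Defaults: cohort of 49 F /
24 M; per-sex slopes (F/M) of −1/−38 (ANB), −7/−8 (divergence), −10/−1
(gonial) mm³ per degree — the published study-scale values. τ = 180 and
σ = 120 make the within-class total SD ≈ 240–260 mm³ once covariate and
sex contributions are added, matching the observed dispersion. Volumes are
floored at 1 mm³ (the floor triggers in ≪ 1 % of draws).

`CohortSpec.from_class_means` instead calibrates a common slope from
target per-class mean volumes using truncated-normal tail expectations
(e.g. for divergence with SD 4 the expected offset in a tail class is
±3.85°), anchoring the intercept to the central-class mean. This mode
reproduces requested class means in expectation.

A note on stability of group-mean *orderings*: with 73 subjects and
within-class SD ≈ 240 mm³, the normodivergent middle group (≈15 subjects)
sits only ≈60 mm³ from its neighbours while the standard error of a
group-mean difference is ≈75 mm³, so the full three-way ordering
hypo > normo > hyper reproduces in only roughly half of simulated cohorts
even though it always holds in expectation. Stable per-seed ordering would
require either a several-fold larger cohort or residual noise far below
the observed dispersion; the acceptance suite measures this rate as-is
rather than simulating an unrealistically quiet cohort.

## Statistics

Random-intercept models are estimated by REML (statsmodels `MixedLM`),
the standard estimator for variance components in small cohorts; the
between-subject variance is floored at zero at the REML boundary.
Confidence intervals and p-values are Wald, from the normal
approximation — the default behavior of the commercial mixed-model
commands used in clinical studies — and are anti-conservative only mildly
at 73 subjects (measured coverage ≈ 93–96 % at the nominal 95 %).
Likelihood-ratio p-values were considered and not used; the choice is
documented so results can be checked against any mixed-model
implementation. Sex is coded F = 0, M = 1; categorical fits use indicator
covariates against the reference levels Class I, normodivergent, normal
growth. Strata or covariates that cannot be fitted (fewer than 3
subjects, constant covariate) are reported as unavailable instead of
failing the run.

ICC(A,1) is computed directly from the two-way mean squares,

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

with the F-based confidence interval (Satterthwaite degrees of freedom);
perfect agreement degenerates the interval to the point estimate. The
reliability design mirrors the study's: 3 subjects × 3 raters × 3
sessions, inter-rater ICC on session means, intra-rater ICC per rater.

Two-sample power uses the noncentral t distribution with
`df = n1 + n2 − 2` and noncentrality `|Δ| / (sd √(1/n1 + 1/n2))`; display
rounding is half-up to two decimals.

## Problem sizes and determinism

The validation suite uses phantoms of ~10⁵–10⁶ voxels, 200-replicate
simulation batteries for slope recovery and null calibration, and
100-seed ordering checks — sizes at which Monte-Carlo error is a small
fraction of the tested tolerances. Every generator consumes an explicit
seed (`numpy.random.default_rng`), REML is deterministic, and the pipeline
report serializes with sorted keys, so reruns are byte-identical.

## Known limitations

- DICOM ingestion, rescale slope/intercept handling and de-identification
  are out of scope; volumes enter as NIfTI-1 or raw+JSON.
- Voxel-center counting has no sub-voxel accuracy; at 0.49/0.49/0.5 mm the
  phantom error is a few tenths of a percent, but heads much smaller than
  5 mm semi-axes would need finer grids.
- The condyle-isolation step (seeded connected component) is an
  operationalization of what clinical software does interactively; real
  data with bridging osseous structures inside the HU window could connect
  the condyle to neighbouring bone, which the 25 mm seed radius mitigates
  but does not eliminate.
- The simulator draws covariates independently and shares them across
  sides; it does not model side asymmetry of angles, covariate
  correlation, or measurement error in landmarks.
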