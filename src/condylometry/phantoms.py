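"""Synthetic data: voxel phantoms with analytic truth, and cohort simulation.

The condylar head of an adult is approximately ellipsoidal, so the phantom
models it as an ellipsoid of bone-density HU on a soft-tissue background,
with a cylindrical neck attached strictly below the cut plane. Because the
neck never crosses the cut, the true head volume above the cut at signed
height ``h`` (relative to the head center, along the cut normal) is the
closed-form ellipsoid cap

    V(h) = pi * a * b * (2c/3 - h + h^3 / (3 c^2)),   h in [-c, c],

which isolates voxelization error when validating the segmentation chain.
Landmarks are emitted co-registered with the grid: condylion at the head
apex, the pterygoid fovea on the anterior neck at the cut height, porion
and orbital points spanning a Frankfurt plane of known orientation, and
menton far inferior.

The cohort simulator draws subjects with two condyles each under the
random-intercept model the analysis assumes: a subject-level normal
intercept (SD ``tau``) plus a per-condyle residual (SD ``sigma``), a sex
effect, and linear dependence of volume on the cephalometric covariates
with optionally sex-specific slopes. Defaults reproduce the study's
conditions: 49 female / 24 male subjects, female mean 701 mm^3, sex effect
+141 mm^3, and the published per-sex slopes for ANB, divergence and gonial
angle. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_imaging import LandmarkSet, VoxelVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "analytic_cap_volume",
    "make_phantom",
    "make_bilateral_phantom",
    "simulate_cohort",
    "reference_landmarks",
]

#: Published per-sex slopes (mm^3 per degree), (female, male).
DEFAULT_SLOPES: dict[str, tuple[float, float]] = {
    "anb_deg": (-1.0, -38.0),
    "divergence_deg": (-7.0, -8.0),
    "gonial_deg": (-10.0, -1.0),
}

#: Covariate centers: the clinically normal values of each angle (degrees).
DEFAULT_CENTERS = {"anb_deg": 2.0, "divergence_deg": 41.0, "gonial_deg": 120.0}

#: Covariate SDs chosen so the central-class occupancy matches the study's
#: observed class sizes (~29% Class I, ~20% normodivergent, ~60% normal growth).
DEFAULT_SDS = {"anb_deg": 5.0, "divergence_deg": 4.0, "gonial_deg": 6.0}

#: Half-widths of the central class bands, per covariate.
_BAND_HALFWIDTH = {"anb_deg": 2.0, "divergence_deg": 1.0, "gonial_deg": 5.0}


def analytic_cap_volume(a: float, b: float, c: float, h: float) -> float:
    """Exact volume (mm^3) of the ellipsoid part above height ``h``.

    ``h`` is measured from the center along the c-axis; ``h = -c`` gives the
    full ellipsoid, ``h = 0`` half of it, ``h = c`` zero.
    """
    if not -c <= h <= c:
        raise ValueError(f"cut height {h} outside [-c, c] = [{-c}, {c}]")
    return np.pi * a * b * (2.0 * c / 3.0 - h + h ** 3 / (3.0 * c ** 2))


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of a single condyle phantom.

    ``cut_height`` is the head/neck boundary relative to the head center
    along the cut normal (default ``-c/2``, i.e. the neck joins below the
    equator). ``rotation`` rigidly rotates the whole scene (geometry and
    landmarks) about the head center. When ``shape``/``grid_origin`` are
    omitted the grid is sized to fit the phantom plus ``margin_mm``.
    """

    semi_axes: tuple[float, float, float] = (7.0, 7.0, 9.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cut_height: float | None = None
    neck_radius: float = 4.0
    neck_length: float = 12.0
    bone_hu: float = 1200.0
    background_hu: float = 0.0
    noise_sd: float = 0.0
    spacing: tuple[float, float, float] = (0.49, 0.49, 0.5)
    margin_mm: float = 3.0
    rotation: np.ndarray | None = None
    shape: tuple[int, int, int] | None = None
    grid_origin: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if not 226.0 <= self.bone_hu <= 3071.0:
            raise ValueError(f"bone HU {self.bone_hu} outside the bone window [226, 3071]")
        if self.cut_height is None:
            self.cut_height = -self.semi_axes[2] / 2.0
        c = self.semi_axes[2]
        if not -c <= self.cut_height <= c:
            raise ValueError(f"cut height {self.cut_height} outside [-c, c]")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)
            if self.rotation.shape != (3, 3):
                raise ValueError("rotation must be a 3x3 matrix")


def _register_to_cut(origin_z: float, cut_z: float, sz: float) -> float:
    """Shift ``origin_z`` so voxel-center layers straddle ``cut_z`` evenly."""
    r = (cut_z - origin_z) % sz
    return origin_z + (r - sz / 2.0)


def _phantom_bounds(spec: PhantomSpec, center: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """World-frame AABB (2x3) of the rotated ellipsoid + neck."""
    a, b, c = (s * scale for s in spec.semi_axes)
    h = spec.cut_height * scale
    top = h - spec.spacing[2] / 2.0
    corners = []
    for box in ([[-a, a], [-b, b], [-c, c]],
                [[-spec.neck_radius, spec.neck_radius]] * 2 + [[top - spec.neck_length, top]]):
        for x in box[0]:
            for y in box[1]:
                for z in box[2]:
                    corners.append([x, y, z])
    corners = np.asarray(corners)
    rot = spec.rotation if spec.rotation is not None else np.eye(3)
    world = corners @ rot.T + center
    return np.array([world.min(axis=0), world.max(axis=0)])


def _rasterize(spec: PhantomSpec, grid_origin: np.ndarray, shape: tuple[int, int, int],
               center: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Boolean mask of the (rotated, scaled) ellipsoid head + neck cylinder."""
    sx, sy, sz = spec.spacing
    x = grid_origin[0] + sx * np.arange(shape[0])[:, None, None] - center[0]
    y = grid_origin[1] + sy * np.arange(shape[1])[None, :, None] - center[1]
    z = grid_origin[2] + sz * np.arange(shape[2])[None, None, :] - center[2]
    rot = spec.rotation if spec.rotation is not None else np.eye(3)
    rt = rot.T
    qx = rt[0, 0] * x + rt[0, 1] * y + rt[0, 2] * z
    qy = rt[1, 0] * x + rt[1, 1] * y + rt[1, 2] * z
    qz = rt[2, 0] * x + rt[2, 1] * y + rt[2, 2] * z
    a, b, c = (s * scale for s in spec.semi_axes)
    head = (qx / a) ** 2 + (qy / b) ** 2 + (qz / c) ** 2 <= 1.0
    # neck attached strictly below the cut: its top sits half a voxel under
    # the cut height so no neck voxel center can survive the clip
    top = spec.cut_height * scale - sz / 2.0
    neck = ((qx ** 2 + qy ** 2 <= spec.neck_radius ** 2)
            & (qz <= top) & (qz >= top - spec.neck_length))
    return head | neck


def _phantom_landmarks(spec: PhantomSpec, center: np.ndarray, side: str,
                       scale: float = 1.0) -> dict[str, np.ndarray]:
    a, b, c = (s * scale for s in spec.semi_axes)
    h = spec.cut_height * scale
    return {
        f"Cd_{side}": np.array([0.0, 0.0, c]) + 0.0,   # head apex
        f"FP_{side}": np.array([0.0, spec.neck_radius, h]),  # anterior neck recess
    }


#: Frankfurt-defining and midline landmarks, in the phantom frame (mm,
#: relative to the head center). The four Po/Or points are coplanar at
#: height +10, so the Frankfurt plane's normal is exactly the frame's z-axis.
_FRAME_LANDMARKS = {
    "Po_R": np.array([45.0, -35.0, 10.0]),
    "Po_L": np.array([-45.0, -35.0, 10.0]),
    "Or_R": np.array([38.0, 30.0, 10.0]),
    "Or_L": np.array([-38.0, 30.0, 10.0]),
    "Me": np.array([0.0, 40.0, -70.0]),
}


def make_phantom(
    spec: PhantomSpec, side: str = "R"
) -> tuple[VoxelVolume, LandmarkSet, dict]:
    """Voxelize a single condyle phantom with co-registered landmarks.

    Returns ``(volume, landmarks, truth)`` where ``truth`` records the
    analytic head volume above the cut and the geometry it derives from.
    Raises if an explicitly requested grid does not hold the phantom with
    at least a two-voxel margin.
    """
    if side not in ("R", "L"):
        raise ValueError(f"side must be 'R' or 'L', got {side!r}")
    center = np.asarray(spec.center, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    bounds = _phantom_bounds(spec, center)
    if spec.shape is not None or spec.grid_origin is not None:
        if spec.shape is None or spec.grid_origin is None:
            raise ValueError("shape and grid_origin must be given together")
        shape = tuple(int(s) for s in spec.shape)
        origin = np.asarray(spec.grid_origin, dtype=float)
        hi = origin + spacing * (np.asarray(shape) - 1)
        if np.any(bounds[0] < origin + 2 * spacing) or np.any(bounds[1] > hi - 2 * spacing):
            raise ValueError("phantom exceeds the requested grid (needs a 2-voxel margin)")
    else:
        # sub-voxel offset keeps the grid in generic position: no voxel-center
        # layer falls exactly on the cut plane, where inclusion would hinge on
        # roundoff in the fitted plane normal
        origin = bounds[0] - spec.margin_mm + 0.26 * spacing
        if spec.rotation is None:
            # axis-aligned cut: register the z-grid so the cut plane bisects a
            # voxel-layer gap, making voxel-center counting second-order
            # accurate at the cut (an oblique cut self-averages instead)
            origin[2] = _register_to_cut(origin[2], center[2] + spec.cut_height, spacing[2])
        shape = tuple(np.ceil((bounds[1] + spec.margin_mm - origin) / spacing).astype(int) + 1)

    mask = _rasterize(spec, origin, shape, center)
    values = np.full(shape, float(spec.background_hu))
    values[mask] = float(spec.bone_hu)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = VoxelVolume(values, tuple(spacing), tuple(origin))

    rot = spec.rotation if spec.rotation is not None else np.eye(3)
    offsets = dict(_FRAME_LANDMARKS)
    offsets.update(_phantom_landmarks(spec, center, side))
    lm = LandmarkSet({name: center + rot @ off for name, off in offsets.items()})

    a, b, c = spec.semi_axes
    truth = {
        "analytic_head_volume_mm3": analytic_cap_volume(a, b, c, spec.cut_height),
        "full_ellipsoid_volume_mm3": 4.0 / 3.0 * np.pi * a * b * c,
        "cut_height_mm": spec.cut_height,
        "semi_axes_mm": tuple(spec.semi_axes),
        "side": side,
    }
    return vol, lm, truth


def make_bilateral_phantom(
    spec: PhantomSpec, mirror_offset: float = 25.0, left_scale: float = 1.0
) -> tuple[VoxelVolume, LandmarkSet, dict]:
    """Two mirrored condyle phantoms in one grid.

    The right head sits at ``center + (mirror_offset, 0, 0)``, the left at
    the mirror image; the left head (and its cut height) may be uniformly
    scaled by ``left_scale``. Overlapping phantoms are an error.
    Rotation is not supported for the bilateral pair.
    """
    if spec.rotation is not None:
        raise ValueError("bilateral phantoms do not support a scene rotation")
    if mirror_offset <= 0:
        raise ValueError("mirror_offset must be positive")
    mid = np.asarray(spec.center, dtype=float)
    c_r = mid + np.array([mirror_offset, 0.0, 0.0])
    c_l = mid - np.array([mirror_offset, 0.0, 0.0])
    spacing = np.asarray(spec.spacing, dtype=float)
    b_r = _phantom_bounds(spec, c_r)
    b_l = _phantom_bounds(spec, c_l, scale=left_scale)
    lo = np.minimum(b_r[0], b_l[0]) - spec.margin_mm
    hi = np.maximum(b_r[1], b_l[1]) + spec.margin_mm
    origin = lo + 0.26 * spacing  # generic position, as in make_phantom
    origin[2] = _register_to_cut(origin[2], c_r[2] + spec.cut_height, spacing[2])
    shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 2)

    mask_r = _rasterize(spec, origin, shape, c_r)
    mask_l = _rasterize(spec, origin, shape, c_l, scale=left_scale)
    if np.any(mask_r & mask_l):
        raise ValueError("left and right phantoms overlap; increase mirror_offset")
    values = np.full(shape, float(spec.background_hu))
    values[mask_r | mask_l] = float(spec.bone_hu)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = VoxelVolume(values, tuple(spacing), tuple(origin))

    points = {name: mid + off for name, off in _FRAME_LANDMARKS.items()}
    for name, off in _phantom_landmarks(spec, c_r, "R").items():
        points[name] = c_r + off
    for name, off in _phantom_landmarks(spec, c_l, "L", scale=left_scale).items():
        points[name] = c_l + off
    lm = LandmarkSet(points)

    a, b, c = spec.semi_axes
    truths = {
        "R": {"analytic_head_volume_mm3": analytic_cap_volume(a, b, c, spec.cut_height)},
        "L": {"analytic_head_volume_mm3":
              left_scale ** 3 * analytic_cap_volume(a, b, c, spec.cut_height)},
    }
    return vol, lm, truths


@dataclass
class CohortSpec:
    """Parameters of the simulated study cohort.

    ``slopes`` maps covariate column → slope in mm^3 per degree, either a
    scalar (common to both sexes) or a ``(female, male)`` pair.
    ``intercept`` is the expected female volume at the covariate centers;
    ``sex_effect`` is added for males. ``tau``/``sigma`` are the
    between-subject and within-subject (per-condyle) SDs in mm^3.
    """

    n_female: int = 49
    n_male: int = 24
    intercept: float = 701.0
    sex_effect: float = 141.0
    slopes: Mapping[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES))
    covariate_centers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CENTERS))
    covariate_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    tau: float = 180.0
    sigma: float = 120.0
    age_mean: float = 30.0
    age_sd: float = 12.0
    age_min: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female + self.n_male <= 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("subject counts must be non-negative")
        if self.tau < 0 or self.sigma < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(s < 0 for s in self.covariate_sds.values()):
            raise ValueError("covariate SDs must be non-negative")

    def slope_for(self, covariate: str, sex: str) -> float:
        s = self.slopes.get(covariate, 0.0)
        if isinstance(s, (tuple, list)):
            return float(s[0] if sex == "F" else s[1])
        return float(s)

    @classmethod
    def from_class_means(
        cls,
        divergence_means: tuple[float, float, float] | None = None,
        growth_means: tuple[float, float, float] | None = None,
        skeletal_means: tuple[float, float, float] | None = None,
        **overrides,
    ) -> "CohortSpec":
        """Calibrate linear slopes from target per-class volume means.

        Each triple is ordered (below-band class, central class, above-band
        class) — e.g. divergence ``(hypo, normo, hyper)``. Under the normal
        covariate model, the expected covariate offset in a tail class is
        ``±sd * phi(w/sd) / (1 - Phi(w/sd))`` for band half-width ``w``, so
        the slope reproducing the outer-class mean gap is
        ``(above - below) / (2 * offset)``. Covariates without a supplied
        triple get slope 0; the intercept is anchored so the central-class
        expectation matches the mean of the supplied central values.
        """
        base = cls(**{k: v for k, v in overrides.items()
                      if k not in ("slopes", "intercept")})
        slopes: dict[str, float] = {k: 0.0 for k in base.covariate_centers}
        centrals = []
        for cov, triple in (("divergence_deg", divergence_means),
                            ("gonial_deg", growth_means),
                            ("anb_deg", skeletal_means)):
            if triple is None:
                continue
            below, central, above = triple
            sd = base.covariate_sds[cov]
            w = _BAND_HALFWIDTH[cov]
            z0 = w / sd
            offset = sd * sps.norm.pdf(z0) / sps.norm.sf(z0)
            slopes[cov] = (above - below) / (2.0 * offset)
            centrals.append(central)
        p_m = base.n_male / (base.n_female + base.n_male)
        intercept = (float(np.mean(centrals)) - p_m * base.sex_effect
                     if centrals else base.intercept)
        kw = dict(overrides)
        kw["slopes"] = slopes
        kw["intercept"] = kw.get("intercept", intercept)
        return cls(**kw)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table (one row per condyle) under ``spec``.

    Covariates are drawn independently per subject and shared by both
    sides; the volume is linear in the centered covariates with a
    subject-level random intercept and a per-condyle residual. Volumes are
    floored at 1 mm^3. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_female + spec.n_male
    sex = np.array(["F"] * spec.n_female + ["M"] * spec.n_male)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), spec.age_min, None)
    covs = {c: rng.normal(spec.covariate_centers[c], spec.covariate_sds[c], n)
            for c in spec.covariate_centers}
    b = rng.normal(0.0, spec.tau, n)
    eps = rng.normal(0.0, spec.sigma, (n, 2))
    rows = []
    for i in range(n):
        mu = spec.intercept + (spec.sex_effect if sex[i] == "M" else 0.0) + b[i]
        for c, values in covs.items():
            mu += spec.slope_for(c, sex[i]) * (values[i] - spec.covariate_centers[c])
        for j, side in enumerate(("R", "L")):
            rows.append({
                "subject_id": f"S{i:03d}",
                "side": side,
                "volume_mm3": max(mu + eps[i, j], 1.0),
                "sex": sex[i],
                "age_years": age[i],
                **{c: covs[c][i] for c in covs},
            })
    return pd.DataFrame(rows)


def reference_landmarks() -> LandmarkSet:
    """A full, anatomically plausible landmark set (mm, mid-cranial origin).

    Intended for tests and demonstrations of the angle operations; the
    values are synthetic, not patient-derived.
    """
    pts = {
        "N": (0.0, 85.0, 55.0),
        "A": (0.0, 92.0, 18.0),
        "B": (0.0, 88.0, -15.0),
        "Ans": (0.0, 90.0, 20.0),
        "Pns": (0.0, 42.0, 22.0),
        "Me": (0.0, 80.0, -45.0),
        "Go_R": (45.0, 0.0, -35.0),
        "Go_L": (-45.0, 0.0, -35.0),
        "Cd_R": (52.0, -5.0, 15.0),
        "Cd_L": (-52.0, -5.0, 15.0),
        "Po_R": (60.0, -10.0, 18.0),
        "Po_L": (-60.0, -10.0, 18.0),
        "Or_R": (35.0, 65.0, 18.0),
        "Or_L": (-35.0, 65.0, 18.0),
        "FP_R": (49.0, 0.0, 5.0),
        "FP_L": (-49.0, 0.0, 5.0),
    }
    return LandmarkSet({k: np.asarray(v) for k, v in pts.items()})
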