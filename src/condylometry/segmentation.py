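"""Condylar-head segmentation: HU threshold, seeded component, plane clip.

The protocol mirrors routine CBCT bone volumetry: voxels in the bone
density window (226–3071 HU by default, inclusive at both ends) are
thresholded, the 26-connected component nearest a seed point (condylion,
falling back to a point above the pterygoid fovea) isolates the condyle,
and the head is separated from the neck by keeping only voxels on the
non-negative side of the cut plane — the plane through the pterygoid fovea
parallel to the Frankfurt horizontal, oriented head-side positive.

Volumes are voxel-center counts times the voxel volume; no partial-volume
weighting or morphological post-processing is applied, so the result is
exactly reproducible from the logged plane equation and thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cephalometry import Plane, condylar_cut_plane, frankfurt_plane
from .io_imaging import LandmarkSet, VoxelVolume

__all__ = [
    "CondyleSegmentation",
    "SegmentationError",
    "threshold_mask",
    "seeded_component",
    "clip_above_plane",
    "segment_condylar_head",
]

#: Bone-density window (HU), inclusive.
DEFAULT_HU_RANGE = (226.0, 3071.0)

#: How far (mm) from the seed point a true voxel may be before we refuse to
#: guess which structure was meant. The condylar head spans well under 25 mm.
SEED_SEARCH_RADIUS_MM = 25.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """A segmentation stage failed; the message names the stage."""


@dataclass
class CondyleSegmentation:
    """Result of :func:`segment_condylar_head` for one side."""

    side: str
    mask: np.ndarray
    volume_mm3: float
    cut_plane: Plane
    hu_range: tuple[float, float]
    n_voxels: int
    seed_world: np.ndarray


def threshold_mask(vol: VoxelVolume, lo: float, hi: float) -> np.ndarray:
    """Boolean grid: true where ``lo <= HU <= hi`` (inclusive both ends)."""
    if lo > hi:
        raise ValueError(f"threshold lower bound {lo} exceeds upper bound {hi}")
    return (vol.values >= lo) & (vol.values <= hi)


def seeded_component(
    mask: np.ndarray,
    seed: np.ndarray,
    vol: VoxelVolume,
    max_distance_mm: float = SEED_SEARCH_RADIUS_MM,
) -> np.ndarray:
    """The 26-connected component of ``mask`` containing (or nearest) ``seed``.

    ``seed`` is a world point (mm). If its voxel is false, the nearest true
    voxel within ``max_distance_mm`` is used instead; no true voxel within
    that radius is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.values.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.values.shape}")
    seed = np.asarray(seed, dtype=float).reshape(3)
    idx = vol.world_to_nearest_index(seed)
    inside = np.all((idx >= 0) & (idx < mask.shape), axis=-1)
    if inside and mask[tuple(idx)]:
        target = tuple(idx)
    else:
        true_idx = np.argwhere(mask)
        if true_idx.size == 0:
            raise ValueError(
                f"no voxel in the mask within {max_distance_mm} mm of seed {seed}"
            )
        d = np.linalg.norm(vol.index_to_world(true_idx) - seed, axis=1)
        best = int(np.argmin(d))
        if d[best] > max_distance_mm:
            raise ValueError(
                f"nearest masked voxel is {d[best]:.1f} mm from seed {seed}, "
                f"beyond the {max_distance_mm} mm search radius"
            )
        target = tuple(true_idx[best])
    labels, _ = ndimage.label(mask, structure=_CONN26)
    return labels == labels[target]


def _signed_distance_grid(vol: VoxelVolume, plane: Plane) -> np.ndarray:
    """Signed distance of every voxel center from ``plane``, via the affine.

    The distance is affine in the index, so it is assembled from three 1D
    arrays instead of materializing the full coordinate grid.
    """
    m = vol.orientation @ np.diag(vol.spacing)
    coeff = plane.n @ m  # distance increment per unit index step, per axis
    base = float((np.asarray(vol.origin) - plane.p0) @ plane.n)
    nx, ny, nz = vol.values.shape
    di = coeff[0] * np.arange(nx)[:, None, None]
    dj = coeff[1] * np.arange(ny)[None, :, None]
    dk = coeff[2] * np.arange(nz)[None, None, :]
    return base + di + dj + dk


def clip_above_plane(mask: np.ndarray, plane: Plane, vol: VoxelVolume) -> np.ndarray:
    """Keep only mask voxels whose center has signed distance ≥ 0.

    The plane must be oriented head-side positive (the cut-plane contract);
    voxel centers exactly on the plane are kept.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.values.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.values.shape}")
    return mask & (_signed_distance_grid(vol, plane) >= 0)


def segment_condylar_head(
    vol: VoxelVolume,
    lm: LandmarkSet,
    side: str,
    hu_lo: float = DEFAULT_HU_RANGE[0],
    hu_hi: float = DEFAULT_HU_RANGE[1],
) -> CondyleSegmentation:
    """Full condylar-head protocol for one side.

    Pipeline: Frankfurt plane (Po×2 + Or×2) → cut plane through FP_side →
    HU threshold → seeded 26-connected component (seed = Cd_side, else
    FP_side shifted 10 mm toward the head along the plane normal) → clip at
    the cut plane. ``volume_mm3`` is the kept-voxel count times the voxel
    volume. Stage failures are re-raised as :class:`SegmentationError`
    labeled with the stage name.
    """
    if side not in ("R", "L"):
        raise ValueError(f"side must be 'R' or 'L', got {side!r}")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise SegmentationError(f"stage {name!r}: {exc}") from exc

    frankfurt = stage("frankfurt_plane", frankfurt_plane, lm)
    cut = stage("condylar_cut_plane", condylar_cut_plane, lm, side, frankfurt)
    bone = stage("threshold_mask", threshold_mask, vol, hu_lo, hu_hi)
    cd_name = f"Cd_{side}"
    seed = lm[cd_name] if cd_name in lm else lm[f"FP_{side}"] + 10.0 * cut.n
    comp = stage("seeded_component", seeded_component, bone, seed, vol)
    head = stage("clip_above_plane", clip_above_plane, comp, cut, vol)
    n_voxels = int(head.sum())
    return CondyleSegmentation(
        side=side,
        mask=head,
        volume_mm3=n_voxels * vol.voxel_volume_mm3,
        cut_plane=cut,
        hu_range=(float(hu_lo), float(hu_hi)),
        n_voxels=n_voxels,
        seed_world=np.asarray(seed, dtype=float),
    )
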