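"""Voxel-volume and landmark I/O, and the world-coordinate contract.

Every module in this package works in a single world frame: RAS-oriented,
millimetres. A :class:`VoxelVolume` maps integer voxel indices ``(i, j, k)``
to world positions through an affine built from its spacing, origin and
direction-cosine matrix; the world position of a voxel is the position of
its *center*. Landmark files must be expressed in the same world frame as
the volume they annotate.

Supported on-disk formats:

* volumes — NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel, or a raw+JSON
  dialect (``<stem>.json`` header next to ``<stem>.raw`` little-endian
  voxel data) for environments without NIfTI tooling;
* landmarks — CSV with header ``name,x,y,z`` or a JSON object
  ``{"name": [x, y, z], ...}``.

Hounsfield values are read and written as stored; no rescale slope or
intercept handling is performed (DICOM ingestion is out of scope).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "LandmarkSet",
    "MissingLandmarkError",
    "KNOWN_LANDMARKS",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]

#: Controlled vocabulary of anatomical landmark names. Bilateral points carry
#: an ``_R``/``_L`` suffix. Unknown names are accepted but logged.
KNOWN_LANDMARKS = frozenset(
    {
        "Po_R", "Po_L",      # porion: highest point of the external acoustic meatus
        "Or_R", "Or_L",      # lower orbital point
        "FP_R", "FP_L",      # pterygoid fovea: anterior recess of the mandibular neck
        "Cd_R", "Cd_L",      # condylion: most superior point of the condyle
        "Go_R", "Go_L",      # gonion
        "A", "B", "N",       # maxillary A point, mandibular B point, nasion
        "Ans", "Pns",        # anterior / posterior nasal spine
        "Me",                # menton
    }
)


class MissingLandmarkError(KeyError):
    """A required landmark is absent from a :class:`LandmarkSet`."""

    def __init__(self, missing: Iterable[str]):
        self.missing = tuple(missing)
        super().__init__(f"missing landmark{'s' if len(self.missing) > 1 else ''} "
                         + ", ".join(self.missing))

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass
class VoxelVolume:
    """A 3D scalar grid of Hounsfield values with a voxel→world affine.

    Parameters
    ----------
    values
        3D array of HU values (any numeric dtype; kept as given).
    spacing
        ``(sx, sy, sz)`` voxel edge lengths in mm, all strictly positive.
    origin
        World coordinates (mm) of the *center* of voxel ``(0, 0, 0)``.
    orientation
        3×3 direction-cosine matrix; identity means axis-aligned RAS.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D shape "
                             f"{self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")

    # -- geometry -----------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """4×4 voxel-index → world-mm affine (homogeneous)."""
        a = np.eye(4)
        a[:3, :3] = self.orientation @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World position(s) of voxel center(s) ``idx`` (…×3 array-like)."""
        idx = np.asarray(idx, dtype=float)
        m = self.orientation @ np.diag(self.spacing)
        return idx @ m.T + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel index/indices of world position(s) ``xyz``."""
        xyz = np.asarray(xyz, dtype=float)
        m = self.orientation @ np.diag(self.spacing)
        return (xyz - np.asarray(self.origin)) @ np.linalg.inv(m).T

    def world_to_nearest_index(self, xyz: np.ndarray) -> np.ndarray:
        return np.round(self.world_to_index(xyz)).astype(int)


@dataclass
class LandmarkSet:
    """Named anatomical points in a volume's world frame (mm).

    Names are unique; bilateral pairs (``*_R`` / ``*_L``) must be distinct
    points. Operations declare their required subset via :meth:`require`,
    which fails fast with the list of absent names.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(-1)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector, got {p}")
            clean[str(name)] = p
        self.points = clean
        for name in clean:
            if name not in KNOWN_LANDMARKS:
                logger.warning("landmark %r is not in the controlled vocabulary", name)
        for base in {n[:-2] for n in clean if n.endswith("_R")}:
            r, l = f"{base}_R", f"{base}_L"
            if l in clean and np.array_equal(clean[r], clean[l]):
                raise ValueError(f"bilateral pair {r}/{l} coincide at {clean[r]}")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def require(self, names: Iterable[str]) -> None:
        """Raise :class:`MissingLandmarkError` naming every absent landmark."""
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Return a copy with every point mapped through ``R x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LandmarkSet({n: rotation @ p + translation for n, p in self.points.items()})


# -- volume I/O --------------------------------------------------------------


def write_volume(path: str | Path, vol: VoxelVolume) -> Path:
    """Write ``vol`` to NIfTI-1 (``.nii``/``.nii.gz``) or the raw+JSON dialect.

    The raw dialect is selected by a ``.json`` suffix; voxel data go to the
    sibling ``.raw`` file as little-endian values in C order.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = path.with_suffix(".raw")
        data = np.ascontiguousarray(vol.values)
        header = {
            "shape": list(data.shape),
            "dtype": data.dtype.str.replace(">", "<"),
            "spacing": list(vol.spacing),
            "origin": list(vol.origin),
            "orientation": vol.orientation.tolist(),
            "raw_file": raw.name,
        }
        path.write_text(json.dumps(header, indent=1))
        data.astype(data.dtype.newbyteorder("<")).tofile(raw)
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), vol.affine)
        nib.save(img, str(path))
        return path
    raise ValueError(f"unsupported volume format for {path.name!r} "
                     "(expected .nii, .nii.gz or .json)")


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a volume written by :func:`write_volume` (or any NIfTI-1 file).

    Spacing, origin and orientation are taken from the header; HU values are
    returned unmodified. Non-3D images and non-positive spacings are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if path.suffix == ".json":
        header = json.loads(path.read_text())
        raw = path.parent / header["raw_file"]
        values = np.fromfile(raw, dtype=np.dtype(header["dtype"]))
        values = values.reshape(header["shape"])
        return VoxelVolume(values, tuple(header["spacing"]), tuple(header["origin"]),
                           np.asarray(header["orientation"]))
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D image, got {values.ndim}D in {path.name}")
    affine = img.affine
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in {path.name}: {spacing}")
    orientation = m / spacing
    return VoxelVolume(values, tuple(spacing), tuple(affine[:3, 3]), orientation)


# -- landmark I/O ------------------------------------------------------------


def write_landmarks(path: str | Path, lm: LandmarkSet) -> Path:
    """Write landmarks as ``name,x,y,z`` CSV or a JSON object (by suffix)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({n: p.tolist() for n, p in lm.points.items()}, indent=1))
        return path
    if path.suffix == ".csv":
        df = pd.DataFrame(
            [(n, *p) for n, p in lm.points.items()], columns=["name", "x", "y", "z"]
        )
        df.to_csv(path, index=False)
        return path
    raise ValueError(f"unsupported landmark format for {path.name!r} (expected .csv or .json)")


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (CSV ``name,x,y,z`` or JSON object form).

    Duplicate names and non-numeric coordinates are errors; names outside
    the controlled vocabulary are accepted with a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        if not isinstance(obj, Mapping):
            raise ValueError(f"landmark JSON must be an object, got {type(obj).__name__}")
        return LandmarkSet({str(k): np.asarray(v, dtype=float) for k, v in obj.items()})
    df = pd.read_csv(path)
    expected = ["name", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"landmark CSV must have columns {expected}, got {list(df.columns)}")
    if df["name"].duplicated().any():
        dups = sorted(df.loc[df["name"].duplicated(), "name"].unique())
        raise ValueError(f"duplicate landmark name(s): {', '.join(map(str, dups))}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        bad = df.loc[coords.isna().any(axis=1), "name"].tolist()
        raise ValueError(f"non-numeric coordinates for landmark(s): {', '.join(map(str, bad))}")
    return LandmarkSet({row["name"]: coords.loc[i].to_numpy() for i, row in df.iterrows()})
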