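"""Cephalometric planes and angles.

Constructs the Frankfurt horizontal (through both porions and both lower
orbital points, by total least squares), the condylar cut plane (through
the pterygoid fovea, parallel to Frankfurt), and the three angular
measurements the analysis uses:

* ANB — signed sagittal discrepancy at nasion between points A and B;
  negative values indicate skeletal Class III;
* divergence (intermaxillary) angle — between the maxillary line Ans–Pns
  and the mandibular line mid(Go_R, Go_L)–Me, folded into [0°, 90°];
* total gonial angle — at gonion between the ramus (Go–Cd) and body
  (Go–Me), unfolded in [0°, 180°].

All angles are invariant under rigid motion and uniform scaling of the
landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_imaging import LandmarkSet

__all__ = [
    "Plane",
    "CephalometricMeasurements",
    "fit_plane",
    "frankfurt_plane",
    "condylar_cut_plane",
    "anb_angle",
    "divergence_angle",
    "gonial_angle",
    "measure",
]

_COLLINEAR_RTOL = 1e-9


@dataclass
class Plane:
    """A plane given by a point ``p0`` (mm) and a unit normal ``n``.

    ``signed_distance(x) = n · (x − p0)``; the orientation of ``n`` is a
    contract recorded by each constructor (e.g. the condylar cut plane puts
    the condylar head on the non-negative side).
    """

    p0: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float).reshape(3)
        n = np.asarray(self.n, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            if norm <= 0 or not np.isfinite(norm):
                raise ValueError("plane normal must be a nonzero finite vector")
            n = n / norm
        self.n = n

    def signed_distance(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return (x - self.p0) @ self.n

    def flipped(self) -> "Plane":
        return Plane(self.p0.copy(), -self.n)


@dataclass
class CephalometricMeasurements:
    """The three angles the study analyzes (degrees)."""

    anb_deg: float
    divergence_deg: float
    gonial_deg_R: float
    gonial_deg_L: float

    @property
    def gonial_deg_mean(self) -> float:
        return 0.5 * (self.gonial_deg_R + self.gonial_deg_L)


def fit_plane(points: np.ndarray, names: list[str] | None = None) -> Plane:
    """Total-least-squares plane through ``points`` (≥3, not collinear).

    Minimizes the sum of squared orthogonal distances; exact interpolation
    when the points are coplanar. Degenerate (collinear or coincident)
    inputs raise a ``ValueError`` naming the offending points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError(f"need at least 3 points of dimension 3, got shape {pts.shape}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # smallest right singular vector = normal of the TLS plane
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    label = ", ".join(names) if names else f"{pts.shape[0]} points"
    if s[0] <= 0 or s[1] <= _COLLINEAR_RTOL * s[0]:
        raise ValueError(f"degenerate plane fit: points are collinear or coincident ({label})")
    return Plane(centroid, vt[2])


def frankfurt_plane(lm: LandmarkSet) -> Plane:
    """Frankfurt horizontal through Po_R, Po_L, Or_R, Or_L (TLS fit).

    Orientation contract: the normal points away from the mandible — menton
    (if present) has negative signed distance. Without Me, the normal's
    largest-magnitude component is made positive.
    """
    names = ["Po_R", "Po_L", "Or_R", "Or_L"]
    lm.require(names)
    plane = fit_plane(np.array([lm[n] for n in names]), names)
    if "Me" in lm:
        if plane.signed_distance(lm["Me"]) > 0:
            plane = plane.flipped()
    else:
        k = int(np.argmax(np.abs(plane.n)))
        if plane.n[k] < 0:
            plane = plane.flipped()
    return plane


def condylar_cut_plane(lm: LandmarkSet, side: str, frankfurt: Plane) -> Plane:
    """Cut plane through the pterygoid fovea, parallel to Frankfurt.

    Orientation contract: the condylar head lies on the non-negative side —
    condylion of the same side (if present) has signed distance ≥ 0.
    Without Cd, the Frankfurt normal is kept as-is (Frankfurt lies above
    menton, hence above the mandibular neck).
    """
    side = _check_side(side)
    fp_name, cd_name = f"FP_{side}", f"Cd_{side}"
    lm.require([fp_name])
    plane = Plane(lm[fp_name], frankfurt.n)
    if cd_name in lm and plane.signed_distance(lm[cd_name]) < 0:
        plane = plane.flipped()
    return plane


def _check_side(side: str) -> str:
    if side not in ("R", "L"):
        raise ValueError(f"side must be 'R' or 'L', got {side!r}")
    return side


def _angle_deg(u: np.ndarray, v: np.ndarray, what: str) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError(f"coincident points make a zero-length direction in {what}")
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _anterior_axis(lm: LandmarkSet) -> np.ndarray:
    """Unit anterior direction used to sign ANB.

    The component of N→mid(Ans, Pns) orthogonal to the Frankfurt normal;
    falls back to +x when the needed landmarks are absent or the
    construction degenerates.
    """
    fallback = np.array([1.0, 0.0, 0.0])
    if not all(n in lm for n in ("N", "Ans", "Pns")):
        return fallback
    axis = 0.5 * (lm["Ans"] + lm["Pns"]) - lm["N"]
    if all(n in lm for n in ("Po_R", "Po_L", "Or_R", "Or_L")):
        try:
            fn = frankfurt_plane(lm).n
            axis = axis - (axis @ fn) * fn
        except ValueError:
            pass
    norm = np.linalg.norm(axis)
    return axis / norm if norm > 1e-9 else fallback


def anb_angle(lm: LandmarkSet) -> float:
    """Signed ANB angle (degrees) at nasion between rays N→A and N→B.

    Magnitude is the unsigned 3D angle; the sign is positive when point A
    projects anterior to point B on the anterior axis (Class II side),
    negative otherwise (Class III side).
    """
    lm.require(["A", "B", "N"])
    a, b, n = lm["A"], lm["B"], lm["N"]
    angle = _angle_deg(a - n, b - n, "ANB (A or B coincides with N)")
    sign = 1.0 if (a - b) @ _anterior_axis(lm) >= 0 else -1.0
    return sign * angle


def divergence_angle(lm: LandmarkSet) -> float:
    """Intermaxillary divergence angle (degrees, folded into [0, 90]).

    Angle between the maxillary line Ans→Pns and the mandibular line
    mid(Go_R, Go_L)→Me; line directions are unsigned, so the result never
    exceeds 90°.
    """
    lm.require(["Ans", "Pns", "Go_R", "Go_L", "Me"])
    u = lm["Pns"] - lm["Ans"]
    v = lm["Me"] - 0.5 * (lm["Go_R"] + lm["Go_L"])
    angle = _angle_deg(u, v, "divergence")
    return 180.0 - angle if angle > 90.0 else angle


def gonial_angle(lm: LandmarkSet, side: str) -> float:
    """Total gonial angle (degrees) at Go between rays Go→Cd and Go→Me.

    Not folded: obtuse values (the clinically typical ≈120°) are preserved.
    """
    side = _check_side(side)
    go_name, cd_name = f"Go_{side}", f"Cd_{side}"
    lm.require([go_name, cd_name, "Me"])
    go = lm[go_name]
    return _angle_deg(lm[cd_name] - go, lm["Me"] - go, f"gonial angle ({side})")


def measure(lm: LandmarkSet) -> CephalometricMeasurements:
    """Compute all three study angles from one landmark set."""
    return CephalometricMeasurements(
        anb_deg=anb_angle(lm),
        divergence_deg=divergence_angle(lm),
        gonial_deg_R=gonial_angle(lm, "R"),
        gonial_deg_L=gonial_angle(lm, "L"),
    )
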