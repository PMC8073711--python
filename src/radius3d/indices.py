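"""Measurement indices computed from the three reference points.

All operations expect the reference points expressed in the anatomical
frame (see :mod:`radius3d.frame`): x dorsal/palmar, y along the long axis
with proximal positive, z radial/ulnar with radial positive.

Reference points: (1) radial styloid process, (2) sigmoid notch volar edge,
(3) sigmoid notch dorsal edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .frame import Point3

__all__ = [
    "ReferenceTriad",
    "TriadIndices",
    "DisplacementRecord",
    "triad_centroid",
    "triad_area",
    "volar_tilt_3d",
    "radial_inclination_3d",
    "displacement",
    "direction_label",
    "vt_2d",
    "ri_2d",
    "compute_indices",
]

Side = Literal["left", "right"]

POINT_NAMES = ("styloid", "sigmoid_volar", "sigmoid_dorsal")


def _pt(p) -> np.ndarray:
    if isinstance(p, Point3):
        return p.as_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ReferenceTriad:
    """The three reference points of one image, in frame coordinates (mm)."""

    p_styloid: Point3
    p_sigmoid_volar: Point3
    p_sigmoid_dorsal: Point3

    def __post_init__(self) -> None:
        for name in ("p_styloid", "p_sigmoid_volar", "p_sigmoid_dorsal"):
            v = getattr(self, name)
            if not isinstance(v, Point3):
                object.__setattr__(self, name, Point3.from_array(_pt(v)))

    @classmethod
    def from_matrix(cls, m) -> "ReferenceTriad":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"expected a (3, 3) matrix, got {m.shape}")
        return cls(*(Point3.from_array(row) for row in m))

    def as_matrix(self) -> np.ndarray:
        """Rows: styloid, sigmoid volar edge, sigmoid dorsal edge."""
        return np.vstack(
            [self.p_styloid.as_array(), self.p_sigmoid_volar.as_array(), self.p_sigmoid_dorsal.as_array()]
        )

    @property
    def is_degenerate(self) -> bool:
        """True if any two points coincide (pairwise distance <= 1e-6 mm)."""
        m = self.as_matrix()
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(m[i] - m[j]) <= 1e-6:
                    return True
        return False

    @property
    def is_collinear(self) -> bool:
        m = self.as_matrix()
        cross = np.cross(m[1] - m[0], m[2] - m[0])
        return bool(np.linalg.norm(cross) <= 1e-9)


@dataclass(frozen=True)
class TriadIndices:
    """Derived indices for one image's reference triad."""

    centroid: Point3
    plane_area: float  # mm^2
    vt_deg: float  # 3D volar tilt, palmar tilt positive
    ri_deg: float  # 3D radial inclination, styloid-distal positive
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.plane_area < 0:
            raise ValueError("plane_area must be >= 0")
        for name, a in (("vt_deg", self.vt_deg), ("ri_deg", self.ri_deg)):
            if not -90.0 <= a <= 90.0:
                raise ValueError(f"{name} out of [-90, 90]: {a}")


@dataclass(frozen=True)
class DisplacementRecord:
    """Post-minus-pre movement of the reference points and their centroid.

    ``vectors`` maps "styloid", "sigmoid_volar", "sigmoid_dorsal" and
    "centroid" to 3-vectors (mm); ``magnitudes`` to Euclidean norms;
    ``labels`` to anatomical direction strings such as "ulnar-palmar-distal".
    The centroid vector is the arithmetic mean of the three point vectors.
    """

    vectors: dict
    magnitudes: dict
    labels: dict


def triad_centroid(triad: ReferenceTriad) -> Point3:
    """Barycentre (component-wise mean) of the three reference points."""
    return Point3.from_array(triad.as_matrix().mean(axis=0))


def triad_area(triad: ReferenceTriad) -> tuple[float, bool]:
    """Area of the 3D triangle spanned by the reference points (mm^2).

    Returns ``(area, degenerate)``; collinear triads give area 0.0 with the
    degeneracy flag set.
    """
    m = triad.as_matrix()
    cross = np.cross(m[1] - m[0], m[2] - m[0])
    area = 0.5 * float(np.linalg.norm(cross))
    degenerate = triad.is_collinear or triad.is_degenerate
    return (0.0 if degenerate else area), degenerate


def _signed_elevation_deg(run: float, rise: float) -> float:
    """Angle between a projected segment and the perpendicular-to-y line.

    ``run`` is the in-plane horizontal separation, ``rise`` the separation
    along the long axis; positive when the second point is proximal to the
    first.  Coincident projections are rejected.
    """
    if abs(run) < 1e-12 and abs(rise) < 1e-12:
        raise ValueError("projected points coincide; angle undefined")
    return float(np.degrees(np.arctan2(rise, abs(run))))


def volar_tilt_3d(triad: ReferenceTriad) -> float:
    """Volar tilt from the sigmoid volar -> dorsal edge line (degrees).

    Measured in the sagittal (x-y) view as the signed angle between the
    projected line and the perpendicular to the long axis.  Positive when
    the volar edge lies distal to the dorsal edge (palmar tilt).
    """
    p2, p3 = triad.p_sigmoid_volar.as_array(), triad.p_sigmoid_dorsal.as_array()
    return _signed_elevation_deg(run=p3[0] - p2[0], rise=p3[1] - p2[1])


def radial_inclination_3d(triad: ReferenceTriad) -> float:
    """Radial inclination from the styloid -> sigmoid volar edge line (degrees).

    Measured in the coronal (y-z) view; positive when the styloid lies
    distal to the sigmoid volar edge.
    """
    p1, p2 = triad.p_styloid.as_array(), triad.p_sigmoid_volar.as_array()
    return _signed_elevation_deg(run=p2[2] - p1[2], rise=p2[1] - p1[1])


def vt_2d(volar_edge_2d, dorsal_edge_2d) -> float:
    """2D volar tilt from radiograph-plane landmarks (degrees).

    Coordinates are (horizontal, vertical) with the vertical axis along the
    radius long axis, proximal positive.  Same sign convention as
    :func:`volar_tilt_3d`; orthographic sagittal projections of 3D landmarks
    reproduce the 3D angle exactly.
    """
    v = np.asarray(volar_edge_2d, dtype=float)
    d = np.asarray(dorsal_edge_2d, dtype=float)
    if v.shape != (2,) or d.shape != (2,):
        raise ValueError("2D landmarks must have exactly 2 components")
    return _signed_elevation_deg(run=d[0] - v[0], rise=d[1] - v[1])


def ri_2d(styloid_2d, ulnar_aspect_2d) -> float:
    """2D radial inclination from radiograph-plane landmarks (degrees)."""
    s = np.asarray(styloid_2d, dtype=float)
    u = np.asarray(ulnar_aspect_2d, dtype=float)
    if s.shape != (2,) or u.shape != (2,):
        raise ValueError("2D landmarks must have exactly 2 components")
    return _signed_elevation_deg(run=u[0] - s[0], rise=u[1] - s[1])


def direction_label(vector, side: Side = "right", dead_zone: float = 0.0) -> str:
    """Anatomical direction label of a frame-coordinate vector.

    Components with magnitude < ``dead_zone`` are omitted.  Terms are
    ordered z-axis, x-axis, y-axis (e.g. "ulnar-palmar-distal"); an all-zero
    vector yields "none".  The x mapping depends on ``side``: +x is dorsal
    on right wrists and palmar on left wrists.
    """
    v = _pt(vector)
    x_pos, x_neg = ("dorsal", "palmar") if side == "right" else ("palmar", "dorsal")
    terms = []
    if abs(v[2]) > dead_zone and v[2] != 0:
        terms.append("radial" if v[2] > 0 else "ulnar")
    if abs(v[0]) > dead_zone and v[0] != 0:
        terms.append(x_pos if v[0] > 0 else x_neg)
    if abs(v[1]) > dead_zone and v[1] != 0:
        terms.append("proximal" if v[1] > 0 else "distal")
    return "-".join(terms) if terms else "none"


def displacement(
    pre: ReferenceTriad,
    post: ReferenceTriad,
    side: Side = "right",
    dead_zone: float = 0.0,
    pre_frame_id=None,
    post_frame_id=None,
) -> DisplacementRecord:
    """Movement of each reference point and the centroid from pre to post.

    Both triads must be expressed in the same anatomical frame; if frame
    identifiers are supplied they must match.  Vectors are post - pre; the
    centroid vector is computed as the mean of the three point vectors so
    the centroid identity holds exactly.
    """
    if pre_frame_id is not None and post_frame_id is not None and pre_frame_id != post_frame_id:
        raise ValueError(f"triads are in different frames: {pre_frame_id!r} != {post_frame_id!r}")
    diffs = post.as_matrix() - pre.as_matrix()
    vectors = {name: diffs[i] for i, name in enumerate(POINT_NAMES)}
    vectors["centroid"] = diffs.mean(axis=0)
    magnitudes = {k: float(np.linalg.norm(v)) for k, v in vectors.items()}
    labels = {k: direction_label(v, side=side, dead_zone=dead_zone) for k, v in vectors.items()}
    return DisplacementRecord(vectors=vectors, magnitudes=magnitudes, labels=labels)


def compute_indices(triad: ReferenceTriad) -> TriadIndices:
    """Centroid, plane area, 3D-VT and 3D-RI for one triad."""
    area, degenerate = triad_area(triad)
    return TriadIndices(
        centroid=triad_centroid(triad),
        plane_area=area,
        vt_deg=volar_tilt_3d(triad),
        ri_deg=radial_inclination_3d(triad),
        degenerate=degenerate,
    )
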