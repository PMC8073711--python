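"""Anatomical coordinate-frame construction for the distal radius.

The frame is built from the long axis of the intact shaft and two landmarks
(base of the sigmoid notch and the radial styloid process):

* ``ey`` — long axis of the radius, proximal direction positive;
* ``ez`` — projection of the sigmoid-base -> styloid line onto the plane
  perpendicular to ``ey``, radial direction positive;
* ``ex = ey x ez`` — normal to the yz plane (right-handed).

The yz, xy and xz planes of the frame are the coronal, sagittal and axial
planes respectively.  The frame origin sits on the long axis at the level of
the articular surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

__all__ = [
    "DegenerateGeometryError",
    "Point3",
    "AxisLine",
    "AnatomicalFrame",
    "RigidTransform",
    "fit_long_axis",
    "build_frame",
    "locate_origin",
    "register_rigid",
    "to_frame",
    "from_frame",
]

Side = Literal["left", "right"]

_ORTHO_TOL = 1e-9
_UNIT_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when an input configuration has no well-defined solution."""


def _as_xyz(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if isinstance(p, Point3):
        a = p.as_array()
    if a.shape != (3,):
        raise ValueError(f"{name} must have exactly 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite components: {a}")
    return a


def _as_points(points, name: str = "points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


@dataclass(frozen=True)
class Point3:
    """A point in frame coordinates (mm).

    ``x`` runs dorsal/palmar, ``y`` along the long axis (proximal positive),
    ``z`` along the radial-ulnar axis (radial positive).
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not np.isfinite(c):
                raise ValueError(f"Point3 components must be finite, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class AxisLine:
    """An infinite line in lab coordinates: ``anchor + t * direction``."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", _as_xyz(self.anchor, "anchor"))
        d = _as_xyz(self.direction, "direction")
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            if n < 1e-12:
                raise ValueError("direction must be a non-zero vector")
            d = d / n
        object.__setattr__(self, "direction", d)

    def project(self, point) -> np.ndarray:
        """Orthogonal projection of ``point`` onto the line."""
        p = _as_xyz(point)
        t = float(np.dot(p - self.anchor, self.direction))
        return self.anchor + t * self.direction

    def parameter(self, point) -> float:
        """Signed axis parameter of the projection of ``point``."""
        return float(np.dot(_as_xyz(point) - self.anchor, self.direction))

    def distance(self, points) -> np.ndarray:
        """Perpendicular distances of one or many points to the line."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.anchor
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        return np.linalg.norm(perp, axis=1)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed frame mapping lab coordinates to anatomy.

    Attributes
    ----------
    origin : (3,) ndarray
        Lab-coordinate position of the frame origin (mm).
    ex, ey, ez : (3,) ndarray
        Unit axis vectors in lab coordinates.
    side : {"left", "right"}
        Which wrist the frame describes; drives dorsal/palmar labelling.
    """

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    side: Side = "right"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_xyz(self.origin, "origin"))
        for name in ("ex", "ey", "ez"):
            object.__setattr__(self, name, _as_xyz(getattr(self, name), name))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.validate()

    def validate(self, tol: float = _ORTHO_TOL) -> None:
        ex, ey, ez = self.ex, self.ey, self.ez
        for name, v in (("ex", ex), ("ey", ey), ("ez", ez)):
            if abs(np.linalg.norm(v) - 1.0) > tol:
                raise ValueError(f"{name} is not unit-norm: |{name}| = {np.linalg.norm(v)}")
        for (na, a), (nb, b) in (
            (("ex", ex), ("ey", ey)),
            (("ex", ex), ("ez", ez)),
            (("ey", ey), ("ez", ez)),
        ):
            if abs(np.dot(a, b)) > tol:
                raise ValueError(f"{na} and {nb} are not orthogonal: dot = {np.dot(a, b)}")
        handed = float(np.dot(ex, np.cross(ey, ez)))
        if abs(handed - 1.0) > tol:
            raise ValueError(f"frame is not right-handed: ex.(ey x ez) = {handed}")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are ``ex``, ``ey``, ``ez``."""
        return np.vstack([self.ex, self.ey, self.ez])

    def to_frame(self, lab_point) -> Point3:
        p = _as_xyz(lab_point, "lab_point")
        return Point3.from_array(self.rotation @ (p - self.origin))

    def from_frame(self, frame_point) -> np.ndarray:
        p = frame_point.as_array() if isinstance(frame_point, Point3) else _as_xyz(frame_point)
        return self.origin + self.rotation.T @ p

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "ex": self.ex.tolist(),
            "ey": self.ey.tolist(),
            "ez": self.ez.tolist(),
            "side": self.side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomicalFrame":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            ex=np.asarray(d["ex"], dtype=float),
            ey=np.asarray(d["ey"], dtype=float),
            ez=np.asarray(d["ez"], dtype=float),
            side=d.get("side", "right"),
        )

    @classmethod
    def identity(cls, side: Side = "right") -> "AnatomicalFrame":
        return cls(
            origin=np.zeros(3),
            ex=np.array([1.0, 0.0, 0.0]),
            ey=np.array([0.0, 1.0, 0.0]),
            ez=np.array([0.0, 0.0, 1.0]),
            side=side,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rms: float = 0.0
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = _as_xyz(self.translation, "translation")
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
            rms=self.rms,
            converged=self.converged,
            n_iter=self.n_iter,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def angle_deg(self) -> float:
        """Rotation angle of the transform in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# long-axis fitting


def _principal_direction(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, dominant eigenvector and singular values of the cloud."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    # SVD of the centered cloud: right singular vectors = covariance eigenvectors
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[0], svals


def fit_long_axis(
    shaft_points,
    method: Literal["pca_centroids", "cylinder_lsq"] = "pca_centroids",
    distal_ref=None,
    slab_mm: float = 2.0,
) -> AxisLine:
    """Fit the long axis of the radius to shaft-surface points.

    Parameters
    ----------
    shaft_points : (n, 3) array-like
        Lab-coordinate points on the intact shaft surface (mm); n >= 10.
    method : {"pca_centroids", "cylinder_lsq"}
        ``pca_centroids`` slices the cloud into slabs along an initial PCA
        axis and fits a total-least-squares line through the slab centroids
        (robust to the distal flare).  ``cylinder_lsq`` fits a least-squares
        cylinder and returns its axis.
    distal_ref : point, optional
        Any point on the distal side of the shaft.  When given, the returned
        direction is flipped if necessary so it points proximally, i.e. away
        from ``distal_ref``.
    slab_mm : float
        Slab thickness for ``pca_centroids``.

    Returns
    -------
    AxisLine
        Unit-direction line anchored near the cloud centroid.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 10 points are given, the cloud has no dominant
        direction, or its extent along the principal direction is < 5 mm.
    """
    pts = _as_points(shaft_points, "shaft_points")
    if len(pts) < 10:
        raise DegenerateGeometryError(f"need >= 10 shaft points, got {len(pts)}")

    centroid, d0, svals = _principal_direction(pts)
    span = np.ptp(pts @ d0)
    if span < 5.0:
        raise DegenerateGeometryError(f"points span only {span:.2f} mm along the principal direction (< 5 mm)")
    # eigenvalues ~ svals**2; require a dominant axis
    if svals[1] > 0 and (svals[0] / svals[1]) ** 2 < 1.2:
        raise DegenerateGeometryError("point cloud is near-isotropic; no dominant long axis")

    if method == "pca_centroids":
        axis = _fit_axis_slab_centroids(pts, centroid, d0, slab_mm)
    elif method == "cylinder_lsq":
        axis = _fit_axis_cylinder(pts, centroid, d0)
    else:
        raise ValueError(f"unknown method {method!r}")

    direction = axis.direction
    if distal_ref is not None:
        ref = _as_xyz(distal_ref, "distal_ref")
        if np.dot(direction, ref - axis.anchor) > 0:
            direction = -direction
    # anchor at the projection of the cloud centroid for stability
    line = AxisLine(anchor=axis.anchor, direction=direction)
    return AxisLine(anchor=line.project(centroid), direction=direction)


def _fit_axis_slab_centroids(pts: np.ndarray, centroid: np.ndarray, d0: np.ndarray, slab_mm: float) -> AxisLine:
    t = (pts - centroid) @ d0
    n_bins = max(2, int(np.ceil(np.ptp(t) / slab_mm)))
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    idx = np.digitize(t, edges) - 1
    centroids = np.array([pts[idx == i].mean(axis=0) for i in range(n_bins) if np.any(idx == i)])
    if len(centroids) < 2:
        raise DegenerateGeometryError("fewer than two populated slabs; cannot fit axis")
    c_mean, c_dir, _ = _principal_direction(centroids)
    if np.dot(c_dir, d0) < 0:
        c_dir = -c_dir
    return AxisLine(anchor=c_mean, direction=c_dir)


def _fit_axis_cylinder(pts: np.ndarray, centroid: np.ndarray, d0: np.ndarray) -> AxisLine:
    # basis perpendicular to the initial direction
    u = np.cross(d0, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(d0, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d0, u)

    r0 = float(np.mean(AxisLine(anchor=centroid, direction=d0).distance(pts)))

    def unpack(params):
        a, b, alpha, beta, r = params
        d = d0 + alpha * u + beta * v
        d = d / np.linalg.norm(d)
        c = centroid + a * u + b * v
        return c, d, r

    def residuals(params):
        c, d, r = unpack(params)
        rel = pts - c
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1) - r

    sol = least_squares(
        residuals,
        x0=np.array([0.0, 0.0, 0.0, 0.0, r0]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    c, d, _ = unpack(sol.x)
    return AxisLine(anchor=c, direction=d)


# ---------------------------------------------------------------------------
# frame construction


def build_frame(long_axis: AxisLine, sigmoid_base, styloid, origin, side: Side = "right") -> AnatomicalFrame:
    """Build the anatomical frame from the long axis and two landmarks.

    ``ey`` is the (proximally oriented) long-axis direction; ``ez`` is the
    unit projection of the sigmoid-base -> styloid vector onto the plane
    perpendicular to ``ey`` (radial positive); ``ex = ey x ez``.  The origin
    is the supplied articular-surface point projected onto the long axis.
    """
    ey = long_axis.direction
    v = _as_xyz(styloid, "styloid") - _as_xyz(sigmoid_base, "sigmoid_base")
    proj = v - np.dot(v, ey) * ey
    norm = np.linalg.norm(proj)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            "styloid - sigmoid_base is parallel to the long axis; cannot orient the z-axis"
        )
    ez = proj / norm
    ex = np.cross(ey, ez)
    return AnatomicalFrame(origin=long_axis.project(origin), ex=ex, ey=ey, ez=ez, side=side)


def locate_origin(long_axis: AxisLine, joint_surface_points) -> np.ndarray:
    """Intersection of the long axis with the articular surface.

    Returns the point on the axis at the parameter of the joint-surface
    point closest to the axis.  A single manually picked point is simply
    projected onto the axis.
    """
    pts = np.asarray(joint_surface_points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    pts = _as_points(pts, "joint_surface_points")
    if len(pts) == 0:
        raise ValueError("joint_surface_points is empty")
    dists = long_axis.distance(pts)
    return long_axis.project(pts[int(np.argmin(dists))])


# ---------------------------------------------------------------------------
# rigid registration (point-to-point ICP)


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=r, translation=fc - r @ mc)


def register_rigid(
    moving_shaft_points,
    fixed_shaft_points,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> RigidTransform:
    """Point-to-point ICP alignment of two overlapping shaft clouds.

    Starts from the identity, alternates nearest-neighbour matching against
    the fixed cloud with a Kabsch update, and stops when the RMS residual
    changes by less than ``tol`` mm.  Returns the transform mapping moving
    into fixed, with the final RMS residual and a convergence flag.
    """
    moving = _as_points(moving_shaft_points, "moving_shaft_points")
    fixed = _as_points(fixed_shaft_points, "fixed_shaft_points")
    if len(moving) < 10 or len(fixed) < 10:
        raise ValueError("both clouds must contain at least 10 points")

    tree = cKDTree(fixed)
    # centroid alignment before the first matching step: with overlapping
    # clouds this removes the gross translation and keeps the first
    # nearest-neighbour correspondences inside the convergence basin
    transform = RigidTransform(rotation=np.eye(3), translation=fixed.mean(axis=0) - moving.mean(axis=0))
    current = transform.apply(moving)
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dists, nn = tree.query(current)
        step = _kabsch(current, fixed[nn])
        transform = step.compose(transform)
        current = step.apply(current)
        rms = float(np.sqrt(np.mean(tree.query(current)[0] ** 2)))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    return RigidTransform(
        rotation=transform.rotation,
        translation=transform.translation,
        rms=rms,
        converged=converged,
        n_iter=it,
    )


def to_frame(frame: AnatomicalFrame, lab_point) -> Point3:
    """Express a lab-coordinate point in the anatomical frame."""
    return frame.to_frame(lab_point)


def from_frame(frame: AnatomicalFrame, frame_point) -> np.ndarray:
    """Inverse of :func:`to_frame`."""
    return frame.from_frame(frame_point)
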