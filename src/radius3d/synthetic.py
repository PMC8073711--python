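"""Synthetic shafts and pre/post reference-point cohorts with ground truth.

The generative model works backwards from an anatomic (post-reduction)
triad: the displaced preoperative triad is produced by a hinge rotation
about the dorsal or volar rim, proximal translation (shortening) and a
radial shift, plus optional translation noise.  Every patient stores the
exact per-point truth vectors so pipeline recovery can be verified.

All canonical geometry lives in the anatomical frame itself: postoperative
"lab" coordinates coincide with frame coordinates, while preoperative data
carry a random rigid pose when shaft clouds are generated so that the
registration stage has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats as sps

from .frame import AxisLine, Point3, RigidTransform
from .indices import POINT_NAMES, ReferenceTriad

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticPatient",
    "generate_shaft_points",
    "apply_fracture_displacement",
    "generate_cohort",
]

Hinge = Literal["dorsal_rim", "volar_rim"]

# default anatomic (postoperative) triad, frame coordinates in mm; component
# signs follow radial-palmar-distal / ulnar-palmar-proximal /
# ulnar-dorsal-proximal positions with magnitudes near 14.5 / 17.3 / 14.2 mm
DEFAULT_POST_TRIAD = (
    Point3(-2.0, -6.0, 13.0),  # styloid: radial, palmar, distal
    Point3(-5.0, 7.0, -15.0),  # sigmoid volar edge: ulnar, palmar, proximal
    Point3(4.9, 6.0, -12.0),  # sigmoid dorsal edge: ulnar, dorsal, proximal
)

SIGMOID_BASE_Y = -2.0
SIGMOID_BASE_Z = -16.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Distributions governing a generated pre/post cohort.

    Landmark noise is isotropic with total (3D RMS) standard deviation
    ``landmark_noise_sd``, i.e. sd/sqrt(3) per axis.  Tilt and shortening
    are Gaussian truncated to anatomically plausible ranges.  Shaft point
    clouds (and the preoperative pose) are generated only when
    ``n_shaft_points > 0``.
    """

    n_patients: int = 52
    postop_triad_means: tuple = DEFAULT_POST_TRIAD
    postop_triad_sd: float = 2.0
    tilt_mean_deg: float = 28.0
    tilt_sd_deg: float = 10.0
    tilt_range_deg: tuple = (0.0, 40.0)
    shortening_mean_mm: float = 5.0
    shortening_sd_mm: float = 2.5
    shortening_range_mm: tuple = (0.0, 15.0)
    shift_mean_mm: float = 3.0
    shift_sd_mm: float = 1.5
    translation_noise_sd: float = 0.5
    dorsal_fraction: float = 39.0 / 52.0
    landmark_noise_sd: float = 0.0
    seed: int = 0
    n_shaft_points: int = 0
    shaft_radius_mm: float = 8.0
    shaft_length_mm: float = 60.0
    shaft_noise_sd: float = 0.0
    pre_pose_angle_deg: float = 5.0
    pre_pose_translation_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in (
            "postop_triad_sd",
            "tilt_sd_deg",
            "shortening_sd_mm",
            "shift_sd_mm",
            "translation_noise_sd",
            "landmark_noise_sd",
            "shaft_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dorsal_fraction <= 1.0:
            raise ValueError("dorsal_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticPatient:
    """One generated patient with full ground truth.

    ``landmarks_pre``/``landmarks_post`` are the observed (noisy, posed)
    lab-coordinate landmarks a user would supply; ``true_pre``/``true_post``
    are the exact triads in anatomical-frame coordinates.
    """

    patient_id: str
    side: str
    hinge: Hinge
    tilt_deg: float
    shortening_mm: float
    shift_mm: float
    true_pre: ReferenceTriad
    true_post: ReferenceTriad
    truth_displacement: dict  # pre - post per point and centroid (mm)
    landmarks_pre: dict
    landmarks_post: dict
    pre_pose: RigidTransform  # maps anatomical-frame pre data into pre-op lab
    shaft_pre: Optional[np.ndarray] = None
    shaft_post: Optional[np.ndarray] = None

    @property
    def reduction_vectors(self) -> dict:
        """Post - pre movement of each point (the reduction)."""
        return {k: -v for k, v in self.truth_displacement.items()}

    @property
    def observed_pre(self) -> ReferenceTriad:
        return ReferenceTriad.from_matrix(np.vstack([self.landmarks_pre[n] for n in POINT_NAMES]))

    @property
    def observed_post(self) -> ReferenceTriad:
        return ReferenceTriad.from_matrix(np.vstack([self.landmarks_post[n] for n in POINT_NAMES]))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(d, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def generate_shaft_points(
    axis: AxisLine,
    radius_mm: float,
    length_mm: float,
    n_points: int,
    noise_sd: float = 0.0,
    seed=0,
    layout: Literal["random", "rings"] = "random",
) -> np.ndarray:
    """Sample points on a cylinder surface about ``axis``.

    ``random`` draws angle and axial position uniformly over the surface;
    ``rings`` places full rings of 20 points with a golden-angle twist per
    ring (noiseless slab centroids then lie exactly on the axis, and the
    grid has no rotational or translational self-symmetry to trap ICP).
    Isotropic Gaussian noise of per-axis sd ``noise_sd`` is added.  The
    cylinder spans axis parameters [-length_mm, 0].
    """
    if radius_mm <= 0 or length_mm <= 0:
        raise ValueError("radius_mm and length_mm must be positive")
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    rng = _rng(seed)
    d = axis.direction
    u, v = _perp_basis(d)
    if layout == "random":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_points)
        t = rng.uniform(-length_mm, 0.0, size=n_points)
    elif layout == "rings":
        # full rings keep each ring centroid exactly on the axis; coprime
        # ring sizes, a per-ring twist and irregular axial spacing leave the
        # grid with no rigid self-symmetry (rotation, translation or screw),
        # so ICP registration cannot alias onto a shifted copy
        ring_sizes = (17, 20, 23)
        n_rings = max(3, int(round(n_points / np.mean(ring_sizes))))
        golden = np.pi * (3.0 - np.sqrt(5.0))
        idx = np.arange(n_rings, dtype=float)
        warped = idx + 0.35 * np.sin(2.4 * idx)
        warped = (warped - warped.min()) / (warped.max() - warped.min())
        t_rings = -length_mm * (1.0 - warped)
        theta_parts, t_parts = [], []
        for i in range(n_rings):
            size = ring_sizes[i % len(ring_sizes)]
            theta_parts.append(np.linspace(0.0, 2.0 * np.pi, size, endpoint=False) + i * golden)
            t_parts.append(np.full(size, t_rings[i]))
        theta = np.concatenate(theta_parts)
        t = np.concatenate(t_parts)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    pts = (
        axis.anchor
        + np.outer(t, d)
        + radius_mm * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    )
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


def _rotation_about_line(anchor: np.ndarray, direction: np.ndarray, angle_deg: float) -> RigidTransform:
    direction = direction / np.linalg.norm(direction)
    a = np.radians(angle_deg)
    kx, ky, kz = direction
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    R = np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)
    return RigidTransform(rotation=R, translation=anchor - R @ anchor)


def apply_fracture_displacement(
    post_triad: ReferenceTriad,
    tilt_deg: float,
    shortening_mm: float,
    shift_mm: float,
    hinge: Hinge = "dorsal_rim",
) -> tuple[ReferenceTriad, dict]:
    """Displace an anatomic triad into its preoperative configuration.

    The triad is rotated by ``tilt_deg`` about a radial-ulnar (z-parallel)
    hinge line through the dorsal or volar sigmoid edge — positive tilt
    moves the fragment toward the hinge side (dorsally for ``dorsal_rim``)
    — then translated proximally by ``shortening_mm`` and radially by
    ``shift_mm``.

    Returns ``(pre_triad, truth)`` where ``truth`` maps point names and
    "centroid" to the exact pre - post displacement vectors.
    """
    m_post = post_triad.as_matrix()
    anchor = (
        post_triad.p_sigmoid_dorsal.as_array()
        if hinge == "dorsal_rim"
        else post_triad.p_sigmoid_volar.as_array()
    )
    angle = tilt_deg if hinge == "dorsal_rim" else -tilt_deg
    rot = _rotation_about_line(anchor, np.array([0.0, 0.0, 1.0]), angle)
    m_pre = rot.apply(m_post) + np.array([0.0, shortening_mm, shift_mm])
    diffs = m_pre - m_post
    truth = {name: diffs[i] for i, name in enumerate(POINT_NAMES)}
    truth["centroid"] = diffs.mean(axis=0)
    return ReferenceTriad.from_matrix(m_pre), truth


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _random_pose(rng, angle_deg: float, translation_mm: float) -> RigidTransform:
    if angle_deg == 0 and translation_mm == 0:
        return RigidTransform.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(-angle_deg, angle_deg)
    rot = _rotation_about_line(np.zeros(3), axis, ang)
    t = rng.uniform(-translation_mm, translation_mm, size=3)
    return RigidTransform(rotation=rot.rotation, translation=t)


def _add_noise(points: np.ndarray, sd_total: float, rng) -> np.ndarray:
    if sd_total == 0:
        return points
    return points + rng.normal(0.0, sd_total / np.sqrt(3.0), size=points.shape)


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticPatient]:
    """Generate a reproducible cohort of synthetic patients.

    Each patient gets five landmarks per stage (the reference triad plus
    sigmoid base and articular origin).  The sigmoid base shares the
    styloid's x-coordinate so the noiseless landmark-built frame is exactly
    the canonical identity frame and stored truths are recovered exactly.
    """
    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    means = np.vstack(
        [p.as_array() if isinstance(p, Point3) else np.asarray(p, float) for p in spec.postop_triad_means]
    )
    use_shafts = spec.n_shaft_points > 0

    for i in range(spec.n_patients):
        post = ReferenceTriad.from_matrix(means + rng.normal(0.0, spec.postop_triad_sd, size=(3, 3)))
        dorsal = rng.random() < spec.dorsal_fraction
        hinge: Hinge = "dorsal_rim" if dorsal else "volar_rim"
        tilt = _truncated_normal(rng, spec.tilt_mean_deg, spec.tilt_sd_deg, *spec.tilt_range_deg)
        shortening = _truncated_normal(
            rng, spec.shortening_mean_mm, spec.shortening_sd_mm, *spec.shortening_range_mm
        )
        shift = float(rng.normal(spec.shift_mean_mm, spec.shift_sd_mm))
        pre, truth = apply_fracture_displacement(post, tilt, shortening, shift, hinge=hinge)
        if spec.translation_noise_sd > 0:
            extra = rng.normal(0.0, spec.translation_noise_sd, size=3)
            pre = ReferenceTriad.from_matrix(pre.as_matrix() + extra)
            truth = {k: v + extra for k, v in truth.items()}

        # frame landmarks: base shares the styloid x so that the projected
        # base->styloid line is exactly +z and the built frame is canonical
        sigmoid_base = np.array([post.p_styloid.x, SIGMOID_BASE_Y, SIGMOID_BASE_Z])
        origin = np.zeros(3)

        post_pts = _add_noise(
            np.vstack([post.as_matrix(), sigmoid_base, origin]), spec.landmark_noise_sd, rng
        )
        pre_pts = _add_noise(
            np.vstack([pre.as_matrix(), sigmoid_base, origin]), spec.landmark_noise_sd, rng
        )

        pose = RigidTransform.identity()
        shaft_pre = shaft_post = None
        if use_shafts:
            # shaft occupies y in [10, 10 + L]: proximal (+y) of the joint
            shaft_axis = AxisLine(
                anchor=np.array([0.0, 10.0 + spec.shaft_length_mm, 0.0]),
                direction=np.array([0.0, 1.0, 0.0]),
            )
            base_cloud = generate_shaft_points(
                shaft_axis,
                spec.shaft_radius_mm,
                spec.shaft_length_mm,
                spec.n_shaft_points,
                noise_sd=0.0,
                seed=rng,
                layout="rings",
            )
            shaft_post = base_cloud.copy()
            shaft_pre = base_cloud.copy()
            if spec.shaft_noise_sd > 0:
                shaft_post = shaft_post + rng.normal(0.0, spec.shaft_noise_sd, size=base_cloud.shape)
                shaft_pre = shaft_pre + rng.normal(0.0, spec.shaft_noise_sd, size=base_cloud.shape)
            pose = _random_pose(rng, spec.pre_pose_angle_deg, spec.pre_pose_translation_mm)
            shaft_pre = pose.apply(shaft_pre)
            pre_pts = pose.apply(pre_pts)

        labels = list(POINT_NAMES) + ["sigmoid_base", "origin"]
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i + 1:04d}",
                side="right",
                hinge=hinge,
                tilt_deg=tilt,
                shortening_mm=shortening,
                shift_mm=shift,
                true_pre=pre,
                true_post=post,
                truth_displacement=truth,
                landmarks_pre={lab: pre_pts[j] for j, lab in enumerate(labels)},
                landmarks_post={lab: post_pts[j] for j, lab in enumerate(labels)},
                pre_pose=pose,
                shaft_pre=shaft_pre,
                shaft_post=shaft_post,
            )
        )
    return patients
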