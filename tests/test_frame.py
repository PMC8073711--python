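import numpy as np
import pytest

from radius3d.frame import (
    AnatomicalFrame,
    AxisLine,
    DegenerateGeometryError,
    Point3,
    RigidTransform,
    build_frame,
    fit_long_axis,
    from_frame,
    locate_origin,
    register_rigid,
    to_frame,
)
from radius3d.synthetic import generate_shaft_points

from conftest import random_rotation


def angular_error(d1, d2) -> float:
    return float(np.arccos(min(1.0, abs(float(np.dot(d1, d2))))))


class TestAxisLine:
    def test_direction_normalised(self):
        line = AxisLine(anchor=[0, 0, 0], direction=[0, 2, 0])
        assert np.linalg.norm(line.direction) == pytest.approx(1.0, abs=1e-15)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            AxisLine(anchor=[0, 0, 0], direction=[0, 0, 0])

    def test_projection(self):
        line = AxisLine(anchor=[0, 0, 0], direction=[0, 1, 0])
        assert np.allclose(line.project([3, 5, -2]), [0, 5, 0])


class TestFitLongAxis:
    def test_collinear_points_exact(self):
        pts = [(0.0, float(k), 0.0) for k in range(10)]
        line = fit_long_axis(pts, distal_ref=(0.0, -1.0, 0.0))
        assert np.allclose(line.direction, [0, 1, 0], atol=1e-12)

    def test_noiseless_cylinder_axis(self, canonical_axis):
        true = AxisLine(anchor=[1, 2, 3], direction=np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        pts = generate_shaft_points(true, radius_mm=8.0, length_mm=60.0, n_points=2000, seed=11)
        line = fit_long_axis(pts, method="cylinder_lsq")
        assert angular_error(line.direction, true.direction) < 1e-6
        # fitted line passes through the true axis
        assert float(true.distance(line.anchor)[0]) < 1e-5

    def test_noiseless_rings_pca_exact(self):
        true = AxisLine(anchor=[1, 2, 3], direction=np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        pts = generate_shaft_points(true, 8.0, 60.0, 600, seed=1, layout="rings")
        line = fit_long_axis(pts, method="pca_centroids")
        assert angular_error(line.direction, true.direction) < 1e-9

    @pytest.mark.parametrize("method", ["cylinder_lsq", "pca_centroids"])
    def test_noisy_cylinder_axis(self, method):
        true = AxisLine(anchor=[1, 2, 3], direction=np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        layout = "rings" if method == "pca_centroids" else "random"
        pts = generate_shaft_points(true, 8.0, 60.0, 2000, noise_sd=0.3, seed=7, layout=layout)
        line = fit_long_axis(pts, method=method)
        assert np.degrees(angular_error(line.direction, true.direction)) < 0.5

    def test_distal_ref_orients_proximally(self):
        pts = [(0.0, float(k), 0.0) for k in range(10)]
        line = fit_long_axis(pts, distal_ref=(0.0, 100.0, 0.0))
        assert np.allclose(line.direction, [0, -1, 0], atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_long_axis([(0, k, 0) for k in range(9)])

    def test_isotropic_cloud_rejected(self, rng):
        directions = rng.normal(size=(500, 3))
        sphere = 10.0 * directions / np.linalg.norm(directions, axis=1, keepdims=True)
        with pytest.raises(DegenerateGeometryError):
            fit_long_axis(sphere)

    def test_small_span_rejected(self, rng):
        pts = rng.normal(scale=[0.5, 0.1, 0.1], size=(100, 3))
        with pytest.raises(DegenerateGeometryError):
            fit_long_axis(pts)

    def test_equivariance_under_rigid_transform(self, rng):
        true = AxisLine(anchor=[0, 0, 0], direction=[0, 1, 0])
        pts = generate_shaft_points(true, 8.0, 60.0, 600, seed=3, layout="rings")
        base = fit_long_axis(pts, method="pca_centroids", distal_ref=(0, -100, 0))
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, size=3)
        moved = fit_long_axis(pts @ R.T + t, method="pca_centroids", distal_ref=R @ np.array([0, -100.0, 0]) + t)
        assert np.allclose(moved.direction, R @ base.direction, atol=1e-9)
        expected_line = AxisLine(anchor=R @ base.anchor + t, direction=R @ base.direction)
        assert float(expected_line.distance(moved.anchor)[0]) < 1e-9


class TestBuildFrame:
    def test_direct_construction(self, canonical_axis):
        frame = build_frame(canonical_axis, sigmoid_base=[0, 0, 0], styloid=[5, -2, 20], origin=[0, 0, 0])
        assert np.allclose(frame.ez, np.array([5.0, 0.0, 20.0]) / np.linalg.norm([5.0, 0.0, 20.0]), atol=1e-12)
        assert frame.ez[0] == pytest.approx(0.2425, abs=1e-4)
        assert frame.ez[2] == pytest.approx(0.9701, abs=1e-4)
        assert np.allclose(frame.ex, np.cross(frame.ey, frame.ez), atol=1e-12)
        frame.validate()  # orthonormality + handedness

    def test_rotated_canonical_matches_oracle(self, rng, canonical_axis):
        base = build_frame(canonical_axis, [0, 0, 0], [5, -2, 20], [0, 0, 0])
        for _ in range(5):
            R = random_rotation(rng)
            axis = AxisLine(anchor=R @ canonical_axis.anchor, direction=R @ canonical_axis.direction)
            frame = build_frame(axis, R @ np.zeros(3), R @ np.array([5.0, -2.0, 20.0]), R @ np.zeros(3))
            assert np.allclose(frame.ex, R @ base.ex, atol=1e-9)
            assert np.allclose(frame.ey, R @ base.ey, atol=1e-9)
            assert np.allclose(frame.ez, R @ base.ez, atol=1e-9)

    def test_degenerate_projection(self, canonical_axis):
        with pytest.raises(DegenerateGeometryError):
            build_frame(canonical_axis, sigmoid_base=[0, 0, 0], styloid=[0, 10, 0], origin=[0, 0, 0])

    def test_frame_invariants_random_inputs(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            axis = AxisLine(anchor=rng.normal(size=3), direction=d)
            styloid = rng.normal(scale=20, size=3)
            base = rng.normal(scale=20, size=3)
            if np.linalg.norm(np.cross(styloid - base, d)) < 1e-3:
                continue
            frame = build_frame(axis, base, styloid, rng.normal(size=3))
            frame.validate(tol=1e-9)


class TestLocateOrigin:
    def test_planar_patch(self, canonical_axis, rng):
        xs = rng.uniform(-5, 5, size=50)
        zs = rng.uniform(-5, 5, size=50)
        pts = np.column_stack([xs, np.full(50, -2.0), zs])
        assert np.allclose(locate_origin(canonical_axis, pts), [0, -2, 0], atol=1e-12)

    def test_single_picked_point(self, canonical_axis):
        assert np.allclose(locate_origin(canonical_axis, [0.5, -2.1, 0.3]), [0, -2.1, 0], atol=1e-12)

    def test_hemisphere_apex(self, canonical_axis, rng):
        # hemisphere of radius 10 centred at (0, -12, 0), apex at (0, -2, 0)
        centre = np.array([0.0, -12.0, 0.0])
        polar = rng.uniform(0, np.radians(80), size=400)
        azim = rng.uniform(0, 2 * np.pi, size=400)
        pts = centre + 10.0 * np.column_stack(
            [np.sin(polar) * np.cos(azim), np.cos(polar), np.sin(polar) * np.sin(azim)]
        )
        pts = np.vstack([pts, centre + [0.0, 10.0, 0.0]])  # include the apex
        assert np.linalg.norm(locate_origin(canonical_axis, pts) - [0, -2, 0]) < 0.1

    def test_empty_surface(self, canonical_axis):
        with pytest.raises(ValueError):
            locate_origin(canonical_axis, np.empty((0, 3)))


class TestRegisterRigid:
    def test_identical_clouds(self, rng):
        pts = rng.normal(scale=10, size=(200, 3))
        reg = register_rigid(pts, pts)
        # arccos is ill-conditioned at 0 rotation; check the matrix directly
        assert np.allclose(reg.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(reg.translation, 0, atol=1e-9)
        assert reg.rms < 1e-9
        assert reg.converged

    def test_known_transform_recovered(self):
        axis = AxisLine(anchor=[0, 0, 0], direction=[0, 1, 0])
        base = generate_shaft_points(axis, 8.0, 60.0, 800, seed=3)
        c, s = np.cos(np.radians(10)), np.sin(np.radians(10))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        truth = RigidTransform(rotation=R, translation=np.array([1.0, 2.0, 3.0]))
        reg = register_rigid(truth.inverse().apply(base), base)
        assert abs(reg.angle_deg() - 10.0) < 1e-6
        assert np.max(np.abs(reg.translation - truth.translation)) < 1e-6
        assert reg.rms < 1e-9

    def test_noisy_residual_scale(self):
        axis = AxisLine(anchor=[0, 0, 0], direction=[0, 1, 0])
        base = generate_shaft_points(axis, 8.0, 60.0, 10000, seed=4)
        c, s = np.cos(np.radians(10)), np.sin(np.radians(10))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        truth = RigidTransform(rotation=R, translation=np.array([1.0, 2.0, 3.0]))
        noisy = truth.inverse().apply(base) + np.random.default_rng(5).normal(0, 0.3, base.shape)
        reg = register_rigid(noisy, base)
        assert 0.2 <= reg.rms <= 0.45

    def test_non_convergence_flagged(self, rng):
        axis = AxisLine(anchor=[0, 0, 0], direction=[0, 1, 0])
        base = generate_shaft_points(axis, 8.0, 60.0, 500, seed=6)
        R = random_rotation(rng)
        reg = register_rigid(base @ R.T + [5, 5, 5], base, max_iter=1)
        assert not reg.converged
        assert reg.rms > 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            register_rigid(np.zeros((5, 3)), np.zeros((20, 3)))


class TestToFrame:
    def test_origin_maps_to_zero(self):
        frame = AnatomicalFrame.identity()
        assert to_frame(frame, [0, 0, 0]).as_array() == pytest.approx([0, 0, 0])

    def test_identity_frame_passthrough(self):
        frame = AnatomicalFrame.identity()
        assert to_frame(frame, [1, 2, 3]).as_array() == pytest.approx([1, 2, 3])

    def test_round_trip(self, rng):
        for _ in range(10):
            R = random_rotation(rng)
            frame = AnatomicalFrame(origin=rng.normal(size=3), ex=R[0], ey=R[1], ez=R[2])
            p = rng.normal(scale=30, size=3)
            back = from_frame(frame, to_frame(frame, p))
            assert np.max(np.abs(back - p)) < 1e-12

    def test_isometry(self, rng):
        R = random_rotation(rng)
        frame = AnatomicalFrame(origin=rng.normal(size=3), ex=R[0], ey=R[1], ez=R[2])
        a, b = rng.normal(scale=30, size=3), rng.normal(scale=30, size=3)
        d_lab = np.linalg.norm(a - b)
        d_frame = np.linalg.norm(to_frame(frame, a).as_array() - to_frame(frame, b).as_array())
        assert abs(d_lab - d_frame) < 1e-9


class TestRigidTransform:
    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.eye(3) * 2.0, translation=np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]), translation=np.zeros(3))

    def test_inverse_composition(self, rng):
        R = random_rotation(rng)
        t = RigidTransform(rotation=R, translation=rng.normal(size=3))
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-12)


class TestPoint3:
    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            Point3(np.nan, 0.0, 0.0)

    def test_array_round_trip(self):
        p = Point3(1.5, -2.0, 3.25)
        assert Point3.from_array(p.as_array()) == p
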