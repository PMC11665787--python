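"""Rigid transforms, the tracking chain, pixel mapping, and PnP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lusrecon import (
    CameraIntrinsics,
    ChainIncompatibilityError,
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    PatternGeometry,
    RigidTransform,
    UltrasoundFrame,
    ValidationError,
    compose_chain,
    invert,
    pixel_to_world,
    pose_from_keypoints,
    project_points,
    transform_points,
    undistort_points,
)


def random_rigid(rng, from_frame="A", to_frame="B", t_scale=50.0):
    r = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-t_scale, t_scale, 3)
    return RigidTransform.from_rotation_translation(r, t, from_frame, to_frame)


class TestRigidTransform:
    def test_rotation_must_be_orthonormal(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(ValidationError, match="orthonormal"):
            RigidTransform(m)

    def test_reflection_rejected(self):
        m = np.eye(4)
        m[0, 0] = -1.0
        with pytest.raises(ValidationError, match="determinant"):
            RigidTransform(m)

    def test_last_row_enforced(self):
        m = np.eye(4)
        m[3, 0] = 0.5
        with pytest.raises(ValidationError, match="last row"):
            RigidTransform(m)


class TestComposeChain:
    def test_identity_composition(self):
        chain = [
            RigidTransform.identity("L", "O"),
            RigidTransform.identity("I", "L"),
            RigidTransform.identity("P", "I"),
            RigidTransform.identity("U", "P"),
        ]
        out = compose_chain(chain)
        assert np.array_equal(out.matrix, np.eye(4))
        assert (out.from_frame, out.to_frame) == ("U", "O")

    def test_commuting_translations(self):
        def trans(v, f, t):
            return RigidTransform.from_rotation_translation(np.eye(3), v, f, t)

        chain = [
            trans((1, 0, 0), "L", "O"),
            trans((0, 2, 0), "I", "L"),
            trans((0, 0, 3), "P", "I"),
            trans((0, 0, 0), "U", "P"),
        ]
        out = compose_chain(chain)
        np.testing.assert_allclose(out.translation, [1, 2, 3], atol=1e-15)

    def test_matches_matrix_product_oracle(self, rng):
        frames = ["O", "L", "I", "P", "U"]
        chain = [
            random_rigid(rng, from_frame=frames[k + 1], to_frame=frames[k])
            for k in range(4)
        ]
        expected = np.eye(4)
        for t in chain:  # element-by-element matrix multiplication oracle
            expected = expected @ t.matrix
        out = compose_chain(chain)
        np.testing.assert_allclose(out.matrix, expected, atol=1e-10)

    def test_label_mismatch_names_pair(self):
        chain = [RigidTransform.identity("L", "O"), RigidTransform.identity("P", "I")]
        with pytest.raises(ChainIncompatibilityError, match="'L'.*'I'"):
            compose_chain(chain)

    def test_associativity(self, rng):
        for _ in range(5):
            a, b, c = (random_rigid(rng, "", "") for _ in range(3))
            ab_c = compose_chain([compose_chain([a, b]), c])
            a_bc = compose_chain([a, compose_chain([b, c])])
            np.testing.assert_allclose(ab_c.matrix, a_bc.matrix, atol=1e-10)


class TestInvert:
    def test_identity(self):
        t = RigidTransform.identity("A", "B")
        assert np.array_equal(invert(t).matrix, np.eye(4))

    def test_translation(self):
        t = RigidTransform.from_rotation_translation(np.eye(3), (1, 2, 3), "A", "B")
        np.testing.assert_allclose(invert(t).translation, [-1, -2, -3], atol=1e-15)

    def test_inverse_times_original_is_identity(self, rng):
        t = random_rigid(rng)
        prod = invert(t).matrix @ t.matrix
        np.testing.assert_allclose(prod, np.eye(4), atol=1e-10)

    def test_involution_and_label_swap(self, rng):
        t = random_rigid(rng, "U", "O")
        tt = invert(invert(t))
        np.testing.assert_allclose(tt.matrix, t.matrix, atol=1e-10)
        assert invert(t).from_frame == "O" and invert(t).to_frame == "U"


class TestTransformPoints:
    def test_identity(self, rng):
        pts = rng.uniform(-10, 10, (20, 3))
        np.testing.assert_array_equal(
            transform_points(RigidTransform.identity(), pts), pts
        )

    def test_rotation_90_about_z(self):
        r = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = RigidTransform.from_rotation_translation(r, (0, 0, 0))
        np.testing.assert_allclose(transform_points(t, [1, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_homogeneous_multiply_oracle(self, rng):
        t = random_rigid(rng)
        pts = rng.uniform(-100, 100, (100, 3))
        hom = np.column_stack([pts, np.ones(100)])
        expected = (t.matrix @ hom.T).T[:, :3]
        np.testing.assert_allclose(transform_points(t, pts), expected, atol=1e-10)

    def test_preserves_distances_and_handedness(self, rng):
        t = random_rigid(rng)
        pts = rng.uniform(-50, 50, (30, 3))
        out = transform_points(t, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)
        v_in = np.linalg.det(np.stack([pts[1] - pts[0], pts[2] - pts[0], pts[3] - pts[0]]))
        v_out = np.linalg.det(np.stack([out[1] - out[0], out[2] - out[0], out[3] - out[0]]))
        assert np.sign(v_in) == np.sign(v_out)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            transform_points(RigidTransform.identity(), [[np.nan, 0, 0]])


class TestPixelToWorld:
    def test_origin_pixel(self):
        f = UltrasoundFrame(np.zeros((4, 4)), 1.0, 1.0, pose=RigidTransform.identity("U", "O"))
        np.testing.assert_array_equal(pixel_to_world(f, [[0, 0]]), [[0, 0, 0]])

    def test_anisotropic_scaling(self):
        f = UltrasoundFrame(
            np.zeros((20, 20)), 0.2, 0.3, pose=RigidTransform.identity("U", "O")
        )
        # (col=10, row=5): x = 10*0.3 = 3.0, y = 5*0.2 = 1.0
        np.testing.assert_allclose(pixel_to_world(f, [[10, 5]]), [[3.0, 1.0, 0.0]], atol=1e-15)

    def test_scale_then_transform_oracle(self, rng):
        pose = random_rigid(rng, "U", "O")
        f = UltrasoundFrame(np.zeros((6, 7)), 0.25, 0.4, pose=pose)
        out = pixel_to_world(f)
        rows, cols = np.mgrid[0:6, 0:7]
        pts_u = np.column_stack(
            [cols.ravel() * 0.4, rows.ravel() * 0.25, np.zeros(42)]
        )
        expected = pts_u @ pose.rotation.T + pose.translation
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_missing_pose_rejected(self):
        f = UltrasoundFrame(np.zeros((4, 4)), 1.0, 1.0)
        with pytest.raises(ValidationError, match="pose"):
            pixel_to_world(f)


@pytest.fixture
def camera():
    return CameraIntrinsics(fx=1000.0, fy=1000.0, cx=320.0, cy=240.0, width=640, height=480)


class TestPoseFromKeypoints:
    def test_exact_recovery_nonplanar(self, camera, rng):
        pattern = PatternGeometry(rng.uniform(-12, 12, (8, 3)))
        r = Rotation.from_euler("xyz", [15, -10, 40], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 110.0])
        pose = RigidTransform.from_rotation_translation(r, t, "P", "I")
        res = pose_from_keypoints(camera, pattern, project_points(camera, pose, pattern.points))
        assert np.linalg.norm(res.pose.rotation - r) < 1e-6
        assert np.linalg.norm(res.pose.translation - t) < 1e-6
        assert res.residual_px < 1e-6

    def test_exact_recovery_planar(self, camera, rng):
        pts = np.column_stack([rng.uniform(-10, 10, (6, 2)), np.zeros(6)])
        pattern = PatternGeometry(pts)
        r = Rotation.from_euler("xyz", [-20, 12, 5], degrees=True).as_matrix()
        t = np.array([-3.0, 6.0, 90.0])
        pose = RigidTransform.from_rotation_translation(r, t, "P", "I")
        res = pose_from_keypoints(camera, pattern, project_points(camera, pose, pattern.points))
        assert np.linalg.norm(res.pose.rotation - r) < 1e-6
        assert np.linalg.norm(res.pose.translation - t) < 1e-6

    def test_frontal_translation_recovered(self, camera, rng):
        pattern = PatternGeometry(rng.uniform(-15, 15, (8, 3)))
        pose = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 100), "P", "I")
        res = pose_from_keypoints(camera, pattern, project_points(camera, pose, pattern.points))
        np.testing.assert_allclose(res.pose.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(res.pose.translation, [0, 0, 100], atol=1e-6)

    def test_too_few_points(self, camera):
        pattern = PatternGeometry([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 5]])
        with pytest.raises(InsufficientCorrespondencesError):
            pose_from_keypoints(camera, pattern, np.zeros((3, 2)))

    def test_collinear_pattern_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            PatternGeometry([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])

    def test_noisy_recovery_monte_carlo(self, camera):
        # median translation error below 2% of the camera distance at 0.5 px noise
        rng = np.random.default_rng(77)
        pattern = PatternGeometry(rng.uniform(-15, 15, (8, 3)))
        errors = []
        for _ in range(100):
            r = Rotation.random(rng=rng).as_matrix()
            t = np.array([rng.uniform(-20, 20), rng.uniform(-20, 20), rng.uniform(80, 150)])
            pose = RigidTransform.from_rotation_translation(r, t, "P", "I")
            det = project_points(camera, pose, pattern.points)
            det = det + rng.normal(0, 0.5, det.shape)
            res = pose_from_keypoints(camera, pattern, det)
            errors.append(np.linalg.norm(res.pose.translation - t) / np.linalg.norm(t))
        assert np.median(errors) < 0.02


def test_undistort_inverts_radial_model():
    intr = CameraIntrinsics(800, 800, 320, 240, 640, 480, distortion=(-0.2, 0.05))
    rng = np.random.default_rng(5)
    undist = rng.uniform([100, 100], [540, 380], (50, 2))
    # forward-distort, then undistort back
    x = (undist[:, 0] - intr.cx) / intr.fx
    y = (undist[:, 1] - intr.cy) / intr.fy
    r2 = x**2 + y**2
    factor = 1 + intr.distortion[0] * r2 + intr.distortion[1] * r2**2
    distorted = np.column_stack([x * factor * intr.fx + intr.cx, y * factor * intr.fy + intr.cy])
    np.testing.assert_allclose(undistort_points(intr, distorted), undist, atol=1e-6)
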