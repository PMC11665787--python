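"""Pressure-compensation: surface fit, displacement, decay model, matching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lusrecon import (
    DecayEstimate,
    DegenerateGeometryError,
    DisplacementProfile,
    DomainError,
    FeatureMatchSet,
    RigidTransform,
    UltrasoundFrame,
    ValidationError,
    compensate_frame,
    compute_displacement_profile,
    decay_shift,
    estimate_decay_depths,
    extract_contact_line,
    fit_reference_surface,
    match_features,
    pixel_to_world,
)
from lusrecon.pressure import filter_matches_ransac


def make_frame(image, pose=None, s_ax=1.0, s_lat=1.0):
    if pose is None:
        pose = RigidTransform.identity("U", "O")
    return UltrasoundFrame(image, s_ax, s_lat, pose=pose)


# ---------------------------------------------------------------------
# Reference surface
# ---------------------------------------------------------------------


class TestReferenceSurface:
    def test_exact_plane(self, rng):
        pts = np.column_stack([rng.uniform(0, 20, (30, 2)), np.full(30, 5.0)])
        surf = fit_reference_surface(pts, model_order=1)
        assert surf.residual_rms_mm < 1e-12
        np.testing.assert_allclose(surf.evaluate([[3.0, 7.0], [11.0, 2.0]]), [5.0, 5.0], atol=1e-10)

    def test_quadratic_recovery(self, rng):
        xy = rng.uniform(-5, 5, (60, 2))
        z = xy[:, 0] ** 2 + xy[:, 1]
        surf = fit_reference_surface(np.column_stack([xy, z]), model_order=2)
        assert surf.residual_rms_mm < 1e-9
        # term order: 1, y, x, y^2, xy, x^2
        np.testing.assert_allclose(surf.coefficients, [0, 1, 0, 0, 0, 1], atol=1e-9)

    def test_noisy_residual_tracks_noise_level(self):
        # sigma = 0.5 mm -> residual RMS in [0.3, 0.7] mm across trials
        rng = np.random.default_rng(99)
        rms = []
        for _ in range(50):
            xy = rng.uniform(-10, 10, (80, 2))
            z = 5 + 0.05 * xy[:, 0] ** 2 - 0.3 * xy[:, 1] + rng.normal(0, 0.5, 80)
            surf = fit_reference_surface(np.column_stack([xy, z]), model_order=2)
            rms.append(surf.residual_rms_mm)
        assert 0.3 < np.median(rms) < 0.7
        assert all(0.3 < r < 0.7 for r in rms)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            fit_reference_surface(np.zeros((4, 3)), model_order=2)

    def test_collinear_samples_degenerate(self):
        x = np.linspace(0, 10, 20)
        pts = np.column_stack([x, x, np.ones(20)])
        with pytest.raises(DegenerateGeometryError):
            fit_reference_surface(pts, model_order=2)


# ---------------------------------------------------------------------
# Contact line + displacement profile
# ---------------------------------------------------------------------


class TestContactLine:
    def test_identity_pose_unit_spacing(self):
        f = make_frame(np.zeros((4, 5)))
        line = extract_contact_line(f)
        np.testing.assert_allclose(line.points, [[c, 0, 0] for c in range(5)], atol=1e-15)

    def test_translated_pose(self):
        pose = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 10), "U", "O")
        line = extract_contact_line(make_frame(np.zeros((4, 5)), pose=pose))
        np.testing.assert_allclose(line.points, [[c, 0, 10] for c in range(5)], atol=1e-15)

    def test_consistent_with_pixel_to_world(self, rng):
        r = Rotation.random(rng=rng).as_matrix()
        pose = RigidTransform.from_rotation_translation(r, rng.uniform(-5, 5, 3), "U", "O")
        f = make_frame(np.zeros((8, 6)), pose=pose, s_ax=0.2, s_lat=0.35)
        line = extract_contact_line(f)
        expected = pixel_to_world(f, np.column_stack([np.arange(6), np.zeros(6)]))
        np.testing.assert_allclose(line.points, expected, atol=1e-12)


class TestDisplacementProfile:
    def _flat_surface(self, height=0.0):
        pts = np.column_stack(
            [np.mgrid[0:10, 0:10].reshape(2, -1).T.astype(float), np.full(100, height)]
        )
        return fit_reference_surface(pts, model_order=1)

    def test_line_on_surface_gives_zero(self):
        surf = self._flat_surface(0.0)
        f = make_frame(np.zeros((4, 5)))
        prof = compute_displacement_profile(extract_contact_line(f), surf)
        np.testing.assert_allclose(prof.d, 0.0, atol=1e-10)

    def test_indented_line_below_flat_surface(self):
        surf = self._flat_surface(0.0)
        pose = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 3), "U", "O")
        prof = compute_displacement_profile(
            extract_contact_line(make_frame(np.zeros((4, 5)), pose=pose)), surf
        )
        np.testing.assert_allclose(prof.d, 3.0, atol=1e-10)
        assert prof.valid.all() and not prof.clamped.any()

    def test_line_above_surface_clamped(self):
        surf = self._flat_surface(5.0)
        prof = compute_displacement_profile(
            extract_contact_line(make_frame(np.zeros((4, 5)))), surf
        )
        np.testing.assert_array_equal(prof.d, 0.0)
        assert prof.clamped.all()

    def test_quadratic_closed_form_oracle(self, rng):
        xy = rng.uniform(0, 30, (100, 2))
        z = 2.0 + 0.01 * xy[:, 0] ** 2 + 0.1 * xy[:, 1]
        surf = fit_reference_surface(np.column_stack([xy, z]), model_order=2)
        pose = RigidTransform.from_rotation_translation(np.eye(3), (5.0, 12.0, 9.0), "U", "O")
        f = make_frame(np.zeros((4, 20)), pose=pose, s_lat=0.5)
        prof = compute_displacement_profile(extract_contact_line(f), surf)
        x = 5.0 + np.arange(20) * 0.5
        expected = 9.0 - (2.0 + 0.01 * x**2 + 0.1 * 12.0)
        np.testing.assert_allclose(prof.d, np.clip(expected, 0, None), atol=1e-9)

    def test_footprint_outside_domain(self):
        surf = self._flat_surface(0.0)
        pose = RigidTransform.from_rotation_translation(np.eye(3), (100, 100, 1), "U", "O")
        with pytest.raises(DomainError):
            compute_displacement_profile(
                extract_contact_line(make_frame(np.zeros((4, 5)), pose=pose)), surf
            )


# ---------------------------------------------------------------------
# Decay model
# ---------------------------------------------------------------------


class TestDecayShift:
    def test_surface_value_is_d(self):
        assert decay_shift(0.0, 4.0, 30.0) == 4.0

    def test_half_depth_is_d_over_e(self):
        assert abs(decay_shift(15.0, 4.0, 30.0) - 4.0 / np.e) < 1e-12

    def test_zero_at_and_beyond_c(self):
        assert decay_shift(30.0, 4.0, 30.0) == 0.0
        assert decay_shift(55.0, 4.0, 30.0) == 0.0

    def test_near_c_matches_direct_evaluation(self):
        z, d, c = 0.99 * 40.0, 5.0, 40.0
        direct = d * np.exp(-z / (c - z))
        assert abs(decay_shift(z, d, c) - direct) < 1e-12
        assert decay_shift(z, d, c) < 1e-40 * d

    def test_negative_inputs_rejected(self):
        for z, d, c in [(-1, 1, 10), (1, -1, 10), (1, 1, 0)]:
            with pytest.raises(ValidationError):
                decay_shift(z, d, c)

    @pytest.mark.parametrize("d,c", [(0.0, 20.0), (2.0, 15.0), (6.0, 40.0), (5.0, 120.0)])
    def test_compensation_map_strictly_increasing(self, d, c):
        z = np.linspace(0, 60, 5000)
        g = z - decay_shift(z, d, c)
        assert np.all(np.diff(g) > 0)

    def test_shift_monotone_decreasing_in_depth(self):
        z = np.linspace(0, 29.9, 2000)
        dz = decay_shift(z, 5.0, 30.0)
        assert np.all(np.diff(dz) <= 0)


# ---------------------------------------------------------------------
# Frame compensation
# ---------------------------------------------------------------------


def uniform_profile(width, d):
    return DisplacementProfile(
        d=np.full(width, float(d)),
        clamped=np.zeros(width, bool),
        valid=np.ones(width, bool),
    )


class TestCompensateFrame:
    def test_zero_displacement_is_identity(self, rng):
        img = rng.random((40, 16))
        f = make_frame(img, s_ax=0.5, s_lat=0.5)
        out = compensate_frame(f, uniform_profile(16, 0.0), DecayEstimate(30.0))
        np.testing.assert_allclose(out.image, img, atol=1e-12)
        assert out.row0_offset_mm == 0.0

    def test_surface_pixel_moves_up_by_d(self):
        img = np.zeros((40, 8))
        img[0, 4] = 1.0  # bright pixel at the transducer face
        f = make_frame(img, s_ax=1.0)
        out = compensate_frame(f, uniform_profile(8, 4.0), DecayEstimate(30.0))
        # canvas grew by 4 rows; the pixel should sit at depth -4 mm = row 0
        assert out.row0_offset_mm == -4.0
        assert out.image[0, 4] == pytest.approx(1.0, abs=1e-9)

    def test_forward_then_inverse_round_trip(self, clean_truth, clean_sim):
        # compensating a noise-free deformed frame with the true (d, c)
        # recovers the rest-shape slice to within interpolation error
        from scipy.ndimage import map_coordinates

        spec = clean_truth.spec
        k = 3
        fr = clean_sim.frames[k]
        w = fr.width
        prof = DisplacementProfile(
            d=clean_sim.true_d_profiles[k],
            clamped=np.zeros(w, bool),
            valid=np.ones(w, bool),
        )
        out = compensate_frame(fr, prof, DecayEstimate(clean_sim.true_c[k]))
        h2 = out.height
        z_out = np.arange(h2) * spec.axial_spacing + out.row0_offset_mm
        x = spec.probe_x0 + np.arange(w) * spec.lateral_spacing
        y = spec.sweep_y0 + k * spec.frame_step_mm
        t_z = fr.pose.translation[2]
        pts = np.stack(
            [
                np.broadcast_to(x, (h2, w)),
                np.full((h2, w), y),
                t_z + np.broadcast_to(z_out[:, None], (h2, w)),
            ]
        )
        ref = map_coordinates(clean_truth.imaging_volume, pts / clean_truth.spacing, order=1, mode="nearest")
        interior = out.valid_mask.copy()
        interior[:4] = False
        interior[-4:] = False
        err = np.abs(out.image - ref)[interior].mean()
        assert err < 0.02  # 2% of the [0, 1] dynamic range

    def test_width_mismatch_rejected(self):
        f = make_frame(np.zeros((10, 8)))
        with pytest.raises(ValidationError):
            compensate_frame(f, uniform_profile(5, 1.0), DecayEstimate(30.0))


# ---------------------------------------------------------------------
# Feature matching
# ---------------------------------------------------------------------


class TestMatchFeatures:
    def test_self_match_depths_equal(self, small_sim):
        f = small_sim.frames[4]
        matches = match_features(f, f)
        c0, p0, c1, p1 = matches.inlier_arrays()
        assert len(p0) >= 4
        np.testing.assert_allclose(p0, p1, atol=1e-9)
        np.testing.assert_allclose(c0, c1, atol=1e-9)

    def test_axial_shift_recovered(self, small_sim):
        f = small_sim.frames[4]
        shifted = UltrasoundFrame(
            np.roll(f.image, 3, axis=0),
            f.axial_spacing_mm,
            f.lateral_spacing_mm,
            pose=f.pose,
            frame_id=99,
        )
        matches = match_features(f, shifted)
        _, p0, _, p1 = matches.inlier_arrays()
        med = np.median(p1 - p0)
        assert abs(med - 3 * f.axial_spacing_mm) <= 0.5 * f.axial_spacing_mm

    def test_consensus_rejects_corrupted_matches(self):
        # synthetic match sets: 70% follow a rigid shift, 30% random
        rng = np.random.default_rng(31)
        rejected_fracs = []
        for _ in range(20):
            n = 60
            kp0 = rng.uniform(10, 140, (n, 2))
            kp1 = kp0 + np.array([2.0, -1.0])
            n_bad = 18
            bad = rng.choice(n, n_bad, replace=False)
            kp1[bad] += rng.uniform(5, 40, (n_bad, 2)) * rng.choice([-1, 1], (n_bad, 2))
            inliers = filter_matches_ransac(kp0, kp1, residual_threshold_px=2.0)
            rejected_fracs.append(np.mean(~inliers[bad]))
        assert np.mean(rejected_fracs) >= 0.9


# ---------------------------------------------------------------------
# Decay-depth estimation
# ---------------------------------------------------------------------


def synthetic_matches(p0, p1, s_ax=0.1):
    n = len(p0)
    return FeatureMatchSet(
        cols0=np.zeros(n),
        rows0=np.asarray(p0) / s_ax,
        cols1=np.zeros(n),
        rows1=np.asarray(p1) / s_ax,
        p0_mm=np.asarray(p0, dtype=float),
        p1_mm=np.asarray(p1, dtype=float),
        inliers=np.ones(n, bool),
    )


def invert_forward_map(rest_depths, d, c):
    """Depth at which deformed content appears, given rest depth (oracle)."""
    z = np.linspace(0, 200, 20000)
    g = z - decay_shift(z, d, c)
    return np.interp(rest_depths, g, z)


class TestEstimateDecayDepths:
    def test_degenerate_symmetric_case_returns_midpoint(self):
        p = np.array([5.0, 8.0, 12.0])
        m = synthetic_matches(p, p)
        e0, e1 = estimate_decay_depths(m, 3.0, 3.0, (10.0, 50.0))
        assert e0.c_mm == e1.c_mm == pytest.approx(30.0)
        assert e0.objective == 0.0 and e0.converged

    def test_parameter_recovery_no_noise(self):
        rng = np.random.default_rng(8)
        errs = []
        for _ in range(20):
            c0, c1 = rng.uniform(20, 60, 2)
            d0, d1 = rng.uniform(3, 6), rng.uniform(0.5, 2.5)
            w = rng.uniform(1, 0.7 * min(c0, c1), 30)
            m = synthetic_matches(invert_forward_map(w, d0, c0), invert_forward_map(w, d1, c1))
            e0, e1 = estimate_decay_depths(m, d0, d1, (10.0, 100.0))
            errs += [abs(e0.c_mm - c0) / c0, abs(e1.c_mm - c1) / c1]
        assert np.median(errs) < 0.10

    def test_recovery_improves_with_more_matches(self):
        # relative error of c decreases as the number of matches grows
        rng = np.random.default_rng(21)
        med_errs = []
        for n_matches in (4, 16, 64):
            errs = []
            for _ in range(15):
                c0, c1 = rng.uniform(25, 50, 2)
                d0, d1 = 5.0, 1.5
                w = rng.uniform(1, 0.7 * min(c0, c1), n_matches)
                p0 = invert_forward_map(w, d0, c0) + rng.normal(0, 0.05, n_matches)
                p1 = invert_forward_map(w, d1, c1) + rng.normal(0, 0.05, n_matches)
                m = synthetic_matches(np.clip(p0, 0, None), np.clip(p1, 0, None))
                e0, e1 = estimate_decay_depths(m, d0, d1, (10.0, 100.0))
                errs += [abs(e0.c_mm - c0) / c0, abs(e1.c_mm - c1) / c1]
            med_errs.append(np.median(errs))
        assert med_errs[2] < med_errs[0]

    def test_single_pair_objective_grid_oracle(self):
        c_true, d0, d1 = 40.0, 5.0, 2.0
        w = np.array([10.0])
        p0 = invert_forward_map(w, d0, c_true)
        p1 = invert_forward_map(w, d1, c_true)

        def objective(c):
            s0 = p0 - decay_shift(p0, d0, c)
            s1 = p1 - decay_shift(p1, d1, c)
            return float(np.sum((s0 - s1) ** 2))

        assert objective(c_true) < objective(15.0)
        assert objective(c_true) < objective(100.0)

    def test_empty_inliers_falls_back(self):
        m = synthetic_matches([5.0], [5.0])
        object.__setattr__(m, "inliers", np.zeros(1, bool))
        e0, e1 = estimate_decay_depths(m, 1.0, 1.0, (10.0, 50.0), imaging_depth_mm=45.0)
        assert not e0.converged and e0.c_mm == 45.0 and e1.c_mm == 45.0

    def test_face_offset_restores_consistency(self):
        # frames whose transducer faces differ in height by (d0 - d1)
        rng = np.random.default_rng(3)
        c0, c1, d0, d1 = 35.0, 30.0, 5.0, 1.5
        w = rng.uniform(7, 25, 30)  # rest depth below the reference surface
        # rest depth below each face: w - d
        p0 = invert_forward_map(w - d0, d0, c0)
        p1 = invert_forward_map(w - d1, d1, c1)
        off = np.full(30, d0 - d1)  # face0 sits (d0 - d1) deeper than face1
        e0, e1 = estimate_decay_depths(m := synthetic_matches(p0, p1), d0, d1, (10.0, 100.0), face_offset_mm=off)
        assert abs(e0.c_mm - c0) / c0 < 0.05
        assert abs(e1.c_mm - c1) / c1 < 0.05
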