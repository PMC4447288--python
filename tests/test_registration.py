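"""Cuboid mapping, surface points, TPS fitting, resampling, full pipeline."""

import numpy as np
import pytest

import torsonorm as tn
from torsonorm.registration import cuboid_pullback, z_segments
from conftest import small_config


def _planes(**kw):
    defaults = dict(ns_z=40, th_z=8, bl_z=14, lv_z=30,
                    ac_left_x=6, ac_right_x=40, a_y=5, p_y=42)
    defaults.update(kw)
    return tn.TorsoPlanes(**defaults)


def _landmarks(**kw):
    return tn.assemble_landmarks(_planes(**kw))


class TestCuboidMap:
    def test_identity_map_reproduces_input(self, phantom_small):
        vol, truth = phantom_small
        lm = truth.landmark_truth
        out = tn.map_cuboid(vol, lm, lm)
        assert np.array_equal(out.data, vol.data)

    def test_all_sixteen_corners_map_exactly(self):
        src = _landmarks()
        dst = _landmarks(ns_z=44, th_z=4, bl_z=18, lv_z=28,
                         ac_left_x=10, ac_right_x=36, a_y=8, p_y=38)
        # pull-back evaluated at each dst corner must give the src corner
        for name in src.points:
            got = cuboid_pullback(np.array([dst.points[name]], float), src, dst)[0]
            assert np.allclose(got, src.points[name], atol=1e-12), name

    def test_z_scaling_maps_landmarks_onto_counterparts(self):
        src = _planes()
        dst = _planes(ns_z=2 * src.ns_z - src.th_z)  # stretch NS slab in z
        src_lm, dst_lm = tn.assemble_landmarks(src), tn.assemble_landmarks(dst)
        pts = cuboid_pullback(dst_lm.as_array(), src_lm, dst_lm)
        assert np.allclose(pts, src_lm.as_array(), atol=1e-12)

    def test_slab_continuity_at_shared_planes(self):
        src = _planes()
        dst = _planes(ns_z=44, th_z=4, bl_z=18, lv_z=28)
        segs = z_segments(src.z_levels(), dst.z_levels())
        # adjacent slabs evaluated at the shared knot agree to < 1e-9
        for i, knot in enumerate(dst.z_levels()[1:-1], start=0):
            lo_a, lo_b = segs[i][2], segs[i][3]
            hi_a, hi_b = segs[i + 1][2], segs[i + 1][3]
            assert abs((lo_a * knot + lo_b) - (hi_a * knot + hi_b)) < 1e-9

    def test_ordering_violation_rejected(self):
        with pytest.raises(tn.ValidationError):
            _planes(bl_z=31)  # BL above LV

    def test_liver_apex_alignment_after_map(self, phantom_small, standard_small):
        # subject with a different physique: after the cuboid map its liver
        # apex must sit at the standard's LV plane (within a voxel)
        subj, struth = tn.generate_phantom(small_config(
            torso_height_scale=1.08, torso_width_scale=0.95, seed=4))
        body = tn.extract_body_mask(subj)
        planes, _ = tn.detect_all_planes(subj, body)
        out = tn.map_cuboid(subj, tn.assemble_landmarks(planes),
                            standard_small.landmarks,
                            out_shape=standard_small.grid_shape)
        out_body = tn.extract_body_mask(out)
        out_planes, _ = tn.detect_all_planes(out, out_body)
        std_lv = standard_small.landmarks.points["LV1"][2]
        assert abs(out_planes.lv_z - std_lv) <= 1


class TestSurfacePoints:
    def _disc_body(self, a, b, nz=12):
        n = 64
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disc = ((xx - 32) / a) ** 2 + ((yy - 32) / b) ** 2 <= 1
        return tn.BinaryMask(np.repeat(disc[:, :, None], nz, axis=2), (4, 4, 4))

    def test_circle_radius_recovered(self):
        body = self._disc_body(20, 20)
        sps = tn.place_surface_points(body, levels=[5], angular_step=15)
        assert len(sps) == 24
        d = np.linalg.norm(sps.points[:, :2] - 32.0, axis=1)
        assert np.all(np.abs(d - 20) <= 0.75)

    def test_ellipse_axes_recovered(self):
        body = self._disc_body(30, 15)
        sps = tn.place_surface_points(body, levels=[5], angular_step=15)
        p0 = sps.points[0]   # angle 0 -> +x
        p90 = sps.points[6]  # 90 degrees -> +y
        assert abs(abs(p0[0] - 32) - 30) <= 0.75
        assert abs(abs(p90[1] - 32) - 15) <= 0.75

    def test_cardinality_and_ordering(self):
        body = self._disc_body(10, 10)
        sps = tn.place_surface_points(body, levels=[3, 7], angular_step=15)
        assert len(sps) == 48
        assert sps.tags == [(lvl, k) for lvl in (3, 7) for k in range(24)]

    def test_empty_level_raises_with_level_name(self):
        body = self._disc_body(10, 10, nz=12)
        body.data[:, :, 9] = False
        with pytest.raises(tn.DetectionError, match="9"):
            tn.place_surface_points(body, levels=[9], angular_step=30)


def _phantom_surface(seed=0):
    vol, _ = tn.generate_phantom(small_config(seed=seed))
    body = tn.extract_body_mask(vol)
    return tn.place_surface_points(body, levels=[10, 16, 22, 28], angular_step=30)


class TestTps:
    def test_identity_fit(self):
        sps = _phantom_surface()
        t = tn.fit_tps(sps, sps, lam=0.0)
        assert np.abs(t.kernel_weights).max() < 1e-8
        assert np.allclose(t.affine_part, np.vstack([np.zeros(3), np.eye(3)]), atol=1e-8)

    def test_exact_interpolation_at_lambda_zero(self):
        src = _phantom_surface()
        rng = np.random.default_rng(5)
        dst_pts = src.points + rng.normal(0, 1.5, size=src.points.shape)
        dst = tn.SurfacePointSet(dst_pts, src.tags, src.angular_step, src.slice_levels)
        t = tn.fit_tps(src, dst, lam=0.0)
        residual = np.abs(t(src.points) - dst_pts).max()
        assert residual < 1e-6

    def test_recovers_known_affine(self):
        src = _phantom_surface()
        A = np.array([[1.1, 0.05, 0.0], [-0.02, 0.95, 0.01], [0.0, 0.03, 1.2]])
        b = np.array([2.0, -1.0, 0.5])
        dst_pts = src.points @ A.T + b
        dst = tn.SurfacePointSet(dst_pts, src.tags, src.angular_step, src.slice_levels)
        t = tn.fit_tps(src, dst, lam=0.0)
        probes = np.random.default_rng(6).uniform(0, 48, size=(100, 3))
        assert np.abs(t(probes) - (probes @ A.T + b)).max() < 1e-5
        assert np.abs(t.kernel_weights).max() < 1e-8

    def test_side_conditions(self):
        src = _phantom_surface()
        dst_pts = src.points + np.random.default_rng(7).normal(0, 1, src.points.shape)
        dst = tn.SurfacePointSet(dst_pts, src.tags, src.angular_step, src.slice_levels)
        t = tn.fit_tps(src, dst)
        assert np.abs(t.kernel_weights.sum(axis=0)).max() < 1e-8
        assert np.abs(t.anchors.T @ t.kernel_weights).max() < 1e-6

    def test_smoothing_residual_grows_with_lambda(self):
        src = _phantom_surface()
        dst_pts = src.points + np.random.default_rng(8).normal(0, 1, src.points.shape)
        dst = tn.SurfacePointSet(dst_pts, src.tags, src.angular_step, src.slice_levels)
        residuals = []
        for lam in (0.0, 1.0, 10.0):
            t = tn.fit_tps(src, dst, lam=lam)
            residuals.append(np.abs(t(src.points) - dst_pts).max())
        assert residuals[0] < residuals[1] < residuals[2]

    def test_degenerate_anchors_raise_solver_error(self):
        pts = np.zeros((8, 3))
        pts[:, 0] = np.arange(8)  # all anchors on one line
        tags = [(0, k) for k in range(8)]
        src = tn.SurfacePointSet(pts, tags, 45, [0])
        with pytest.raises(tn.SolverError):
            tn.fit_tps(src, src)


class TestResample:
    def test_identity_transform_exact(self, phantom_small):
        vol, _ = phantom_small
        out = tn.resample_nn(vol, tn.TpsTransform.identity())
        assert np.array_equal(out.data, vol.data)

    def test_translation_preserves_histogram_on_overlap(self, phantom_small):
        vol, _ = phantom_small
        t = tn.TpsTransform.from_affine(np.eye(3), np.array([3.0, 0.0, 0.0]))
        out = tn.resample_nn(vol, t)
        # output voxel v reads source v+3 -> overlap region comparison
        assert np.array_equal(out.data[:-3], vol.data[3:])

    def test_nn_never_invents_intensities(self, phantom_small):
        vol, _ = phantom_small
        t = tn.TpsTransform.from_affine(np.eye(3) * 1.31, np.array([-2.2, 1.7, 0.4]))
        out = tn.resample_nn(vol, t)
        src_vals = set(np.unique(vol.data)) | {np.float32(0.0)}
        assert set(np.unique(out.data)) <= src_vals


class TestStandardize:
    def test_self_standardization_idempotent(self, phantom_small, standard_small):
        vol, _ = phantom_small
        out, report = tn.standardize(vol, standard_small)
        assert float(np.abs(out.data - vol.data).mean()) < 0.05
        assert report.landmarks.points == standard_small.landmarks.points
        assert report.tps_residual < 1e-6

    def test_sex_mismatch_rejected(self, standard_small):
        vol, _ = tn.generate_phantom(small_config(sex="female"))
        with pytest.raises(tn.ValidationError, match="sex"):
            tn.standardize(vol, standard_small)

    def test_stage_error_carries_stage_name(self, standard_small):
        flat = tn.SuvVolume(np.full((48, 48, 48), 0.1), (4, 4, 4), sex="male")
        with pytest.raises(tn.StageError, match="body-extraction"):
            tn.standardize(flat, standard_small)

    def test_liver_centroids_cluster_after_standardization(self, standard_small):
        # dispersion reduction: jittered subjects' livers land on the standard
        base = small_config(noise_sd=0.05)
        centroids_before, centroids_after = [], []
        for vol, truth in tn.phantom_population(base, 6, seed=31):
            out, report = tn.standardize(vol, standard_small)
            liver = truth.organ_masks["liver"].astype(np.float32)
            lvol = tn.SuvVolume(liver, vol.spacing, sex=vol.sex)
            warped = tn.apply_registration(lvol, report).data > 0.5
            centroids_before.append(np.mean(np.nonzero(liver), axis=1))
            centroids_after.append(np.mean(np.nonzero(warped), axis=1))
        after = np.array(centroids_after)
        spread_after = np.abs(after - after.mean(axis=0)).max()
        before = np.array(centroids_before)
        spread_before = np.abs(before - before.mean(axis=0)).max()
        assert spread_after <= 2.0
        assert spread_after <= spread_before
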