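"""Denoising, centring, alignment, segmentation and scale standardisation."""

import numpy as np
import pytest
from matplotlib.colors import hsv_to_rgb

from berry3d import BerrySpec, ColouredPointCloud, generate, rgb_to_hsv
from berry3d.errors import EmptyCloudError, ScaleError, SegmentationError
from berry3d.preprocess import (
    PreprocessConfig,
    align_principal_axis,
    center_to_origin,
    denoise_by_hue,
    hue_mask,
    preprocess_cloud,
    segment_body_holder,
    standardize_scale,
)


def coloured(points, hue_deg):
    """Cloud with every point at the given hue (s = v = 0.8)."""
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    hsv = np.column_stack(
        [np.full(n, hue_deg % 360) / 360, np.full(n, 0.8), np.full(n, 0.8)]
    )
    rgb = np.round(hsv_to_rgb(hsv) * 255).astype(np.uint8)
    return rgb_to_hsv(ColouredPointCloud(points=points, colours_rgb=rgb))


def merge(*clouds):
    return rgb_to_hsv(
        ColouredPointCloud(
            points=np.vstack([c.points for c in clouds]),
            colours_rgb=np.vstack([c.colours_rgb for c in clouds]),
        )
    )


class TestHueMask:
    def test_plain_interval(self):
        assert hue_mask(np.array([10.0, 50.0]), [(0, 30)]).tolist() == [True, False]

    def test_wrapping_interval(self):
        m = hue_mask(np.array([355.0, 5.0, 180.0]), [(330, 30)])
        assert m.tolist() == [True, True, False]

    def test_full_circle(self):
        assert hue_mask(np.arange(0, 360, 7.0), [(0, 360)]).all()


class TestDenoise:
    def test_exact_hue_partition(self):
        rng = np.random.default_rng(0)
        red = coloured(rng.normal(size=(600, 3)), 0.0)
        green = coloured(rng.normal(size=(550, 3)), 120.0)
        cfg = PreprocessConfig(noise_hue_keep=((350, 30),), min_segment_points=10)
        kept = denoise_by_hue(merge(red, green), cfg)
        assert kept.n_points == 600

    def test_keep_everything_is_identity(self):
        cloud, _ = generate(BerrySpec(n_points=2_000, seed=9))
        cfg = PreprocessConfig(noise_hue_keep=((0, 360),))
        assert denoise_by_hue(rgb_to_hsv(cloud), cfg).n_points == cloud.n_points

    def test_generator_noise_removed_exactly(self):
        spec = BerrySpec(n_points=10_000, noise_fraction=0.05, seed=11)
        cloud, truth = generate(spec)
        kept = denoise_by_hue(rgb_to_hsv(cloud), PreprocessConfig())
        assert kept.n_points == int((truth.labels != "noise").sum())

    def test_too_few_survivors_raise(self):
        green = coloured(np.random.default_rng(1).normal(size=(800, 3)), 120.0)
        with pytest.raises(EmptyCloudError, match="empty after denoising"):
            denoise_by_hue(green, PreprocessConfig(noise_hue_keep=((350, 30),)))


class TestCenter:
    def test_single_point(self):
        c = center_to_origin(coloured([(5.0, 5.0, 5.0)], 0))
        np.testing.assert_allclose(c.points, [[0, 0, 0]], atol=1e-12)

    def test_two_points(self):
        c = center_to_origin(coloured([(0, 0, 0), (2, 0, 0)], 0))
        np.testing.assert_allclose(c.points, [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_idempotent(self):
        cloud, _ = generate(BerrySpec(n_points=2_000, seed=12))
        once = center_to_origin(cloud)
        twice = center_to_origin(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-9)


class TestAlign:
    def test_diagonal_segment_maps_to_z(self):
        t = np.linspace(-1, 1, 200)
        pts = np.column_stack([t, t, t])
        aligned, rot, degenerate = align_principal_axis(coloured(pts, 0))
        assert not degenerate
        assert np.abs(aligned.points[:, :2]).max() < 1e-9
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)

    def test_prolate_z_cloud_keeps_axis(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(3_000, 3)) * [1.0, 1.0, 6.0]
        aligned, rot, _ = align_principal_axis(coloured(pts, 0))
        # main axis must stay on z (up to the sample-covariance wobble of
        # the finite cloud); sign may flip
        assert abs(abs(rot[2, 2]) - 1.0) < 1e-5

    def test_degenerate_sphere_flagged(self):
        # octahedrally symmetrised sample: covariance exactly isotropic
        rng = np.random.default_rng(8)
        v = rng.normal(size=(800, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sym = np.vstack([v[:, perm] * sign
                         for perm in ([0, 1, 2], [1, 2, 0], [2, 0, 1])
                         for sign in ([1, 1, 1], [-1, -1, -1])])
        aligned, rot, degenerate = align_principal_axis(coloured(sym * 15, 0))
        assert degenerate
        np.testing.assert_array_equal(rot, np.eye(3))


class TestSegmentation:
    def test_exact_partition(self):
        rng = np.random.default_rng(3)
        red = coloured(rng.normal(size=(10_000, 3)), 0.0)
        blue = coloured(rng.normal(size=(2_000, 3)), 230.0)
        body, holder = segment_body_holder(merge(red, blue), PreprocessConfig())
        assert holder.n_points == 2_000
        assert body.n_points == 10_000

    def test_all_red_raises(self):
        red = coloured(np.random.default_rng(4).normal(size=(3_000, 3)), 0.0)
        with pytest.raises(SegmentationError, match="holder segment empty"):
            segment_body_holder(red, PreprocessConfig())

    def test_generator_labels_recovered_exactly(self):
        spec = BerrySpec(n_points=8_000, seed=13)
        cloud, truth = generate(spec)
        body, holder = segment_body_holder(rgb_to_hsv(cloud), PreprocessConfig())
        assert holder.n_points == int((truth.labels == "holder").sum())
        assert body.n_points == int((truth.labels == "berry").sum())


class TestScale:
    def test_scale_factor_arithmetic(self):
        rng = np.random.default_rng(5)
        body = coloured(rng.normal(size=(600, 3)) * [1, 1, 3], 0.0)
        hz = np.column_stack(
            [rng.normal(size=(600, 2)) * 0.1, rng.uniform(-2, 0, 600)]
        )
        # pin the holder extremes so the extent is exactly 2 units
        hz[0, 2], hz[1, 2] = -2.0, 0.0
        holder = coloured(hz, 230.0)
        out = standardize_scale(body, holder, PreprocessConfig())
        assert out.scale_factor == pytest.approx(19.0)

    def test_zero_extent_holder_raises(self):
        body = coloured(np.random.default_rng(6).normal(size=(600, 3)), 0.0)
        holder = coloured(np.zeros((600, 3)), 230.0)
        with pytest.raises(ScaleError):
            standardize_scale(body, holder, PreprocessConfig())

    def test_chain_scale_invariance(self):
        cloud, _ = generate(BerrySpec(n_points=8_000, seed=14))
        cfg = PreprocessConfig()
        a = preprocess_cloud(cloud, cfg)
        b = preprocess_cloud(cloud.with_points(cloud.points * 3.7), cfg)
        np.testing.assert_allclose(b.points, a.points, atol=1e-9)
        assert b.scale_factor == pytest.approx(a.scale_factor / 3.7)


class TestFullChain:
    def test_body_frame_invariants(self):
        cloud, _ = generate(BerrySpec(n_points=10_000, seed=15))
        body = preprocess_cloud(cloud, PreprocessConfig())
        np.testing.assert_allclose(
            body.points.mean(axis=0), 0.0, atol=1e-6 * body.body_height_mm
        )
        np.testing.assert_allclose(
            body.rotation @ body.rotation.T, np.eye(3), atol=1e-9
        )

    def test_height_recovered_at_arbitrary_sfm_scale(self):
        spec = BerrySpec(profile="cylinder", height_mm=31.0, radius_mm=10.0,
                         n_points=20_000, scale=0.013, seed=16)
        body = preprocess_cloud(generate(spec)[0], PreprocessConfig())
        assert body.body_height_mm == pytest.approx(31.0, abs=0.2)

    def test_known_rotation_recovered(self):
        from scipy.spatial.transform import Rotation

        spec = BerrySpec(n_points=15_000, seed=17)
        cloud, _ = generate(spec)
        r0 = Rotation.random(random_state=np.random.default_rng(7)).as_matrix()
        twin = preprocess_cloud(cloud, PreprocessConfig())
        body = preprocess_cloud(cloud.with_points(cloud.points @ r0.T),
                                PreprocessConfig())
        z = np.array([0.0, 0.0, 1.0])
        # the recovered growth axis (in input coordinates) must match the
        # unrotated twin's axis after undoing r0, to well under 0.1 deg
        axis_twin = twin.rotation.T @ z
        axis_rot = r0.T @ (body.rotation.T @ z)
        angle = np.degrees(np.arccos(np.clip(abs(axis_rot @ axis_twin), -1, 1)))
        assert angle < 0.1
        # and both sit close to the geometric symmetry axis of the berry
        ideal = np.degrees(np.arccos(np.clip(abs(axis_twin @ z), -1, 1)))
        assert ideal < 0.5
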