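"""Slice stack, bounding-box aspect, circularity and straightness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from berry3d import BerrySpec, generate, preprocess_cloud, PreprocessConfig
from berry3d.errors import DegenerateGeometryError
from berry3d.slices import (
    Slice,
    SliceStack,
    bbox_aspect,
    build_slices,
    circularity,
    largest_slice,
    polyline_straightness,
    straightness,
)
from berry3d._geometry import hull_measures, hull_polygon
from conftest import cylinder_surface, make_body, sphere_points


def slice_from_xy(xy: np.ndarray, z: float = 0.0) -> Slice:
    hull = hull_polygon(xy)
    area, perim, c = hull_measures(hull)
    return Slice(z_level=z, indices=np.arange(len(xy)), xy=xy, valid=True,
                 hull_area=area, hull_perimeter=perim,
                 centroid=np.array([c[0], c[1], z]), hull_xy=hull)


class TestBuildSlices:
    def test_cylinder_slice_areas(self):
        body = make_body(cylinder_surface(50_000, 10.0, 30.0, seed=1))
        stack = build_slices(body)
        areas = [s.hull_area for s in stack.slices if s.valid]
        np.testing.assert_allclose(areas, np.pi * 100, rtol=0.02)

    def test_cylinder_centroids_on_axis(self):
        body = make_body(cylinder_surface(50_000, 10.0, 30.0, seed=2))
        stack = build_slices(body)
        for s in stack.slices:
            if s.valid:
                assert np.linalg.norm(s.centroid[:2]) < 0.1

    def test_empty_slabs_marked_invalid(self):
        # two clusters with a gap: the in-between slabs hold no points
        rng = np.random.default_rng(3)
        lower = cylinder_surface(2_000, 10.0, 10.0, seed=3)
        upper = cylinder_surface(2_000, 10.0, 10.0, seed=4) + [0, 0, 20.0]
        stack = build_slices(make_body(np.vstack([lower, upper])), n_slices=100)
        assert any(not s.valid for s in stack.slices)
        # invalid slices are excluded from the largest-slice search
        assert stack.slices[stack.largest_index].valid


class TestLargestSlice:
    def test_cone_widens_downward(self):
        cloud, _ = generate(BerrySpec(profile="cone", radius_mm=12.0,
                                      height_mm=32.0, n_points=20_000, seed=4))
        body = preprocess_cloud(cloud, PreprocessConfig())
        stack = build_slices(body)
        first_valid = next(i for i, s in enumerate(stack.slices) if s.valid)
        # monotone radius: the widest slice is at the base (hull-area noise
        # between the bottom two slabs allows one slice of slack)
        assert stack.largest_index - first_valid <= 1

    def test_sphere_equator(self):
        body = make_body(sphere_points(30_000, 15.0, seed=5))
        stack = build_slices(body)
        assert abs(stack.largest_index - 50) <= 1

    def test_berry_profile_argmax(self):
        spec = BerrySpec(n_points=30_000, seed=6)
        cloud, truth = generate(spec)
        body = preprocess_cloud(cloud, PreprocessConfig())
        stack = build_slices(body)
        z_levels = np.array([s.z_level for s in stack.slices])
        z0 = body.points[:, 2].min()
        # ground-truth argmax of r(z)^2 along the profile
        zg = np.linspace(0, spec.height_mm, 2001)
        z_true = zg[np.argmax(truth.profile_radius(zg))]
        measured = stack.slices[stack.largest_index].z_level - z0
        slice_pitch = (stack.z_max - stack.z_min) / 100
        assert abs(measured - z_true) <= 2 * slice_pitch


class TestBBoxAspect:
    def test_axis_aligned_rectangle_exact(self):
        gx, gy = np.meshgrid(np.linspace(0, 4, 9), np.linspace(0, 2, 5))
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        assert bbox_aspect(slice_from_xy(xy)) == pytest.approx(2.0, abs=1e-12)

    def test_ellipse(self):
        t = np.random.default_rng(7).uniform(0, 2 * np.pi, 5_000)
        xy = np.column_stack([20 * np.cos(t), 10 * np.sin(t)])
        assert bbox_aspect(slice_from_xy(xy)) == pytest.approx(2.0, rel=0.02)

    def test_circle(self):
        t = np.random.default_rng(8).uniform(0, 2 * np.pi, 2_000)
        xy = np.column_stack([np.cos(t), np.sin(t)])
        assert bbox_aspect(slice_from_xy(xy)) == pytest.approx(1.0, abs=0.02)


class TestCircularity:
    def test_dense_circle(self):
        t = np.linspace(0, 2 * np.pi, 3_000, endpoint=False)
        xy = np.column_stack([np.cos(t), np.sin(t)])
        assert circularity(slice_from_xy(xy)) == pytest.approx(1.0, abs=0.005)

    def test_square_corners_exact(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert circularity(slice_from_xy(xy)) == pytest.approx(np.pi / 4, rel=1e-12)

    def test_hexagon_corners_exact(self):
        t = np.arange(6) * np.pi / 3
        xy = np.column_stack([np.cos(t), np.sin(t)])
        assert circularity(slice_from_xy(xy)) == pytest.approx(
            np.pi * np.sqrt(3) / 6, rel=1e-12
        )


class TestStraightness:
    def test_collinear_centroids(self):
        body = make_body(cylinder_surface(30_000, 10.0, 30.0, seed=9))
        stack = build_slices(body)
        assert straightness(stack) == pytest.approx(1.0, abs=1e-3)

    def test_semicircular_arc(self):
        """Centroid path on a semicircle: arc/chord = pi R / 2R = pi/2."""
        t = np.linspace(0, np.pi, 80)
        centroids = np.column_stack(
            [10 * np.sin(t), np.zeros_like(t), 10 - 10 * np.cos(t)]
        )
        assert polyline_straightness(centroids) == pytest.approx(np.pi / 2, rel=0.01)

    def test_sinusoidal_axis_matches_quadrature(self):
        from berry3d.synthetic import axis_straightness

        spec = BerrySpec(axis_amplitude_mm=3.0, axis_shape="sine",
                         n_points=30_000, seed=10)
        cloud, _ = generate(spec)
        body = preprocess_cloud(cloud, PreprocessConfig())
        measured = straightness(build_slices(body))
        assert measured == pytest.approx(axis_straightness(spec), rel=0.02)

    def test_invalid_slices_bridged(self):
        s_lo = slice_from_xy(np.random.default_rng(11).normal(size=(50, 2)), z=0.0)
        s_hi = slice_from_xy(np.random.default_rng(12).normal(size=(50, 2)), z=10.0)
        bad = Slice(z_level=5.0, indices=np.array([]), xy=np.empty((0, 2)),
                    valid=False)
        stack = SliceStack(slices=[s_lo, bad, s_hi], band_halfwidth_mm=1.0,
                           z_min=0.0, z_max=10.0)
        assert straightness(stack, 0.0, 1.0) >= 1.0

    def test_coincident_end_centroids_raise(self):
        s1 = slice_from_xy(np.array([[0, 0], [1, 0], [0, 1]], float), z=0.0)
        s2 = slice_from_xy(np.array([[0, 0], [1, 0], [0, 1]], float), z=0.0)
        stack = SliceStack(slices=[s1, s2], band_halfwidth_mm=1.0,
                           z_min=0.0, z_max=0.0)
        with pytest.raises(DegenerateGeometryError):
            straightness(stack, 0.0, 1.0)


@settings(derandomize=True, max_examples=30)
@given(
    arrays(np.float64, (25, 2), elements=st.floats(-50, 50)).filter(
        lambda a: hull_polygon(a) is not None
    )
)
def test_isoperimetric_and_aspect_floors(xy):
    """cir <= 1 and l_w >= 1 for any non-degenerate planar point set."""
    slc = slice_from_xy(xy)
    if slc.hull_area <= 0:
        return
    assert circularity(slc) <= 1.0 + 1e-9
    assert bbox_aspect(slc) >= 1.0
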