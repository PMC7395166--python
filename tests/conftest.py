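import numpy as np
import pytest

from berry3d.preprocess import BodyCloud


def make_body(points: np.ndarray) -> BodyCloud:
    """Wrap raw coordinates in a BodyCloud for direct metric-level tests."""
    points = np.asarray(points, dtype=np.float64)
    return BodyCloud(
        points=points,
        scale_factor=1.0,
        rotation=np.eye(3),
        body_height_mm=float(points[:, 2].max() - points[:, 2].min()),
        source_id="test",
    )


def brute_force_hull(points_2d: np.ndarray):
    """O(N^3) convex-hull oracle: an ordered pair (i, j) is a hull edge iff
    every other point lies strictly on its left.  Returns (area, perimeter)
    from the CCW-ordered hull vertices."""
    pts = np.asarray(points_2d, dtype=np.float64)
    n = len(pts)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.ones(n, dtype=bool)
            others[[i, j]] = False
            if np.all(cross[others] > 0):
                on_hull.add(i)
                on_hull.add(j)
    idx = np.array(sorted(on_hull))
    centre = pts[idx].mean(axis=0)
    order = np.argsort(np.arctan2(pts[idx, 1] - centre[1], pts[idx, 0] - centre[0]))
    v = pts[idx[order]]
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())
    return float(area), perim


def sphere_points(n: int, radius: float, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def cylinder_surface(n: int, radius: float, height: float, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


@pytest.fixture(scope="session")
def cylinder_body_50k() -> BodyCloud:
    """Dense noise-free cylinder: the canonical ideal solid of revolution."""
    return make_body(cylinder_surface(50_000, radius=10.0, height=30.0, seed=1))
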