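"""Small shared 2D geometry helpers: convex hulls and their measures."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

__all__ = ["hull_polygon", "hull_measures", "pca_axes_2d"]


def hull_polygon(points_2d: np.ndarray) -> np.ndarray | None:
    """Convex hull of 2D points as a CCW vertex array, or None if degenerate."""
    pts = np.asarray(points_2d, dtype=np.float64)
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # collinear or otherwise degenerate
    return pts[hull.vertices]


def hull_measures(
    vertices: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """(area, perimeter, centroid) of a convex polygon given CCW vertices.

    The centroid is the area centroid of the polygon (the contour moment),
    which is independent of how densely the source points sample the
    boundary.
    """
    poly = Polygon(vertices)
    c = poly.centroid
    return float(poly.area), float(poly.length), np.array([c.x, c.y])


def pca_axes_2d(points_2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues ascending, eigenvectors as columns) of 2D point covariance."""
    pts = np.asarray(points_2d, dtype=np.float64)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    return np.linalg.eigh(cov)
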