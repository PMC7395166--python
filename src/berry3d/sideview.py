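"""Rotational side-view metrics: CV_A, Max_A/Min_A and CV_D.

A perfectly uniform berry is a solid of revolution about its growth axis:
every side view is identical.  To quantify deviation from that ideal, the
equatorial band (the middle 50% of the body height, which excludes calyx and
nose artefacts) is rotated about z in ``360/n_views`` degree increments
(3.6 degrees for the default 100 views) and projected onto the x–z plane.
Each projection contributes

* the area of its 2D convex hull — dispersion of these areas gives CV_A and
  the max/min ratio Max_A/Min_A;
* the orientation of its first principal axis — dispersion of these angles
  gives CV_D.

Orientation convention: per-view principal axes are axial quantities
(defined mod 180 degrees, eigenvector sign-free).  Each view's axis is
expressed as its signed deviation from the circular-mean axis of all views,
offset by +90 degrees so the mean sits near 90 and the coefficient of
variation is well defined for every body orientation; an ideal solid of
revolution then scores CV_D = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import hull_polygon, pca_axes_2d
from .errors import DegenerateGeometryError, EmptyCloudError
from .preprocess import BodyCloud
from shapely.geometry import Polygon

__all__ = [
    "SideViewSet",
    "AreaMetrics",
    "equatorial_band",
    "project_side_views",
    "area_metrics",
    "orientation_cv",
]


@dataclass
class SideViewSet:
    """Hull areas and principal-orientation angles of the rotational views."""

    n_views: int
    step_deg: float
    areas: np.ndarray        # (n_views,) mm^2
    angles_deg: np.ndarray   # (n_views,) axial angle in [0, 180)

    def __post_init__(self) -> None:
        assert abs(self.n_views * self.step_deg - 360.0) < 1e-9


@dataclass
class AreaMetrics:
    cv_a: float
    max_min_a: float


def equatorial_band(
    body: BodyCloud, lower_frac: float = 0.25, upper_frac: float = 0.75
) -> BodyCloud:
    """Points within the middle band of the body height (default middle 50%)."""
    z = body.points[:, 2]
    z0, z1 = z.min(), z.max()
    h = z1 - z0
    if h <= 0:
        raise DegenerateGeometryError("body has zero height; no equatorial band")
    keep = (z >= z0 + lower_frac * h) & (z <= z0 + upper_frac * h)
    if not keep.any():
        raise EmptyCloudError("equatorial band contains no points")
    return body.with_points(body.points[keep])


def _principal_angle(points_2d: np.ndarray) -> float:
    """Axial angle (degrees in [0, 180)) of the major principal direction."""
    _, vecs = pca_axes_2d(points_2d)
    v = vecs[:, 1]  # largest eigenvalue
    return float(np.degrees(np.arctan2(v[0], v[1])) % 180.0)


def project_side_views(band: BodyCloud | np.ndarray, n_views: int = 100) -> SideViewSet:
    """Rotate the band about z and project each view onto the x–z plane.

    The projection of a point set is invariant to a 180-degree rotation
    (the silhouette seen from behind mirrors the one seen from the front and
    has the same hull area), so for even ``n_views`` the second half of the
    areas is the mirror of the first half — this symmetry holds exactly by
    construction.
    """
    if n_views < 3:
        raise ValueError("n_views must be >= 3")
    pts = band.points if isinstance(band, BodyCloud) else np.asarray(band, float)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    step = 360.0 / n_views

    half = n_views // 2 if n_views % 2 == 0 else n_views
    areas = np.empty(n_views)
    angles = np.empty(n_views)
    for i in range(half):
        a = np.radians(i * step)
        px = x * np.cos(a) - y * np.sin(a)
        proj = np.column_stack([px, z])
        hull = hull_polygon(proj)
        if hull is None:
            raise DegenerateGeometryError(
                f"side view {i}: fewer than 3 non-collinear projected points"
            )
        areas[i] = Polygon(hull).area
        angles[i] = _principal_angle(proj)
        if n_views % 2 == 0:
            # mirrored view: same hull area, axially reflected angle
            areas[i + half] = areas[i]
            angles[i + half] = (-angles[i]) % 180.0
    return SideViewSet(n_views=n_views, step_deg=step, areas=areas, angles_deg=angles)


def area_metrics(views: SideViewSet) -> AreaMetrics:
    """CV (population SD / mean) and max/min ratio of the view hull areas."""
    areas = views.areas
    if np.any(areas <= 0):
        raise DegenerateGeometryError("non-positive side-view hull area")
    return AreaMetrics(
        cv_a=float(areas.std() / areas.mean()),
        max_min_a=float(areas.max() / areas.min()),
    )


def orientation_cv(views: SideViewSet) -> float:
    """CV_D: dispersion of per-view principal orientations.

    Angles are axial (mod 180).  The circular-mean axis is found by angle
    doubling; each view is expressed as 90 + its signed deviation from that
    mean axis, and CV_D is the population SD over the mean of those values.
    """
    ang2 = np.radians(2.0 * views.angles_deg)
    mean_axis = 0.5 * np.degrees(np.arctan2(np.sin(ang2).sum(), np.cos(ang2).sum()))
    dev = (views.angles_deg - mean_axis + 90.0) % 180.0 - 90.0  # (-90, 90]
    values = 90.0 + dev
    return float(values.std() / values.mean())
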