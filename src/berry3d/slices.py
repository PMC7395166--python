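"""Horizontal slice metrics: L/W, CIR and STR.

The standardised body is cut into ``n_slices`` evenly spaced horizontal
slices (a "slice" is the set of points inside a slab of configurable
half-thickness; adjacent slabs tile the body height by default).  Each valid
slice yields a convex hull in the x–y plane with an area, a perimeter and an
area centroid (the contour moment).  From the stack:

* **L/W** — aspect ratio of the bounding box aligned with the principal
  directions of the largest slice; 1 for a circular cross-section.
* **CIR** — circularity ``4*pi*A / p**2`` of the largest slice's hull; 1 for
  a circle, smaller for anything else (isoperimetric inequality).
* **STR** — straightness of the centre axis: the ratio of the polyline
  length through consecutive slice centroids to the straight-line distance
  between the first and last centroid, taken over the middle 80% of the
  body height (80 of the 100 default slices); 1 for a straight axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import hull_measures, hull_polygon, pca_axes_2d
from .errors import DegenerateGeometryError
from .preprocess import BodyCloud

__all__ = [
    "Slice",
    "SliceStack",
    "build_slices",
    "largest_slice",
    "bbox_aspect",
    "circularity",
    "straightness",
    "polyline_straightness",
]


@dataclass
class Slice:
    z_level: float
    indices: np.ndarray          # indices into the body point array
    xy: np.ndarray               # (n, 2) member points projected to x-y
    valid: bool
    hull_area: float = 0.0
    hull_perimeter: float = 0.0
    centroid: np.ndarray | None = None   # (3,): hull area centroid + z level
    hull_xy: np.ndarray | None = None    # CCW hull vertices


@dataclass
class SliceStack:
    slices: list
    band_halfwidth_mm: float
    z_min: float
    z_max: float

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def largest_index(self) -> int:
        """Index of the valid slice with maximal hull area (ties → lower index)."""
        areas = [s.hull_area if s.valid else -np.inf for s in self.slices]
        return int(np.argmax(areas))


def build_slices(
    body: BodyCloud,
    n_slices: int = 100,
    band_halfwidth_mm: float | None = None,
) -> SliceStack:
    """Cut the body into ``n_slices`` evenly spaced horizontal slices.

    Slice levels sit at the centres of ``n_slices`` equal sub-intervals of
    the body height; the default slab half-width ``H / (2 n_slices)`` makes
    adjacent slabs tile the height exactly.
    """
    pts = body.points
    z = pts[:, 2]
    z0, z1 = float(z.min()), float(z.max())
    h = z1 - z0
    if h <= 0:
        raise DegenerateGeometryError("body has zero height; cannot slice")
    hw = h / (2.0 * n_slices) if band_halfwidth_mm is None else float(band_halfwidth_mm)

    order = np.argsort(z)
    z_sorted = z[order]
    levels = z0 + (np.arange(n_slices) + 0.5) * h / n_slices

    slices: list[Slice] = []
    n_valid = 0
    for zi in levels:
        lo = np.searchsorted(z_sorted, zi - hw, side="left")
        hi = np.searchsorted(z_sorted, zi + hw, side="right")
        idx = order[lo:hi]
        xy = pts[idx, :2]
        hull = hull_polygon(xy)
        if hull is None:
            slices.append(Slice(zi, idx, xy, valid=False))
            continue
        area, perim, cxy = hull_measures(hull)
        if area <= 0:
            slices.append(Slice(zi, idx, xy, valid=False))
            continue
        slices.append(
            Slice(
                z_level=zi,
                indices=idx,
                xy=xy,
                valid=True,
                hull_area=area,
                hull_perimeter=perim,
                centroid=np.array([cxy[0], cxy[1], zi]),
                hull_xy=hull,
            )
        )
        n_valid += 1
    if n_valid == 0:
        raise DegenerateGeometryError("all slices degenerate; cannot measure body")
    return SliceStack(slices=slices, band_halfwidth_mm=hw, z_min=z0, z_max=z1)


def largest_slice(stack: SliceStack) -> Slice:
    return stack.slices[stack.largest_index]


def bbox_aspect(slc: Slice) -> float:
    """Aspect ratio (>= 1) of the principal-axis-aligned bounding box."""
    if not slc.valid:
        raise DegenerateGeometryError("cannot fit a bounding box to an invalid slice")
    _, vecs = pca_axes_2d(slc.xy)
    proj = (slc.xy - slc.xy.mean(axis=0)) @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    short, long = float(extents.min()), float(extents.max())
    if short <= 0:
        raise DegenerateGeometryError("collinear slice: zero bounding-box width")
    return long / short


def circularity(slc: Slice) -> float:
    """Circularity ``4*pi*A / p**2`` of the slice's convex hull."""
    if not slc.valid or slc.hull_perimeter <= 0:
        raise DegenerateGeometryError("cannot compute circularity of invalid slice")
    return float(4.0 * np.pi * slc.hull_area / slc.hull_perimeter**2)


def polyline_straightness(centroids: np.ndarray) -> float:
    """Arc-length over chord of an ordered centroid path (>= 1)."""
    c = np.asarray(centroids, dtype=np.float64)
    if len(c) < 2:
        raise DegenerateGeometryError("need at least two centroids for straightness")
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1).sum()
    chord = float(np.linalg.norm(c[-1] - c[0]))
    if chord <= 1e-9:
        raise DegenerateGeometryError("end centroids coincide; straightness undefined")
    return float(seg / chord)


def straightness(
    stack: SliceStack, lower_frac: float = 0.10, upper_frac: float = 0.90
) -> float:
    """STR over the middle window of the body height (default middle 80%).

    Invalid slices inside the window are skipped; consecutive distances
    bridge over them.  Centroids are 3D (slice z-level included), so a
    perfectly straight axis yields exactly 1.
    """
    h = stack.z_max - stack.z_min
    zlo = stack.z_min + lower_frac * h
    zhi = stack.z_min + upper_frac * h
    eps = 1e-9 * max(h, 1.0)
    cents = [
        s.centroid
        for s in stack.slices
        if s.valid and (zlo - eps) <= s.z_level <= (zhi + eps)
    ]
    if len(cents) < 2:
        raise DegenerateGeometryError("fewer than two valid slices in STR window")
    return polyline_straightness(np.vstack(cents))
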