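"""Surface-curvature metrics: CV_C and Max_C/Min_C.

Curvature is the most noise-sensitive of the uniformity measures, so the
body surface is first smoothed with a moving-least-squares (MLS) projection:
every point is replaced by its projection onto a degree-2 polynomial surface
fitted (with Gaussian distance weights) to its radius neighbourhood in the
frame of the local tangent plane.

Principal curvatures are then estimated per point by an (unweighted) local
quadric fit over the k nearest neighbours: with the local frame's z-axis
along the inward surface normal, the height field is fitted as

    z' = a x'^2 + b x'y' + c y'^2 + d x' + e y' + f

and k1 >= k2 are the eigenvalues of the second-fundamental-form matrix
[[2a, b], [b, 2c]] (positive for convex regions).  The average curvature of
a point is the mean of the magnitudes, (|k1| + |k2|) / 2.

Sixteen patches are seeded at equal angular spacing around the largest
slice's centroid, each patch being the ``patch_k`` body points nearest its
seed.  The patch curvature is the mean of the upper half of its members'
average curvatures, and CV_C / Max_C/Min_C summarise the 16 patch values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError
from .preprocess import BodyCloud
from .slices import SliceStack, largest_slice

log = logging.getLogger(__name__)

__all__ = [
    "CurvatureField",
    "Patch",
    "PatchSet",
    "SmoothResult",
    "mean_nn_spacing",
    "mls_smooth",
    "principal_curvatures",
    "top_half_mean",
    "build_patches",
    "curvature_summary",
]

_MIN_FIT_POINTS = 6  # a 6-coefficient quadric needs at least 6 samples


@dataclass
class SmoothResult:
    body: BodyCloud
    mean_displacement_mm: float
    unsmoothed_fraction: float
    radius_mm: float


@dataclass
class CurvatureField:
    normals: np.ndarray   # (N, 3) outward unit normals
    k1: np.ndarray        # (N,) max principal curvature, 1/mm
    k2: np.ndarray        # (N,) min principal curvature, 1/mm
    k_avg: np.ndarray     # (N,) (|k1| + |k2|) / 2
    valid: np.ndarray     # (N,) bool, False where the fit was degenerate
    neighbourhood_size: int


@dataclass
class Patch:
    seed_index: int
    member_indices: np.ndarray
    curvature: float


@dataclass
class PatchSet:
    patches: list
    seed_angles_deg: np.ndarray

    @property
    def curvatures(self) -> np.ndarray:
        return np.array([p.curvature for p in self.patches])


def mean_nn_spacing(points: np.ndarray, tree: cKDTree | None = None) -> float:
    """Mean distance to the nearest neighbour; the cloud's sampling scale."""
    tree = tree or cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def _local_frames(
    rel: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched tangent frames from weighted neighbourhood covariances.

    ``rel`` is (N, k, 3) neighbour offsets, ``w`` (N, k) weights.  Returns
    unit (normal, t1, t2) arrays of shape (N, 3); the normal is the
    smallest-eigenvalue direction.
    """
    cov = np.einsum("nk,nki,nkj->nij", w, rel, rel)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    return vecs[..., 0], vecs[..., 1], vecs[..., 2]


def _fit_quadrics(
    rel: np.ndarray,
    w: np.ndarray,
    normal: np.ndarray,
    t1: np.ndarray,
    t2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched weighted least-squares fit of z' = f(x', y') quadrics.

    Returns (coef (N, 6) ordered [a, b, c, d, e, f], ok mask).  A tiny
    Tikhonov term keeps near-singular normal matrices solvable; genuinely
    rank-deficient fits are flagged instead of trusted.
    """
    u = np.einsum("nki,ni->nk", rel, t1)
    v = np.einsum("nki,ni->nk", rel, t2)
    zl = np.einsum("nki,ni->nk", rel, normal)
    design = np.stack(
        [u * u, u * v, v * v, u, v, np.ones_like(u)], axis=-1
    )  # (N, k, 6)
    ata = np.einsum("nk,nka,nkb->nab", w, design, design)
    atb = np.einsum("nk,nka,nk->na", w, design, zl)
    scale = np.trace(ata, axis1=1, axis2=2) / 6.0
    bad = ~(scale > 0)
    if bad.any():  # empty neighbourhoods: substitute solvable dummies
        ata[bad] = np.eye(6)
        atb[bad] = 0.0
        scale = np.where(bad, 1.0, scale)
    reg = 1e-12 * scale[:, None, None] * np.eye(6)[None]
    coef = np.linalg.solve(ata + reg, atb[..., None])[..., 0]
    ok = np.isfinite(coef).all(axis=1) & ~bad
    return coef, ok


def mls_smooth(
    body: BodyCloud,
    radius_mm: float | None = None,
    max_neighbours: int = 48,
) -> SmoothResult:
    """Moving-least-squares smoothing of the body surface.

    Each point is moved onto a degree-2 polynomial surface fitted over its
    radius neighbourhood (Gaussian weights, bandwidth ``radius/2``) in the
    local tangent frame.  The default radius is 4x the mean nearest-neighbour
    spacing — on a Poisson-sampled surface that radius captures ~12 points,
    comfortably above the 6 a quadric fit needs.  Points with fewer than 6
    neighbours inside the radius are copied unsmoothed and counted.
    """
    pts = body.points
    tree = cKDTree(pts)
    if radius_mm is None:
        radius_mm = 4.0 * mean_nn_spacing(pts, tree)
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")

    k = min(len(pts), max_neighbours)
    dist, idx = tree.query(pts, k=k)
    w = np.exp(-((dist / (radius_mm / 2.0)) ** 2))
    w[dist > radius_mm] = 0.0
    n_inside = (w > 0).sum(axis=1)
    enough = n_inside >= _MIN_FIT_POINTS

    rel = pts[idx] - pts[:, None, :]
    normal, t1, t2 = _local_frames(rel, w)
    coef, ok = _fit_quadrics(rel, w, normal, t1, t2)
    usable = enough & ok

    # f(0,0) = constant term: offset of the fitted surface at the point
    new_pts = pts.copy()
    new_pts[usable] += coef[usable, 5, None] * normal[usable]

    disp = np.linalg.norm(new_pts - pts, axis=1)
    frac_unsmoothed = 1.0 - usable.mean()
    if frac_unsmoothed > 0.10:
        log.warning(
            "%s: %.0f%% of points left unsmoothed (sparse neighbourhoods)",
            body.source_id, 100 * frac_unsmoothed,
        )
    smoothed = body.with_points(new_pts)
    smoothed.body_height_mm = float(new_pts[:, 2].max() - new_pts[:, 2].min())
    return SmoothResult(
        body=smoothed,
        mean_displacement_mm=float(disp.mean()),
        unsmoothed_fraction=float(frac_unsmoothed),
        radius_mm=float(radius_mm),
    )


def principal_curvatures(body: BodyCloud, k_neighbours: int = 30) -> CurvatureField:
    """Per-point principal curvatures from local quadric fits over k-NN."""
    if k_neighbours < 8:
        raise ValueError("k_neighbours must be >= 8")
    pts = body.points
    tree = cKDTree(pts)
    k = min(len(pts), k_neighbours)
    _, idx = tree.query(pts, k=k)
    rel = pts[idx] - pts[:, None, :]
    w = np.ones(rel.shape[:2])

    normal, t1, t2 = _local_frames(rel, w)
    # orient the frame z-axis inward (toward the body centroid) so convex
    # surfaces get positive curvature; sphere of radius R -> k1 = k2 = 1/R
    centroid = pts.mean(axis=0)
    inward = np.einsum("ni,ni->n", normal, centroid - pts)
    sign = np.where(inward >= 0, 1.0, -1.0)
    normal_in = normal * sign[:, None]

    coef, ok = _fit_quadrics(rel, w, normal_in, t1, t2)
    a, b, c = coef[:, 0], coef[:, 1], coef[:, 2]
    # eigenvalues of [[2a, b], [b, 2c]]
    tr = a + c
    disc = np.sqrt(np.maximum((a - c) ** 2 + b**2, 0.0))
    k1 = tr + disc
    k2 = tr - disc
    k_avg = 0.5 * (np.abs(k1) + np.abs(k2))
    return CurvatureField(
        normals=-normal_in,  # outward
        k1=k1,
        k2=k2,
        k_avg=k_avg,
        valid=ok,
        neighbourhood_size=k,
    )


def top_half_mean(values: np.ndarray) -> float:
    """Mean of the upper half of ``values`` (midpoint on the upper side)."""
    v = np.sort(np.asarray(values, dtype=np.float64))[::-1]
    n = len(v)
    if n == 0:
        raise ValueError("empty value set")
    return float(v[: (n + 1) // 2].mean())


def build_patches(
    body: BodyCloud,
    field: CurvatureField,
    stack: SliceStack,
    n_patches: int = 16,
    patch_k: int = 200,
) -> PatchSet:
    """Seed ``n_patches`` patches evenly around the largest slice contour.

    Seed directions sit at equal angular spacing around the largest slice's
    centroid; each seed is the slice member point nearest that direction,
    and its patch is the ``patch_k`` valid-curvature body points nearest the
    seed.  Patch curvature = mean of the upper half of member average
    curvatures.
    """
    ls = largest_slice(stack)
    if not ls.valid:
        raise DegenerateGeometryError("largest slice invalid; cannot seed patches")
    cx, cy = ls.centroid[0], ls.centroid[1]
    ang = np.arctan2(ls.xy[:, 1] - cy, ls.xy[:, 0] - cx)

    valid_idx = np.flatnonzero(field.valid)
    if len(valid_idx) == 0:
        raise DegenerateGeometryError("no valid curvature estimates for patches")
    tree = cKDTree(body.points[valid_idx])
    k = min(patch_k, len(valid_idx))

    seed_angles = np.arange(n_patches) * (360.0 / n_patches)
    patches: list[Patch] = []
    for a_deg in seed_angles:
        a = np.radians(a_deg)
        diff = np.angle(np.exp(1j * (ang - a)))  # wrapped to (-pi, pi]
        j = int(np.argmin(np.abs(diff)))
        seed_index = int(ls.indices[j])
        seed_pt = body.points[seed_index]
        _, nn = tree.query(seed_pt, k=k)
        members = valid_idx[np.atleast_1d(nn)]
        if len(members) == 0:
            raise DegenerateGeometryError(f"patch at {a_deg:.1f} deg is empty")
        patches.append(
            Patch(
                seed_index=seed_index,
                member_indices=members,
                curvature=top_half_mean(field.k_avg[members]),
            )
        )
    return PatchSet(patches=patches, seed_angles_deg=seed_angles)


def curvature_summary(patches: PatchSet) -> tuple[float, float | None]:
    """(CV_C, Max_C/Min_C) over the patch curvatures.

    If the smallest patch curvature is not positive (flat or saddle patch)
    the ratio is undefined and returned as ``None``; CV_C is still computed.
    """
    vals = patches.curvatures
    cv_c = float(vals.std() / vals.mean())
    max_min = float(vals.max() / vals.min()) if vals.min() > 0 else None
    return cv_c, max_min
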