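"""Pre-processing chain: raw SfM cloud → standardised berry body.

The chain mirrors the acquisition geometry: a berry glued onto a dark-blue
foam holder, reconstructed at an arbitrary scale and orientation.  Steps:

1. hue-threshold denoising (keep berry + holder hues, drop stray colours),
2. translation of the cloud centroid to the origin,
3. rotation aligning the principal (largest-eigenvalue) axis with +z,
   holder end pointing to negative z,
4. hue-threshold segmentation into body and holder,
5. uniform rescaling so the holder's z-extent equals its known physical
   height (38 mm), converting reconstruction units to millimetres.

After segmentation the *body* cloud is re-centred and re-aligned on its own
covariance so that every metric downstream sees a body whose centroid is at
the origin and whose main orientation is exactly +z; the drift between the
whole-cloud frame and the body frame is recorded, not silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cloud_io import ColouredPointCloud
from .errors import (
    DegenerateGeometryError,
    EmptyCloudError,
    ScaleError,
    SegmentationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "BodyCloud",
    "hue_mask",
    "denoise_by_hue",
    "center_to_origin",
    "align_principal_axis",
    "segment_body_holder",
    "standardize_scale",
    "preprocess_cloud",
]

#: eigenvalue-ratio threshold below which the principal axis is ambiguous
_EIG_RATIO_TOL = 1e-6


@dataclass
class PreprocessConfig:
    """Thresholds and physical constants for the pre-processing chain.

    Hue intervals are ``(low, high)`` pairs in degrees; an interval with
    ``low > high`` wraps through 0 (e.g. ``(330, 30)`` is the red band).
    The defaults match the synthetic palette: red berry, blue holder.
    """

    noise_hue_keep: tuple = ((330.0, 30.0), (200.0, 260.0))
    holder_hue_range: tuple = (200.0, 260.0)
    holder_height_mm: float = 38.0
    min_segment_points: int = 500

    def __post_init__(self) -> None:
        if self.holder_height_mm <= 0:
            raise ValueError("holder_height_mm must be positive")

    def to_dict(self) -> dict:
        return {
            "noise_hue_keep": [list(iv) for iv in self.noise_hue_keep],
            "holder_hue_range": list(self.holder_hue_range),
            "holder_height_mm": self.holder_height_mm,
            "min_segment_points": self.min_segment_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if "noise_hue_keep" in d:
            d["noise_hue_keep"] = tuple(tuple(iv) for iv in d["noise_hue_keep"])
        if "holder_hue_range" in d:
            d["holder_hue_range"] = tuple(d["holder_hue_range"])
        return cls(**d)


@dataclass
class BodyCloud:
    """The segmented, origin-centred, z-aligned, millimetre-scaled berry body."""

    points: np.ndarray            # (N, 3) mm
    scale_factor: float           # reconstruction units → mm multiplier
    rotation: np.ndarray          # total 3x3 orthonormal rotation applied
    body_height_mm: float
    source_id: str = ""
    flags: list = field(default_factory=list)
    centroid_drift_mm: float = 0.0  # |body centroid − whole-cloud centroid|

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "BodyCloud":
        return BodyCloud(
            points=np.asarray(points, dtype=np.float64),
            scale_factor=self.scale_factor,
            rotation=self.rotation,
            body_height_mm=self.body_height_mm,
            source_id=self.source_id,
            flags=list(self.flags),
            centroid_drift_mm=self.centroid_drift_mm,
        )


def hue_mask(hues: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask of hues lying in the union of (possibly wrapping) intervals."""
    hues = np.asarray(hues, dtype=np.float64)
    mask = np.zeros(len(hues), dtype=bool)
    for lo, hi in intervals:
        if lo <= hi:
            mask |= (hues >= lo) & (hues <= hi)
        else:  # wraps through 0
            mask |= (hues >= lo) | (hues <= hi)
    return mask


def denoise_by_hue(
    cloud: ColouredPointCloud, cfg: PreprocessConfig
) -> ColouredPointCloud:
    """Keep only points whose hue lies in the configured berry/holder bands."""
    if cloud.colours_hsv is None:
        raise ValueError("colours_hsv not populated; call rgb_to_hsv first")
    keep = hue_mask(cloud.colours_hsv[:, 0], cfg.noise_hue_keep)
    n_kept = int(keep.sum())
    log.debug(
        "%s: denoise retained %d/%d points (%.1f%%)",
        cloud.source_id, n_kept, cloud.n_points, 100.0 * n_kept / cloud.n_points,
    )
    if n_kept < cfg.min_segment_points:
        raise EmptyCloudError(
            f"cloud empty after denoising: {n_kept} points survive "
            f"(minimum {cfg.min_segment_points})"
        )
    return cloud.select(keep)


def center_to_origin(cloud: ColouredPointCloud) -> ColouredPointCloud:
    """Translate the cloud so its moment (mean of coordinates) is the origin."""
    return cloud.with_points(cloud.points - cloud.points.mean(axis=0))


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping unit vector ``v`` onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:  # antiparallel: rotate 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (eigenvalues ascending, eigenvectors) of the point covariance.

    Covariance uses 1/N (population) normalisation; irrelevant to the
    eigenvectors but fixed for reproducibility.
    """
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred / len(points)
    return np.linalg.eigh(cov)


def align_principal_axis(
    cloud: ColouredPointCloud, holder_mask: np.ndarray | None = None
) -> tuple[ColouredPointCloud, np.ndarray, bool]:
    """Rotate the cloud so its main orientation lies along +z.

    The main orientation is the eigenvector of the largest eigenvalue of the
    point covariance.  The sign is chosen so the holder points (if a mask is
    supplied) end up at negative z; without a mask the hemisphere containing
    more points goes to negative z.  Returns ``(rotated cloud, rotation,
    degenerate_flag)``; a near-spherical covariance yields the identity
    rotation and ``degenerate_flag=True``.
    """
    pts = cloud.points
    eigvals, eigvecs = principal_axis(pts)
    if eigvals[2] < (1.0 + _EIG_RATIO_TOL) * eigvals[1]:
        log.warning(
            "%s: degenerate covariance (eig ratio %.3g); identity rotation",
            cloud.source_id, eigvals[2] / max(eigvals[1], 1e-300),
        )
        return cloud, np.eye(3), True

    axis = eigvecs[:, 2]
    rot = _rotation_to_z(axis)
    rotated = pts @ rot.T

    if holder_mask is not None and holder_mask.any():
        flip = rotated[holder_mask, 2].mean() > rotated[~holder_mask, 2].mean()
    else:
        flip = (rotated[:, 2] > 0).sum() > (rotated[:, 2] < 0).sum()
    if flip:
        flip_rot = np.diag([1.0, -1.0, -1.0])
        rot = flip_rot @ rot
        rotated = pts @ rot.T
    return cloud.with_points(rotated), rot, False


def segment_body_holder(
    cloud: ColouredPointCloud, cfg: PreprocessConfig
) -> tuple[ColouredPointCloud, ColouredPointCloud]:
    """Split the cloud into berry body and blue holder by hue threshold."""
    if cloud.colours_hsv is None:
        raise ValueError("colours_hsv not populated; call rgb_to_hsv first")
    holder = hue_mask(cloud.colours_hsv[:, 0], [cfg.holder_hue_range])
    n_holder = int(holder.sum())
    n_body = cloud.n_points - n_holder
    if n_holder < cfg.min_segment_points:
        raise SegmentationError(
            f"holder segment empty: {n_holder} points "
            f"(minimum {cfg.min_segment_points})"
        )
    if n_body < cfg.min_segment_points:
        raise SegmentationError(
            f"body segment empty: {n_body} points "
            f"(minimum {cfg.min_segment_points})"
        )
    return cloud.select(~holder), cloud.select(holder)


def standardize_scale(
    body: ColouredPointCloud,
    holder: ColouredPointCloud,
    cfg: PreprocessConfig,
    rotation: np.ndarray | None = None,
    degenerate_axis: bool = False,
) -> BodyCloud:
    """Rescale the body to millimetres using the holder's known height.

    ``scale_factor = holder_height_mm / (max z − min z of the holder)`` in
    the aligned frame.  The body is then re-centred on its own centroid (the
    drift from the whole-cloud centroid is recorded) and its azimuth is
    canonicalised; the z axis stays the whole-cloud principal axis — the
    holder anchors it far more robustly than the body alone, whose vertical
    and horizontal variances are comparable for squat or lobed berries.
    """
    hz = holder.points[:, 2]
    extent = float(hz.max() - hz.min())
    if extent <= 1e-12:
        raise ScaleError(f"holder z-extent {extent:g} too small to set scale")
    scale = cfg.holder_height_mm / extent

    pts = body.points * scale
    centroid = pts.mean(axis=0)
    drift = float(np.linalg.norm(centroid))
    pts = pts - centroid

    total_rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    flags: list[str] = []
    if degenerate_axis:
        flags.append("degenerate-axis")
    else:
        # canonicalise the azimuth: put the body's larger x-y principal axis
        # on x (up to a harmless 180-degree ambiguity), so the recovered
        # frame — and every discretely sampled metric — is reproducible
        # under arbitrary rigid motion of the input.  Solids of revolution
        # have no x-y anisotropy and keep their azimuth.
        xy = pts[:, :2]
        cov2 = xy.T @ xy / len(xy)
        vals2, vecs2 = np.linalg.eigh(cov2)
        if vals2[1] > (1.0 + _EIG_RATIO_TOL) * vals2[0]:
            ang = np.arctan2(vecs2[1, 1], vecs2[0, 1])
            ca, sa = np.cos(-ang), np.sin(-ang)
            spin = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            pts = pts @ spin.T
            total_rot = spin @ total_rot

    height = float(pts[:, 2].max() - pts[:, 2].min())
    log.debug(
        "%s: scale %.6g, body height %.2f mm, centroid drift %.3f mm",
        body.source_id, scale, height, drift,
    )
    return BodyCloud(
        points=pts,
        scale_factor=scale,
        rotation=total_rot,
        body_height_mm=height,
        source_id=body.source_id,
        flags=flags,
        centroid_drift_mm=drift,
    )


def preprocess_cloud(cloud: ColouredPointCloud, cfg: PreprocessConfig) -> BodyCloud:
    """Run the full chain: denoise → centre → align → segment → standardise."""
    from .cloud_io import rgb_to_hsv

    if cloud.colours_hsv is None:
        cloud = rgb_to_hsv(cloud)
    clean = denoise_by_hue(cloud, cfg)
    centred = center_to_origin(clean)
    holder_m = hue_mask(centred.colours_hsv[:, 0], [cfg.holder_hue_range])
    aligned, rot, degenerate = align_principal_axis(centred, holder_mask=holder_m)
    if not degenerate:
        # alignment postcondition: the aligned cloud's covariance main axis
        # is exactly +z
        _, eigvecs = principal_axis(aligned.points)
        assert abs(abs(eigvecs[2, 2]) - 1.0) < 1e-6, "eigen-alignment failed"
    body, holder = segment_body_holder(aligned, cfg)
    return standardize_scale(body, holder, cfg, rotation=rot,
                             degenerate_axis=degenerate)
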