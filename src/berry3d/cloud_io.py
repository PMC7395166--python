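"""Coloured point-cloud I/O and colour-space conversion.

Clouds arrive as PLY files produced by Structure-from-Motion reconstruction:
one strawberry sitting on a dark-blue foam holder per file, with per-vertex
RGB colour.  This module reads and writes such files (ASCII or binary
little-endian, via :mod:`trimesh`) and converts colours to HSV, which is the
space every downstream hue threshold operates in.

Hue is expressed in degrees on ``[0, 360)`` throughout the package;
saturation and value lie in ``[0, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv

from .errors import PlyReadError, PlyWriteError

log = logging.getLogger(__name__)

__all__ = ["ColouredPointCloud", "read_ply", "write_ply", "rgb_to_hsv"]


@dataclass
class ColouredPointCloud:
    """N points with xyz coordinates and per-point colour.

    ``points`` are in arbitrary reconstruction units until the preprocessing
    chain rescales them to millimetres.  ``colours_hsv`` is ``None`` until
    :func:`rgb_to_hsv` is applied.
    """

    points: np.ndarray                  # (N, 3) float64
    colours_rgb: np.ndarray             # (N, 3) uint8
    colours_hsv: np.ndarray | None = None  # (N, 3): h deg [0,360), s, v [0,1]
    source_id: str = ""
    n_dropped_nonfinite: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.colours_rgb = np.asarray(self.colours_rgb, dtype=np.uint8)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.colours_rgb.shape != self.points.shape:
            raise ValueError("colours_rgb must match points in shape")
        if len(self.points) < 1:
            raise ValueError("cloud must contain at least one point")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "ColouredPointCloud":
        """Return a new cloud restricted to ``mask`` (boolean or index array)."""
        return ColouredPointCloud(
            points=self.points[mask],
            colours_rgb=self.colours_rgb[mask],
            colours_hsv=None if self.colours_hsv is None else self.colours_hsv[mask],
            source_id=self.source_id,
            n_dropped_nonfinite=self.n_dropped_nonfinite,
        )

    def with_points(self, points: np.ndarray) -> "ColouredPointCloud":
        """Return a copy with replaced coordinates (same colours)."""
        return ColouredPointCloud(
            points=points,
            colours_rgb=self.colours_rgb,
            colours_hsv=self.colours_hsv,
            source_id=self.source_id,
            n_dropped_nonfinite=self.n_dropped_nonfinite,
        )


def read_ply(path: str | Path) -> ColouredPointCloud:
    """Read a coloured point cloud from a PLY file.

    The vertex element must carry ``x, y, z`` and ``red, green, blue``
    properties.  Faces, normals and any extra properties are ignored.
    Rows with non-finite coordinates are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise PlyReadError(f"{path}: file does not exist")
    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        raise PlyReadError(f"{path}: unreadable PLY ({exc})") from exc

    vertices = np.asarray(obj.vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or len(vertices) == 0:
        raise PlyReadError(f"{path}: no vertex element with x, y, z found")

    colours = None
    if isinstance(obj, trimesh.PointCloud):
        try:
            colours = np.asarray(obj.colors)
        except Exception:
            colours = None
    else:  # a mesh whose faces we discard
        try:
            colours = np.asarray(obj.visual.vertex_colors)
        except Exception:
            colours = None
    if colours is None or len(colours) != len(vertices) or colours.ndim != 2:
        raise PlyReadError(
            f"{path}: vertex colour properties 'red', 'green', 'blue' are missing"
        )
    colours = colours[:, :3].astype(np.uint8)

    finite = np.isfinite(vertices).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.warning("%s: dropped %d non-finite vertices", path.name, n_dropped)
        vertices = vertices[finite]
        colours = colours[finite]
    if len(vertices) == 0:
        raise PlyReadError(f"{path}: all vertices non-finite")

    return ColouredPointCloud(
        points=vertices,
        colours_rgb=colours,
        source_id=path.stem,
        n_dropped_nonfinite=n_dropped,
    )


def write_ply(
    cloud: ColouredPointCloud,
    path: str | Path,
    encoding: str = "binary_le",
) -> None:
    """Write ``cloud`` to PLY with float32 coordinates and uchar colours.

    ``encoding`` is ``"ascii"`` or ``"binary_le"`` (binary little-endian).
    """
    if encoding not in ("ascii", "binary_le"):
        raise ValueError(f"unknown encoding {encoding!r}")
    path = Path(path)
    pc = trimesh.PointCloud(
        cloud.points.astype(np.float32), colors=cloud.colours_rgb
    )
    try:
        pc.export(
            str(path),
            file_type="ply",
            encoding="ascii" if encoding == "ascii" else "binary_little_endian",
        )
    except OSError as exc:
        raise PlyWriteError(f"{path}: cannot write ({exc})") from exc


def rgb_to_hsv(cloud: ColouredPointCloud) -> ColouredPointCloud:
    """Populate ``colours_hsv`` from ``colours_rgb`` (hexcone model).

    Hue is returned in degrees on ``[0, 360)`` with hue 0 for achromatic
    points; saturation and value lie in ``[0, 1]``.
    """
    rgb = cloud.colours_rgb.astype(np.float64) / 255.0
    hsv = _mpl_rgb_to_hsv(rgb)
    hsv[:, 0] = (hsv[:, 0] * 360.0) % 360.0
    return ColouredPointCloud(
        points=cloud.points,
        colours_rgb=cloud.colours_rgb,
        colours_hsv=hsv,
        source_id=cloud.source_id,
        n_dropped_nonfinite=cloud.n_dropped_nonfinite,
    )
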