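"""Parametric synthetic berry + holder clouds with ground truth.

Real inputs are Structure-from-Motion reconstructions of a strawberry on a
blue foam holder.  This module emulates them: a berry surface of revolution
``r(z)`` (cylinder, cone, sphere, or a smooth conic-berry profile) with
controllable deformations —

* angular lobing ``r(z, theta) = r(z) * (1 + a cos(m theta))``,
* a bent central axis (sinusoidal or circular-arc lateral offset),
* surface noise, stray noise points, rigid tilt and an arbitrary global
  scale (SfM units are arbitrary).

Every deformation is recorded in a :class:`GroundTruth` object (per-point
part labels, the axis curve, closed-form curvatures where the profile has
one, the applied rotation/scale/translation), so tests can compare measured
metrics against known geometry.  Generation is deterministic: the same spec
yields byte-identical clouds.

The generator's scene constants mirror the acquisition rig: holder block of
38 x 19 x 19 mm (height x length x width) under the berry, red berry hues,
blue holder hues.  Default berry proportions (30 mm tall, 12.5 mm maximum
radius) are typical of a ripe dessert strawberry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.interpolate import PchipInterpolator

from .cloud_io import ColouredPointCloud, write_ply

__all__ = [
    "BerrySpec",
    "GroundTruth",
    "generate",
    "axis_straightness",
    "make_fixture_suite",
    "HOLDER_SIZE_MM",
]

#: holder block dimensions (height, length, width) in mm
HOLDER_SIZE_MM = (38.0, 19.0, 19.0)

_PROFILES = ("cylinder", "cone", "sphere", "berry")
_AXIS_SHAPES = ("none", "sine", "s_curve", "arc")


@dataclass
class BerrySpec:
    """Full description of one synthetic scene.

    ``radius_mm`` is the profile's maximum radius; ``height_mm`` the berry
    height.  ``lobe_amplitude``/``lobe_count`` modulate the radius with
    angle; ``axis_amplitude_mm``/``axis_shape`` bend the central axis;
    ``tilt_deg`` rotates the whole scene about x; ``scale`` is the
    arbitrary SfM unit scale applied last.  ``noise_sigma_mm`` jitters
    surface points; ``noise_fraction`` adds that fraction of stray points
    with hues outside both the berry and holder bands.
    """

    profile: str = "berry"
    height_mm: float = 30.0
    radius_mm: float = 12.5
    lobe_amplitude: float = 0.0
    lobe_count: int = 0
    axis_amplitude_mm: float = 0.0
    axis_shape: str = "none"
    tilt_deg: float = 0.0
    n_points: int = 50_000
    noise_sigma_mm: float = 0.0
    noise_fraction: float = 0.0
    berry_hue_deg: float = 0.0
    holder_hue_deg: float = 230.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.axis_shape not in _AXIS_SHAPES:
            raise ValueError(f"unknown axis shape {self.axis_shape!r}")
        if self.n_points < 1000:
            raise ValueError("n_points must be >= 1000")
        if self.height_mm <= 0 or self.radius_mm <= 0 or self.scale <= 0:
            raise ValueError("height_mm, radius_mm and scale must be positive")
        if abs(self.lobe_amplitude) >= 1.0:
            raise ValueError("lobe_amplitude must keep r > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def sha1(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class GroundTruth:
    spec: BerrySpec
    labels: np.ndarray          # (N,) 'berry' / 'holder' / 'noise'
    rotation: np.ndarray        # applied 3x3 rotation (tilt)
    scale: float                # applied global scale
    translation: np.ndarray     # applied translation (post-scale units)
    k1: float | None = None     # closed-form curvatures (1/mm) where defined
    k2: float | None = None

    def axis_offset(self, z: np.ndarray) -> np.ndarray:
        """Lateral (x, y) offset of the central axis at height z (pre-transform, mm)."""
        return _axis_offset(self.spec, np.asarray(z, dtype=np.float64))

    def profile_radius(self, z: np.ndarray) -> np.ndarray:
        return _profile(self.spec)(np.asarray(z, dtype=np.float64))


def _profile(spec: BerrySpec):
    """Radius-vs-height function r(z) on [0, height_mm]."""
    h, r0 = spec.height_mm, spec.radius_mm
    if spec.profile == "cylinder":
        return lambda z: np.full_like(np.asarray(z, float), r0)
    if spec.profile == "cone":
        # apex at the top (nose), tiny tip radius to keep r > 0
        return lambda z: np.maximum(r0 * (1.0 - np.asarray(z, float) / h), 0.02 * r0)
    if spec.profile == "sphere":
        R = h / 2.0
        return lambda z: np.sqrt(
            np.maximum(R**2 - (np.asarray(z, float) - R) ** 2, 0.0)
        )
    # smooth conic-berry profile: widest ~40% up, tapering to the nose
    knots_t = np.array([0.0, 0.15, 0.40, 0.65, 0.85, 1.0])
    knots_r = np.array([0.55, 0.92, 1.0, 0.85, 0.55, 0.10]) * r0
    interp = PchipInterpolator(knots_t * h, knots_r)
    return lambda z: np.asarray(interp(np.clip(z, 0.0, h)), dtype=np.float64)


def _axis_offset(spec: BerrySpec, z: np.ndarray) -> np.ndarray:
    """(len(z), 2) lateral axis offset; bends lie in the x-z plane."""
    t = np.clip(z / spec.height_mm, 0.0, 1.0)
    ox = np.zeros_like(t)
    if spec.axis_shape == "sine":
        # C-shaped bulge: zero at both ends, maximal at mid-height
        ox = spec.axis_amplitude_mm * np.sin(np.pi * t)
    elif spec.axis_shape == "s_curve":
        # S-shaped (shear-like) bend: tilts side-view orientations
        ox = spec.axis_amplitude_mm * np.sin(2 * np.pi * t)
    elif spec.axis_shape == "arc":
        ox = spec.axis_amplitude_mm * np.sqrt(np.maximum(1.0 - (2 * t - 1) ** 2, 0.0))
    return np.column_stack([ox, np.zeros_like(ox)])


def axis_straightness(
    spec: BerrySpec, lower_frac: float = 0.10, upper_frac: float = 0.90,
    n_quad: int = 20_001,
) -> float:
    """Arc-length over chord of the true axis curve inside a height window.

    Quadrature oracle for STR: independent of the slicing pipeline.
    """
    z = np.linspace(lower_frac * spec.height_mm, upper_frac * spec.height_mm, n_quad)
    off = _axis_offset(spec, z)
    path = np.column_stack([off, z])
    arc = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
    chord = np.linalg.norm(path[-1] - path[0])
    return float(arc / chord)


def _sample_surface(spec: BerrySpec, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted sample of the deformed surface of revolution (mm)."""
    h = spec.height_mm
    r_of_z = _profile(spec)
    zg = np.linspace(0.0, h, 4096)
    rg = r_of_z(zg)
    drdz = np.gradient(rg, zg)
    # area element of a surface of revolution: dA ∝ r sqrt(1 + r'^2) dz
    w = np.maximum(rg, 1e-9) * np.sqrt(1.0 + drdz**2)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(zg))])
    cdf /= cdf[-1]

    n = spec.n_points
    z = np.interp(rng.random(n), cdf, zg)

    if spec.lobe_amplitude > 0 and spec.lobe_count > 0:
        # angular density ∝ local circumference factor (1 + a cos m theta)
        a, m = spec.lobe_amplitude, spec.lobe_count
        theta = np.empty(n)
        need = np.arange(n)
        while len(need):
            cand = rng.uniform(0.0, 2 * np.pi, len(need))
            accept = rng.random(len(need)) < (1 + a * np.cos(m * cand)) / (1 + a)
            theta[need[accept]] = cand[accept]
            need = need[~accept]
        radial = r_of_z(z) * (1 + a * np.cos(m * theta))
    else:
        theta = rng.uniform(0.0, 2 * np.pi, n)
        radial = r_of_z(z)

    pts = np.column_stack(
        [radial * np.cos(theta), radial * np.sin(theta), z]
    )
    pts[:, :2] += _axis_offset(spec, z)
    if spec.noise_sigma_mm > 0:
        pts += rng.normal(0.0, spec.noise_sigma_mm, pts.shape)
    return pts


def _sample_holder(spec: BerrySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform area sample of the holder box surface, top face at z = 0."""
    hh, hl, hw = HOLDER_SIZE_MM
    faces = [  # (area, sampler) for the 6 faces of the box
        (hl * hw, lambda m: np.column_stack(
            [rng.uniform(-hl / 2, hl / 2, m), rng.uniform(-hw / 2, hw / 2, m),
             np.zeros(m)])),
        (hl * hw, lambda m: np.column_stack(
            [rng.uniform(-hl / 2, hl / 2, m), rng.uniform(-hw / 2, hw / 2, m),
             np.full(m, -hh)])),
        (hl * hh, lambda m: np.column_stack(
            [rng.uniform(-hl / 2, hl / 2, m), np.full(m, -hw / 2),
             rng.uniform(-hh, 0, m)])),
        (hl * hh, lambda m: np.column_stack(
            [rng.uniform(-hl / 2, hl / 2, m), np.full(m, hw / 2),
             rng.uniform(-hh, 0, m)])),
        (hw * hh, lambda m: np.column_stack(
            [np.full(m, -hl / 2), rng.uniform(-hw / 2, hw / 2, m),
             rng.uniform(-hh, 0, m)])),
        (hw * hh, lambda m: np.column_stack(
            [np.full(m, hl / 2), rng.uniform(-hw / 2, hw / 2, m),
             rng.uniform(-hh, 0, m)])),
    ]
    areas = np.array([f[0] for f in faces])
    counts = rng.multinomial(n, areas / areas.sum())
    return np.vstack([f[1](m) for (f, m) in zip(faces, counts) if m > 0])


def _hues_to_rgb(
    hue_deg: np.ndarray, s: np.ndarray, v: np.ndarray
) -> np.ndarray:
    hsv = np.column_stack([(hue_deg % 360.0) / 360.0, s, v])
    return np.round(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)


def generate(spec: BerrySpec) -> tuple[ColouredPointCloud, GroundTruth]:
    """Generate a coloured berry + holder scene with ground truth."""
    rng = np.random.default_rng(spec.seed)

    berry = _sample_surface(spec, rng)

    # holder point count matched to its surface area relative to the berry
    r_of_z = _profile(spec)
    zg = np.linspace(0.0, spec.height_mm, 1024)
    berry_area = float(np.trapezoid(2 * np.pi * r_of_z(zg), zg))
    hh, hl, hw = HOLDER_SIZE_MM
    holder_area = 2 * hl * hw + 2 * hh * (hl + hw)
    n_holder = max(int(round(spec.n_points * holder_area / berry_area)), 1500)
    holder = _sample_holder(spec, n_holder, rng)

    n_noise = int(round(spec.noise_fraction * spec.n_points))
    if n_noise:
        rmax = 2.0 * spec.radius_mm
        noise_theta = rng.uniform(0, 2 * np.pi, n_noise)
        noise_r = rmax * np.sqrt(rng.random(n_noise))
        noise = np.column_stack(
            [noise_r * np.cos(noise_theta), noise_r * np.sin(noise_theta),
             rng.uniform(-hh - 5.0, spec.height_mm + 5.0, n_noise)]
        )
    else:
        noise = np.empty((0, 3))

    pts = np.vstack([berry, holder, noise])
    labels = np.concatenate(
        [np.full(len(berry), "berry"), np.full(len(holder), "holder"),
         np.full(len(noise), "noise")]
    )

    # colours: hue jitter stays inside the configured bands; stray points get
    # green-to-cyan hues, disjoint from both the red and blue defaults
    nb, nh = len(berry), len(holder)
    hues = np.concatenate(
        [spec.berry_hue_deg + rng.uniform(-8, 8, nb),
         spec.holder_hue_deg + rng.uniform(-8, 8, nh),
         rng.uniform(60, 190, len(noise))]
    )
    sat = np.concatenate(
        [rng.uniform(0.75, 0.95, nb), rng.uniform(0.6, 0.8, nh),
         rng.uniform(0.3, 0.9, len(noise))]
    )
    val = np.concatenate(
        [rng.uniform(0.55, 0.85, nb), rng.uniform(0.25, 0.45, nh),
         rng.uniform(0.3, 0.9, len(noise))]
    )
    rgb = _hues_to_rgb(hues, sat, val)

    # rigid tilt about x, then the arbitrary SfM scale and a translation
    t = np.radians(spec.tilt_deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
    )
    translation = rng.uniform(-0.5, 0.5, 3) * spec.height_mm * spec.scale
    pts = (pts @ rot.T) * spec.scale + translation

    cloud = ColouredPointCloud(
        points=pts, colours_rgb=rgb, source_id=f"synthetic-{spec.sha1()}"
    )
    k1 = k2 = None
    if spec.profile == "sphere":
        k1 = k2 = 2.0 / spec.height_mm   # 1/R with R = height/2
    elif spec.profile == "cylinder":
        k1, k2 = 1.0 / spec.radius_mm, 0.0
    truth = GroundTruth(
        spec=spec, labels=labels, rotation=rot, scale=spec.scale,
        translation=translation, k1=k1, k2=k2,
    )
    return cloud, truth


#: named fixture specs used by the test-suite and docs (modest point counts
#: keep a full-suite run fast while leaving every hull well sampled)
FIXTURE_SPECS = {
    "ideal_cone": BerrySpec(profile="cone", radius_mm=12.0, height_mm=32.0,
                            n_points=20_000, seed=101),
    "sphere": BerrySpec(profile="sphere", height_mm=30.0, radius_mm=15.0,
                        n_points=20_000, seed=102),
    "lobed": BerrySpec(profile="berry", lobe_amplitude=0.2, lobe_count=2,
                       n_points=20_000, seed=103),
    "bent_axis": BerrySpec(profile="berry", axis_amplitude_mm=3.0,
                           axis_shape="sine", n_points=20_000, seed=104),
    "tilted_rescaled": BerrySpec(profile="cone", radius_mm=12.0, height_mm=32.0,
                                 tilt_deg=25.0, scale=0.013,
                                 n_points=20_000, seed=101),
    "noisy": BerrySpec(profile="berry", noise_sigma_mm=0.15,
                       noise_fraction=0.05, n_points=20_000, seed=106),
}


def make_fixture_suite(out_dir: str | Path, encoding: str = "binary_le") -> dict:
    """Write the named PLY fixtures plus a JSON manifest; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, spec in FIXTURE_SPECS.items():
        cloud, truth = generate(spec)
        path = out_dir / f"{name}.ply"
        write_ply(cloud, path, encoding=encoding)
        entry = {
            "file": path.name,
            "spec": spec.to_dict(),
            "spec_sha1": spec.sha1(),
            "expected": {},
        }
        if name in ("ideal_cone", "tilted_rescaled"):
            entry["expected"] = {"cv_a_max": 0.02, "max_min_a_max": 1.03,
                                 "l_w_max": 1.03, "cir_min": 0.99,
                                 "str_max": 1.005}
        if name == "bent_axis":
            entry["expected"] = {"str": axis_straightness(spec)}
        manifest[name] = entry
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
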