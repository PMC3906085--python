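"""Synthetic contrast-filled vessel phantoms with analytic ground truth.

A phantom is a tubular lumen swept along a parametric centerline (straight
line, circular arc, or helix) with a per-arc-length cross-section (circle,
ellipse, or crescent), optionally narrowed by a Gaussian stenosis and
decorated with a high-HU calcific insert.  The tube is voxelized with
sub-voxel supersampling, blurred by a Gaussian point-spread function and
corrupted by additive Gaussian noise — the regime of contrast-enhanced
coronary CT — while the analytic centerline, cross-sectional area (CSA) and
inscribed-circle diameter remain available noise-free as ground truth.

Default intensities (lumen 450 HU, background 50 HU, calcific 900 HU) sit in
the typical CCTA contrast regime, consistent with the >700 HU rule used to
classify calcium downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .volume_io import Volume

__all__ = [
    "PhantomSpec",
    "CalcificInsert",
    "GroundTruth",
    "generate_phantom",
    "analytic_csa",
    "crescent_area",
    "crescent_inscribed_diameter",
    "crescent_polygon",
]

# default study conditions: 0.4 mm isotropic grid, CCTA-like contrast,
# sigma 0.6 mm PSF and 20 HU Gaussian noise
DEFAULT_SPACING = (0.4, 0.4, 0.4)
DEFAULT_LUMEN_HU = 450.0
DEFAULT_BACKGROUND_HU = 50.0
DEFAULT_CALCIFIC_HU = 900.0
DEFAULT_PSF_SIGMA_MM = 0.6
DEFAULT_NOISE_SIGMA_HU = 20.0


# ---------------------------------------------------------------------------
# analytic profile geometry


def _circle_area(r: float) -> float:
    return math.pi * r * r


def _lens_area(R: float, r: float, d: float) -> float:
    """Area of the intersection of two disks with radii R, r at center distance d."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rm = min(R, r)
        return math.pi * rm * rm
    a = r * r * math.acos((d * d + r * r - R * R) / (2 * d * r))
    b = R * R * math.acos((d * d + R * R - r * r) / (2 * d * R))
    c = 0.5 * math.sqrt(
        (-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R)
    )
    return a + b - c


def crescent_area(R: float, r: float, offset: float) -> float:
    """Area of disk(R) minus its overlap with disk(r) centered ``offset`` away."""
    area = _circle_area(R) - _lens_area(R, r, offset)
    if area <= 0:
        raise ValueError("crescent parameters yield an empty lumen")
    return area


def crescent_inscribed_diameter(R: float, r: float, offset: float) -> float:
    """Diameter of the largest circle inside the crescent.

    For a cutting disk that truly bites into the rim (offset + r > R) the
    optimum sits on the symmetry axis opposite the cut, where the distances to
    the two circular boundaries balance: diameter = R + offset - r.
    """
    if offset >= R + r:
        return 2.0 * R  # disks disjoint: full disk survives
    if offset + r <= R:
        raise ValueError("cutting disk strictly inside: not a crescent")
    return R + offset - r


def crescent_polygon(R: float, r: float, offset: float, n: int = 256) -> np.ndarray:
    """Boundary polygon (n-ish vertices, CCW, 2D) of the crescent cross-section."""
    if offset >= R + r:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.c_[R * np.cos(t), R * np.sin(t)]
    # intersection points of the two circles; cutter centered at (offset, 0)
    x = (offset * offset + R * R - r * r) / (2 * offset)
    y2 = R * R - x * x
    if y2 <= 0:
        raise ValueError("degenerate crescent (tangent circles)")
    y = math.sqrt(y2)
    # outer boundary: big-circle arc from (x, y) CCW the long way round to (x, -y)
    a0 = math.atan2(y, x)
    a1 = math.atan2(-y, x) + 2 * math.pi
    touter = np.linspace(a0, a1, n // 2)
    outer = np.c_[R * np.cos(touter), R * np.sin(touter)]
    # inner boundary: cutter-circle arc from (x, -y) back to (x, y), traversed
    # clockwise (through the point (offset - r, 0) inside the big circle)
    b0 = math.atan2(-y, x - offset)
    b1 = math.atan2(y, x - offset) - 2 * math.pi
    tinner = np.linspace(b0, b1, n // 2)
    inner = np.c_[offset + r * np.cos(tinner), r * np.sin(tinner)]
    return np.vstack([outer, inner[1:-1]])


@dataclass
class _Profile:
    """Nominal (unmodulated) 2D cross-section in the local (u, v) frame."""

    kind: str
    params: tuple

    def area(self) -> float:
        if self.kind == "circle":
            (r,) = self.params
            return _circle_area(r)
        if self.kind == "ellipse":
            a, b = self.params
            return math.pi * a * b
        if self.kind == "crescent":
            R, r, off = self.params
            return crescent_area(R, r, off)
        raise ValueError(self.kind)

    def inscribed_diameter(self) -> float:
        if self.kind == "circle":
            (r,) = self.params
            return 2 * r
        if self.kind == "ellipse":
            a, b = self.params
            return 2 * min(a, b)
        if self.kind == "crescent":
            R, r, off = self.params
            return crescent_inscribed_diameter(R, r, off)
        raise ValueError(self.kind)

    def max_radius(self) -> float:
        if self.kind == "circle":
            return self.params[0]
        if self.kind == "ellipse":
            return max(self.params)
        return self.params[0]

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        if self.kind == "circle":
            (r,) = self.params
            return u * u + v * v <= r * r
        if self.kind == "ellipse":
            a, b = self.params
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if self.kind == "crescent":
            R, r, off = self.params
            inside_big = u * u + v * v <= R * R
            inside_cut = (u - off) ** 2 + v * v <= r * r
            return inside_big & ~inside_cut
        raise ValueError(self.kind)

    def polygon(self, n: int = 256) -> np.ndarray:
        if self.kind == "circle":
            (r,) = self.params
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return np.c_[r * np.cos(t), r * np.sin(t)]
        if self.kind == "ellipse":
            a, b = self.params
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return np.c_[a * np.cos(t), b * np.sin(t)]
        if self.kind == "crescent":
            return crescent_polygon(*self.params, n=n)
        raise ValueError(self.kind)


def _make_profile(kind: str, params) -> _Profile:
    params = tuple(float(p) for p in params)
    if any(p <= 0 for p in params):
        raise ValueError(f"profile parameters must be positive, got {params}")
    if kind == "crescent":
        R, r, off = params
        if off >= R + r:
            pass  # disjoint cutter: degenerates to a circle, still valid
        elif off + r <= R:
            raise ValueError("crescent cutter strictly inside the lumen disk")
        if off >= R and off + r <= off:  # pragma: no cover - unreachable guard
            raise ValueError("empty crescent")
        if crescent_area(R, r, off) <= 0:
            raise ValueError("crescent parameters yield an empty lumen")
    elif kind == "circle":
        if len(params) != 1:
            raise ValueError("circle takes one parameter (radius)")
    elif kind == "ellipse":
        if len(params) != 2:
            raise ValueError("ellipse takes two parameters (a, b)")
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return _Profile(kind, params)


# ---------------------------------------------------------------------------
# parametric centerlines


class _Curve:
    """Arc-length parameterized 3D curve with an orthonormal moving frame."""

    def __init__(self, kind: str, params: dict):
        self.kind = kind
        self.params = params

    @property
    def length(self) -> float:
        p = self.params
        if self.kind == "line":
            return float(p["length"])
        if self.kind == "arc":
            return float(p["radius"] * p["angle"])
        if self.kind == "helix":
            R, pitch, turns = p["radius"], p["pitch"], p["turns"]
            return float(turns * math.sqrt((2 * math.pi * R) ** 2 + pitch**2))
        raise ValueError(self.kind)

    def point(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        p = self.params
        c = np.asarray(p.get("center", (0.0, 0.0, 0.0)), dtype=float)
        if self.kind == "line":
            d = _unit(np.asarray(p.get("direction", (0, 0, 1)), dtype=float))
            return c + s[:, None] * d
        if self.kind == "arc":
            R = p["radius"]
            t = s / R
            return c + np.c_[R * (1 - np.cos(t)), np.zeros_like(t), R * np.sin(t)]
        if self.kind == "helix":
            R, pitch = p["radius"], p["pitch"]
            L1 = math.sqrt((2 * math.pi * R) ** 2 + pitch**2)  # arc length per turn
            theta = 2 * math.pi * s / L1
            return c + np.c_[
                R * np.cos(theta) - R,
                R * np.sin(theta),
                pitch * theta / (2 * math.pi),
            ]
        raise ValueError(self.kind)

    def tangent(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        p = self.params
        if self.kind == "line":
            d = _unit(np.asarray(p.get("direction", (0, 0, 1)), dtype=float))
            return np.tile(d, (len(s), 1))
        if self.kind == "arc":
            t = s / p["radius"]
            return np.c_[np.sin(t), np.zeros_like(t), np.cos(t)]
        if self.kind == "helix":
            R, pitch = p["radius"], p["pitch"]
            L1 = math.sqrt((2 * math.pi * R) ** 2 + pitch**2)
            theta = 2 * math.pi * s / L1
            vec = np.c_[
                -R * np.sin(theta),
                R * np.cos(theta),
                np.full_like(theta, pitch / (2 * math.pi)),
            ]
            return vec / np.linalg.norm(vec, axis=1, keepdims=True)
        raise ValueError(self.kind)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported orthonormal normals (n1, n2) along the curve."""
    n = len(tangents)
    n1 = np.empty_like(tangents)
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, t0) * t0
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, n):
        v = n1[i - 1] - np.dot(n1[i - 1], tangents[i]) * tangents[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(tangents, n1)
    return n1, n2


# ---------------------------------------------------------------------------
# spec and ground truth


@dataclass
class CalcificInsert:
    """Spherical high-HU blob placed at arc length ``s`` offset radially from the axis."""

    s: float
    radius: float
    radial_offset: float
    hu: float = DEFAULT_CALCIFIC_HU


@dataclass
class PhantomSpec:
    centerline: str = "line"  # line | arc | helix
    centerline_params: dict = field(default_factory=dict)
    profile: str = "circle"  # circle | ellipse | crescent
    profile_params: tuple = (2.0,)
    stenosis_depth: float = 0.0  # fractional area reduction at apex
    stenosis_center: float | None = None  # arc length mm; default mid-vessel
    stenosis_width: float = 3.0  # Gaussian sigma, mm
    lumen_hu: float = DEFAULT_LUMEN_HU
    background_hu: float = DEFAULT_BACKGROUND_HU
    calcific: CalcificInsert | None = None
    psf_sigma: float = DEFAULT_PSF_SIGMA_MM  # mm
    noise_sigma: float = DEFAULT_NOISE_SIGMA_HU  # HU
    shape: tuple[int, int, int] = (48, 48, 64)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    supersample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_hu <= self.background_hu:
            raise ValueError("lumen HU must exceed background HU")
        if self.calcific is not None and self.calcific.hu <= self.lumen_hu:
            raise ValueError("calcific HU must exceed lumen HU")
        if not 0.0 <= self.stenosis_depth < 1.0:
            raise ValueError("stenosis depth must be in [0, 1)")
        if self.stenosis_width <= 0:
            raise ValueError("stenosis width must be positive")
        _make_profile(self.profile, self.profile_params)  # validates geometry

    def curve(self) -> _Curve:
        params = dict(self.centerline_params)
        if self.centerline == "line":
            params.setdefault("length", (self.shape[2] - 1) * self.spacing[2] - 4.0)
            extent = np.asarray(self.shape) * np.asarray(self.spacing)
            params.setdefault("center", (extent[0] / 2, extent[1] / 2, 2.0))
            params.setdefault("direction", (0.0, 0.0, 1.0))
        return _Curve(self.centerline, params)


@dataclass
class GroundTruth:
    """Analytic, noise-free geometry of a phantom."""

    s: np.ndarray  # arc lengths, mm, strictly increasing
    points: np.ndarray  # (n, 3) world mm
    tangents: np.ndarray  # (n, 3) unit vectors
    csa: Callable[[np.ndarray], np.ndarray]  # s -> mm^2
    inscribed_diameter: Callable[[np.ndarray], np.ndarray]  # s -> mm
    length: float
    nominal_area: float

    def point_at(self, s: float) -> np.ndarray:
        return np.array(
            [np.interp(s, self.s, self.points[:, i]) for i in range(3)]
        )


def _stenosis_factor(spec: PhantomSpec, length: float):
    if spec.stenosis_depth == 0.0:
        return lambda s: np.ones_like(np.atleast_1d(np.asarray(s, dtype=float)))
    s0 = spec.stenosis_center if spec.stenosis_center is not None else length / 2.0
    depth, w = spec.stenosis_depth, spec.stenosis_width

    def factor(s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return 1.0 - depth * np.exp(-((s - s0) ** 2) / (2 * w * w))

    return factor


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Voxelize the phantom and return the CT-like volume plus analytic truth.

    The lumen indicator is evaluated on a ``supersample``-times finer grid,
    averaged back (partial-volume rendering), mapped to HU, blurred with the
    Gaussian PSF, then corrupted with seeded Gaussian noise.  Ground truth is
    exact and untouched by blur or noise.
    """
    curve = spec.curve()
    length = curve.length
    profile = _make_profile(spec.profile, spec.profile_params)
    factor = _stenosis_factor(spec, length)

    # dense stations for distance queries and for the returned truth samples
    step = min(spec.spacing) / 2.0
    n_st = max(int(math.ceil(length / step)) + 1, 8)
    s_st = np.linspace(0.0, length, n_st)
    pts = curve.point(s_st)
    tans = curve.tangent(s_st)
    n1, n2 = _transport_frames(tans)

    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    shape = tuple(int(n) for n in spec.shape)
    rmax = profile.max_radius()

    # margin check: tube surface must stay >= 3 voxels away from every face
    lo = origin - spacing / 2.0
    hi = origin + (np.asarray(shape) - 0.5) * spacing
    margin = 3.0 * spacing
    root2 = math.sqrt(0.5)
    surf_dirs = [n1, -n1, n2, -n2, (n1 + n2) * root2, (n1 - n2) * root2,
                 (-n1 + n2) * root2, (-n1 - n2) * root2]
    surf = np.concatenate([pts + rmax * d for d in surf_dirs] + [pts])
    if np.any(surf < lo + margin) or np.any(surf > hi - margin):
        raise ValueError("tube exits grid (needs a >=3-voxel margin on every face)")

    ss = max(int(spec.supersample), 1)
    fine_shape = tuple(n * ss for n in shape)
    fine_spacing = spacing / ss
    # supersample voxel centers tile each coarse voxel
    fine_origin = origin - spacing / 2.0 + fine_spacing / 2.0

    # restrict membership tests to points within rmax of the centerline
    tree = cKDTree(pts)
    axes = [
        fine_origin[a] + np.arange(fine_shape[a]) * fine_spacing[a] for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", copy=False)
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dist, idx = tree.query(coords, workers=-1, distance_upper_bound=rmax * 1.05 + step)
    cand = np.isfinite(dist)
    inside = np.zeros(coords.shape[0], dtype=bool)
    if np.any(cand):
        ci = idx[cand]
        rel = coords[cand] - pts[ci]
        u = np.einsum("ij,ij->i", rel, n1[ci])
        v = np.einsum("ij,ij->i", rel, n2[ci])
        w = np.einsum("ij,ij->i", rel, tans[ci])
        s_proj = s_st[ci] + w
        scale = np.sqrt(factor(s_st[ci]))  # area scales by the stenosis factor
        inside[cand] = (
            profile.contains(u / scale, v / scale)
            & (s_proj >= 0.0)  # flat end caps: no lumen beyond the endpoints
            & (s_proj <= length)
        )
    indicator = inside.reshape(fine_shape).astype(np.float32)

    if spec.calcific is not None:
        ins = spec.calcific
        c_pt = curve.point(np.array([ins.s]))[0]
        ci = int(np.argmin(np.abs(s_st - ins.s)))
        center = c_pt + n1[ci] * ins.radial_offset
        d2 = ((coords - center) ** 2).sum(axis=1)
        calc = (d2 <= ins.radius**2).reshape(fine_shape)
    else:
        calc = None

    def block_mean(fine: np.ndarray) -> np.ndarray:
        return fine.reshape(
            shape[0], ss, shape[1], ss, shape[2], ss
        ).mean(axis=(1, 3, 5))

    frac = block_mean(indicator)
    hu = spec.background_hu + (spec.lumen_hu - spec.background_hu) * frac
    if calc is not None:
        cfrac = block_mean(calc.astype(np.float32))
        hu = hu + np.maximum(spec.calcific.hu - hu, 0.0) * cfrac

    if spec.psf_sigma > 0:
        hu = gaussian_filter(hu, sigma=spec.psf_sigma / spacing, mode="nearest")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)

    vol = Volume(hu.astype(np.float32), tuple(spacing), tuple(origin))

    # truth callables close over the analytic profile
    nominal = profile.area()
    d_nom = profile.inscribed_diameter()

    def csa(s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any((s < -1e-9) | (s > length + 1e-9)):
            raise ValueError(f"arc length outside [0, {length:.3f}] mm")
        return nominal * factor(s)

    def inscribed(s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any((s < -1e-9) | (s > length + 1e-9)):
            raise ValueError(f"arc length outside [0, {length:.3f}] mm")
        return d_nom * np.sqrt(factor(s))

    truth = GroundTruth(
        s=s_st,
        points=pts,
        tangents=tans,
        csa=csa,
        inscribed_diameter=inscribed,
        length=length,
        nominal_area=nominal,
    )
    return vol, truth


def analytic_csa(gt: GroundTruth, s) -> np.ndarray:
    """Exact lumen area (mm^2) of the cross-section normal to the axis at ``s``."""
    return gt.csa(s)
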