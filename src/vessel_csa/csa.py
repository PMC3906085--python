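"""Shape-free cross-sectional area along the centerline.

At each station a cutting plane normal to the local tangent is intersected
with the lumen surface mesh; the resulting closed contour is measured
directly — polygon area by the shoelace sum and lumen "diameter" as the
largest inscribed circle — with no circularity assumption anywhere, which is
what keeps the measurement honest on crescent-shaped and stenotic lumens.
Planes that deviate (crossing a neighbor inside the lumen, or producing an
area wildly off both neighbors) are repaired by interpolating center and
normal from their valid neighbors and re-slicing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize
from shapely.geometry import Point, Polygon

from .centerline import Centerline, resample as _resample_centerline

__all__ = [
    "CrossSection",
    "CSAProfile",
    "slice_mesh",
    "polygon_area",
    "inscribed_diameter",
    "equivalent_diameter",
    "build_profile",
]

log = logging.getLogger(__name__)

AREA_JUMP_FRACTION = 0.30
MAX_REPAIR_ROUNDS = 3
END_MARGIN_MM = 1.5


@dataclass
class CrossSection:
    s: float  # arc length, mm
    center: np.ndarray  # 3D point on the centerline
    normal: np.ndarray  # unit cutting-plane normal
    polygon: np.ndarray  # (k, 3) ordered vertex loop (closed implicitly)
    area: float  # mm^2
    inscribed_diam: float  # mm
    flag: str = "ok"  # ok | repaired | excluded

    @property
    def equivalent_diam(self) -> float:
        return equivalent_diameter(self.area)


@dataclass
class CSAProfile:
    sections: list[CrossSection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def valid_sections(self) -> list[CrossSection]:
        return [c for c in self.sections if c.flag != "excluded"]

    @property
    def s(self) -> np.ndarray:
        return np.array([c.s for c in self.valid_sections])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.valid_sections])

    @property
    def inscribed_diams(self) -> np.ndarray:
        return np.array([c.inscribed_diam for c in self.valid_sections])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "s_mm": [c.s for c in self.sections],
                "area_mm2": [c.area for c in self.sections],
                "inscribed_diam_mm": [c.inscribed_diam for c in self.sections],
                "equiv_diam_mm": [c.equivalent_diam for c in self.sections],
                "flag": [c.flag for c in self.sections],
            }
        )

    def write_csv(self, path: str) -> str:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")
        return path


# ---------------------------------------------------------------------------
# plane-mesh intersection


def slice_mesh(m: trimesh.Trimesh, center, normal, all_loops: bool = False):
    """Closed intersection contour(s) of a plane with the lumen mesh.

    Triangle-plane intersection segments are chained into closed loops; the
    loop containing ``center`` (projected into the plane), or failing that the
    loop whose centroid is nearest, is returned as the lumen contour.  With
    ``all_loops=True`` every closed loop is returned.
    """
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    section = m.section(plane_origin=center, plane_normal=normal)
    if section is None:
        raise ValueError(f"plane at {center} does not intersect the mesh")
    loops = []
    for poly in section.discrete:
        closed = np.allclose(poly[0], poly[-1], atol=1e-8)
        if not closed:
            gap = np.linalg.norm(poly[0] - poly[-1])
            raise ValueError(
                f"open intersection chain (gap {gap:.3g} mm near {poly[-1]}): "
                "mesh is not watertight there"
            )
        loop = poly[:-1]
        if len(loop) >= 3:
            loops.append(loop)
    if not loops:
        raise ValueError("plane produced no usable (>=3 vertex) loop")
    if all_loops:
        return loops
    return _pick_loop(loops, center, normal)


def _pick_loop(loops, center, normal) -> np.ndarray:
    e1, e2 = _plane_basis(normal)
    c2 = np.array([np.dot(center, e1), np.dot(center, e2)])
    containing = []
    for loop in loops:
        uv = np.column_stack([loop @ e1, loop @ e2])
        if Polygon(uv).contains(Point(c2)):
            containing.append((Polygon(uv).area, loop))
    if containing:
        # innermost containing loop = the lumen wall around the centerline point
        return min(containing, key=lambda t: t[0])[1]
    cents = np.array([loop.mean(axis=0) for loop in loops])
    return loops[int(np.argmin(np.linalg.norm(cents - center, axis=1)))]


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# contour measures


def _project_loop(loop: np.ndarray) -> np.ndarray:
    """Project a near-planar 3D loop onto its best-fit plane (SVD), -> (k, 2)."""
    loop = np.asarray(loop, dtype=float)
    c = loop.mean(axis=0)
    _, _, vt = np.linalg.svd(loop - c, full_matrices=False)
    return (loop - c) @ vt[:2].T


def polygon_area(loop: np.ndarray) -> float:
    """Shoelace area of a closed planar 3D (or 2D) polygon, orientation-free."""
    loop = np.asarray(loop, dtype=float)
    if loop.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    uv = loop if loop.shape[1] == 2 else _project_loop(loop)
    x, y = uv[:, 0], uv[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def inscribed_diameter(loop: np.ndarray, grid_fraction: float = 1 / 20) -> float:
    """Diameter of the largest circle contained in the polygon.

    Coarse search on a grid at ``grid_fraction`` of the equivalent radius,
    followed by Nelder-Mead refinement of the signed distance to the boundary.
    Robust on non-convex (crescent) contours, where centroid-based tricks fail.
    """
    loop = np.asarray(loop, dtype=float)
    uv = loop if loop.shape[1] == 2 else _project_loop(loop)
    poly = Polygon(uv)
    if not poly.is_valid:
        poly = poly.buffer(0)
    boundary = poly.exterior

    area = poly.area
    step = max(grid_fraction * math.sqrt(area / math.pi), 1e-6)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + step / 2, maxx, step)
    ys = np.arange(miny + step / 2, maxy, step)
    X, Y = np.meshgrid(xs, ys)
    from shapely import contains_xy, points as shapely_points

    inside = contains_xy(poly, X.ravel(), Y.ravel())
    if not inside.any():
        # degenerate sliver: fall back to the centroid
        starts = [np.asarray(poly.representative_point().coords[0])]
    else:
        import shapely

        cand = np.column_stack([X.ravel()[inside], Y.ravel()[inside]])
        d = shapely.distance(boundary, shapely_points(cand))
        # a non-convex contour can hold several competing pockets: refine
        # from a few well-separated near-optimal grid cells, not just one
        order = np.argsort(-d)
        starts, min_sep = [], 4.0 * step
        for i in order:
            p = cand[i]
            if all(np.linalg.norm(p - q) >= min_sep for q in starts):
                starts.append(p)
            if len(starts) == 3 or d[i] < 0.8 * d[order[0]]:
                break

    def neg_signed_dist(p):
        pt = Point(p)
        d = boundary.distance(pt)
        return -d if poly.contains(pt) else d

    r = 0.0
    for start in starts:
        res = minimize(
            neg_signed_dist,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-4 * step, "fatol": 1e-10, "maxiter": 400},
        )
        r = max(r, -res.fun, -neg_signed_dist(start))
    return float(2.0 * r)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: 2 sqrt(area / pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return float(2.0 * math.sqrt(area / math.pi))


# ---------------------------------------------------------------------------
# profile construction with deviated-plane repair


def _planes_cross_inside(c1, n1, a1, c2, n2, a2) -> bool:
    """Do two cutting planes intersect within the lumen radius of either section?"""
    d = np.cross(n1, n2)
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return False  # parallel planes never cross
    d = d / nd
    # a point on the intersection line of the two planes
    b = np.array([np.dot(n1, c1), np.dot(n2, c2)])
    A = np.vstack([n1, n2])
    p0 = np.linalg.lstsq(A, b, rcond=None)[0]
    for c, a in ((c1, a1), (c2, a2)):
        r = equivalent_diameter(a) / 2.0 if a > 0 else 0.0
        rel = c - p0
        dist_line = np.linalg.norm(rel - np.dot(rel, d) * d)
        if dist_line < r:
            return True
    return False


def _slice_section(m, s, center, normal, flag="ok") -> CrossSection:
    loop = slice_mesh(m, center, normal)
    area = polygon_area(loop)
    return CrossSection(
        s=float(s),
        center=np.asarray(center, dtype=float),
        normal=np.asarray(normal, dtype=float),
        polygon=loop,
        area=area,
        inscribed_diam=inscribed_diameter(loop),
        flag=flag,
    )


def build_profile(
    m: trimesh.Trimesh,
    c: Centerline,
    step: float = 0.25,
    area_jump: float = AREA_JUMP_FRACTION,
    max_repair_rounds: int = MAX_REPAIR_ROUNDS,
    end_margin: float = END_MARGIN_MM,
) -> CSAProfile:
    """Cross-section per arc-length station, with deviated-plane detection/repair.

    A plane is deviated when it crosses a neighboring plane inside the lumen,
    or when its area jumps more than ``area_jump`` relative to both neighbors.
    Deviated planes are repaired by replacing center and normal with the
    average of the valid neighbors and re-slicing, up to
    ``max_repair_rounds``; irreparable stations are flagged ``excluded``.

    Stations within ``end_margin`` mm of either centerline end are skipped:
    thinning leaves jagged, sometimes hooked path endpoints (their positions
    are preserved exactly through smoothing), and a plane with such an end
    tangent shaves a sliver off the surface cap instead of cutting a true
    cross-section.
    """
    cl = _resample_centerline(c, step)
    keep = (cl.arc_lengths >= end_margin - 1e-9) & (
        cl.arc_lengths <= cl.length - end_margin + 1e-9
    )
    if not keep.any():
        raise ValueError("centerline shorter than twice the end margin")
    cl = Centerline(cl.points[keep], cl.arc_lengths[keep], cl.tangents[keep])
    n_st = len(cl.points)
    sections: list[CrossSection | None] = [None] * n_st
    for i in range(n_st):
        try:
            sections[i] = _slice_section(
                m, cl.arc_lengths[i], cl.points[i], cl.tangents[i]
            )
        except ValueError as exc:
            log.warning("station %d (s=%.2f mm): %s", i, cl.arc_lengths[i], exc)
            sections[i] = CrossSection(
                s=float(cl.arc_lengths[i]),
                center=cl.points[i],
                normal=cl.tangents[i],
                polygon=np.empty((0, 3)),
                area=float("nan"),
                inscribed_diam=float("nan"),
                flag="excluded",
            )

    for round_ in range(max_repair_rounds):
        deviated = _find_deviated(sections, area_jump)
        if not deviated:
            break
        for i in deviated:
            prev_ok = next(
                (sections[j] for j in range(i - 1, -1, -1) if sections[j].flag != "excluded" and j not in deviated),
                None,
            )
            next_ok = next(
                (sections[j] for j in range(i + 1, n_st) if sections[j].flag != "excluded" and j not in deviated),
                None,
            )
            if prev_ok is None or next_ok is None:
                continue
            w = (sections[i].s - prev_ok.s) / max(next_ok.s - prev_ok.s, 1e-9)
            center = (1 - w) * prev_ok.center + w * next_ok.center
            normal = (1 - w) * prev_ok.normal + w * next_ok.normal
            nn = np.linalg.norm(normal)
            if nn < 1e-9:
                continue
            normal = normal / nn
            try:
                sections[i] = _slice_section(
                    m, sections[i].s, center, normal, flag="repaired"
                )
            except ValueError as exc:
                log.warning("repair failed at station %d: %s", i, exc)
    else:
        deviated = _find_deviated(sections, area_jump)
        for i in deviated:
            sections[i].flag = "excluded"
            log.warning(
                "station %d (s=%.2f mm) still deviated after %d repair rounds; excluded",
                i,
                sections[i].s,
                max_repair_rounds,
            )

    return CSAProfile([s for s in sections if s is not None])


def _find_deviated(sections, area_jump) -> list[int]:
    n = len(sections)
    bad = []
    for i, sec in enumerate(sections):
        if sec.flag == "excluded":
            continue
        neighbors = [
            sections[j]
            for j in (i - 1, i + 1)
            if 0 <= j < n and sections[j].flag != "excluded"
        ]
        if not neighbors:
            continue
        jumps = [
            abs(sec.area - nb.area) / nb.area for nb in neighbors if nb.area > 0
        ]
        if jumps and all(j > area_jump for j in jumps):
            bad.append(i)
            continue
        for nb in neighbors:
            if _planes_cross_inside(
                sec.center, sec.normal, sec.area, nb.center, nb.normal, nb.area
            ):
                bad.append(i)
                break
    return bad
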