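"""Sub-voxel centerline extraction.

A discrete curve skeleton from topology-preserving 3D thinning is inherently
jagged: each voxel sits on the grid, so the raw path staircases with errors
up to half a voxel, worst at high curvature.  The pipeline therefore refines
in three steps, all in continuous coordinates:

1. prune the skeleton graph to a single main path (the vessel of interest is
   branch-free by assumption; side branches are discarded),
2. moving-average smoothing to knock down the grid zigzag,
3. overlapping local cubic Bezier curves, blended across their overlaps —
   control points need not lie on the curve, which is exactly what lets the
   fit cut through the jag while the *local* windows prevent the global
   over-smoothing a single high-order fit would cause.

The refined curve is densely sampled, arc-length reparameterized, and carries
unit tangents, which downstream become cutting-plane normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .thinning import skeletonize_3d
from .volume_io import LabelMask

__all__ = [
    "Skeleton",
    "Centerline",
    "thin_skeleton",
    "extract_main_path",
    "smooth_points",
    "bezier_refine",
    "resample",
]

_NEIGHBORS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


@dataclass
class Skeleton:
    """Thinned voxel set with its 26-neighborhood adjacency graph.

    ``depth`` maps each skeleton voxel to its distance-to-boundary (mm) in
    the original mask — the local lumen radius, used to judge whether a
    terminal branch is a real vessel continuation or a surface-bump artifact.
    """

    voxels: list[tuple[int, int, int]]
    graph: nx.Graph
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    depth: dict | None = None

    def __len__(self) -> int:
        return len(self.voxels)

    def world(self, voxel) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(voxel, dtype=float) * np.asarray(
            self.spacing
        )


@dataclass
class Centerline:
    """Ordered sub-voxel points with arc-length parameterization and unit tangents."""

    points: np.ndarray  # (n, 3) world mm
    arc_lengths: np.ndarray  # (n,) cumulative mm, strictly increasing
    tangents: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_lengths = np.asarray(self.arc_lengths, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        if np.any(np.diff(self.arc_lengths) <= 0):
            raise ValueError("arc lengths must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def __len__(self) -> int:
        return len(self.points)


def _build_centerline(points: np.ndarray) -> Centerline:
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    points = points[keep]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = np.gradient(points, s, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return Centerline(points, s, tangents)


# ---------------------------------------------------------------------------
# thinning


def thin_skeleton(mask: LabelMask) -> Skeleton:
    """Topology-preserving 3D thinning of the lumen mask to a curve skeleton.

    Sequential simple-point deletion in distance-transform order (see
    :mod:`vessel_csa.thinning`): only voxels whose removal leaves both the
    foreground's 26-connectivity and the background's 6-connectivity intact
    are deleted, so the skeleton stays connected and inside the object.
    """
    fg = mask.data > 0
    from scipy import ndimage

    labels, ncomp = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if ncomp == 0:
        raise ValueError("empty mask")
    if ncomp > 1:
        raise ValueError(
            f"mask has {ncomp} connected components; split it and thin each separately"
        )
    # a contrast-filled lumen is solid: interior cavities are segmentation
    # noise, and homotopic thinning would otherwise preserve each one as a
    # closed medial surface instead of a curve
    fg = ndimage.binary_fill_holes(fg)
    skel = skeletonize_3d(fg, spacing=mask.spacing)
    voxels = sorted(map(tuple, np.argwhere(skel)))
    g = nx.Graph()
    vox_set = set(voxels)
    g.add_nodes_from(voxels)
    spacing = np.asarray(mask.spacing)
    for v in voxels:
        for off in _NEIGHBORS_26:
            nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if nb in vox_set and nb > v:
                w = float(np.linalg.norm(np.asarray(off) * spacing))
                g.add_edge(v, nb, weight=w)
    dist = ndimage.distance_transform_edt(fg, sampling=mask.spacing)
    depth = {v: float(dist[v]) for v in voxels}
    return Skeleton(voxels, g, mask.spacing, mask.origin, depth)


_BRANCH_DEPTH_RATIO = 0.5  # leaf must keep at least half the junction's depth


def _prune_insignificant_branches(s: Skeleton) -> nx.Graph:
    """Drop terminal branches that dive toward the lumen surface.

    The medial axis of a tube keeps its distance-to-boundary near the local
    radius along its whole run, including the (retracted) ends.  A noise bump
    fused to the wall grows a medial branch that descends to the surface, so
    its leaf is much shallower than the junction it hangs off.  Prune a
    terminal branch when the leaf's depth falls below half the junction's;
    iterate so stubs exposed by one round are re-examined.
    """
    g = s.graph.copy()
    depth = s.depth or {}
    for _round in range(16):
        changed = False
        for leaf in sorted(n for n in g.nodes if g.degree(n) == 1):
            if not g.has_node(leaf) or g.degree(leaf) != 1:
                continue  # removed or merged during this round
            chain = [leaf]
            cur, prev = leaf, None
            while g.degree(cur) <= 2:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                chain.append(cur)
            # trim from the leaf until the chain regains half its peak depth;
            # a bump branch is shallow throughout, so it vanishes up to its
            # junction, while a true vessel run only sheds its whisker tip
            dmax = max(depth.get(v, 0.0) for v in chain)
            cut = 0
            limit = len(chain) - 1 if g.degree(cur) >= 3 else len(chain) - 2
            while cut < limit and depth.get(chain[cut], 0.0) < _BRANCH_DEPTH_RATIO * dmax:
                cut += 1
            if cut and g.number_of_nodes() - cut >= 2:
                g.remove_nodes_from(chain[:cut])
                changed = True
        if not changed:
            break
    return g


def extract_main_path(
    s: Skeleton, endpoints: tuple | None = None
) -> list[tuple[int, int, int]]:
    """Single ordered voxel path through the skeleton; side branches discarded.

    With explicit endpoints (voxel indices, snapped to the skeleton within 3
    voxels) the weighted shortest path between them is returned; otherwise
    insignificant terminal branches are pruned and the graph-diameter path
    (the longest shortest-path, endpoints drawn from the skeleton's degree-1
    leaves, lexicographically smallest pair on ties) is returned.
    """
    g = s.graph
    if g.number_of_nodes() == 1:
        return list(g.nodes)
    if not nx.is_connected(g):
        raise ValueError("skeleton graph is not connected")

    if endpoints is not None:
        a, b = (_snap(s, e) for e in endpoints)
        return nx.shortest_path(g, a, b, weight="weight")

    g = _prune_insignificant_branches(s)
    leaves = sorted(n for n in g.nodes if g.degree(n) <= 1)
    if not leaves:  # pure cycle: fall back to all nodes as candidates
        leaves = sorted(g.nodes)
    best = None
    for src in leaves:
        dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        far = max(dist.items(), key=lambda kv: (kv[1], tuple(-c for c in kv[0])))
        cand = (far[1], tuple(sorted((src, far[0]))))
        if best is None or cand[0] > best[0] + 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    a, b = best[1]
    path = nx.shortest_path(g, a, b, weight="weight")
    return _retract_path_ends(s, path)


def _retract_path_ends(s: Skeleton, path: list) -> list:
    """Retract each path end to where the lumen regains its full caliber.

    Near the cut faces of the vessel the distance field is cap-limited, and
    thinning there may wander off the true axis by up to the lumen radius;
    path ends are dropped while their depth sits below 90% of the skeleton's
    typical (75th-percentile) depth, i.e. until the centerline runs through
    full-caliber lumen again.
    """
    if len(path) < 6 or not s.depth:
        return path
    threshold = 0.9 * float(np.percentile(list(s.depth.values()), 75))
    lo, hi = 0, len(path) - 1
    while lo < hi - 2 and s.depth.get(tuple(path[lo]), 0.0) < threshold:
        lo += 1
    while hi > lo + 2 and s.depth.get(tuple(path[hi]), 0.0) < threshold:
        hi -= 1
    if hi - lo + 1 < 4:
        return path
    return path[lo : hi + 1]


def _snap(s: Skeleton, endpoint) -> tuple[int, int, int]:
    endpoint = tuple(int(c) for c in endpoint)
    if s.graph.has_node(endpoint):
        return endpoint
    tree = cKDTree(np.asarray(s.voxels, dtype=float))
    d, i = tree.query(np.asarray(endpoint, dtype=float))
    if d > 3.0:
        raise ValueError(f"endpoint {endpoint} is {d:.1f} voxels from the skeleton (>3)")
    return tuple(s.voxels[i])


# ---------------------------------------------------------------------------
# smoothing and Bezier refinement


def smooth_points(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing with a shrinking window at the ends.

    The window shrinks symmetrically near the endpoints (size ``2k+1`` at
    distance ``k`` from an end), so the first and last points are preserved
    exactly.
    """
    path = np.asarray(path, dtype=float)
    n = len(path)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > n:
        raise ValueError("window exceeds path length")
    half = window // 2
    out = np.empty_like(path)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = path[i - k : i + k + 1].mean(axis=0)
    return out


def _bezier(ctrl: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic Bezier with 4 control points, evaluated at parameters t in [0,1]."""
    t = t[:, None]
    u = 1.0 - t
    return (
        u**3 * ctrl[0]
        + 3 * u**2 * t * ctrl[1]
        + 3 * u * t**2 * ctrl[2]
        + t**3 * ctrl[3]
    )


def bezier_refine(
    path: np.ndarray,
    window: int = 4,
    samples_per_segment: int = 10,
    spacing=None,
    origin=None,
) -> Centerline:
    """Piecewise local cubic Bezier smoothing of an ordered point path.

    Windows of 4 consecutive points (advancing by 2, i.e. 50% overlap) each
    define a cubic Bezier; where two windows cover the same stretch their
    curves are blended linearly, giving a continuous composite that tracks
    the path without global over-smoothing.  The composite is densely
    sampled and arc-length reparameterized; tangents come from central
    differences of the resampled curve.

    ``path`` may be voxel indices (pass ``spacing``/``origin`` to map to
    world mm) or world-coordinate points.
    """
    if window != 4:
        raise ValueError("local curves are cubic: window must be 4")
    pts = np.asarray(path, dtype=float)
    if spacing is not None:
        orig = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
        pts = orig + pts * np.asarray(spacing, dtype=float)
    # deduplicate consecutive repeats
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 1e-12):
        warnings.warn("removing repeated consecutive points from path")
        pts = pts[np.concatenate([[True], seg > 1e-12])]
    n = len(pts)
    if n < 4:
        raise ValueError("need at least 4 distinct points for cubic refinement")

    starts = list(range(0, n - 3, 2))
    if starts[-1] != n - 4:
        starts.append(n - 4)  # final window ends exactly at the last point

    # dense global parameter u in point-index space [0, n-1]
    n_dense = (n - 1) * samples_per_segment + 1
    u = np.linspace(0.0, n - 1, n_dense)
    acc = np.zeros((n_dense, 3))
    wacc = np.zeros(n_dense)
    for i in starts:
        t = (u - i) / 3.0
        sel = (t >= -1e-12) & (t <= 1.0 + 1e-12)
        tsel = np.clip(t[sel], 0.0, 1.0)
        curve = _bezier(pts[i : i + 4], tsel)
        # hat weight: ramps over the first/last index unit of the window so
        # overlapping windows cross-fade; full weight in the middle
        w = np.minimum(np.minimum(u[sel] - i, (i + 3) - u[sel]), 1.0)
        w = np.clip(w, 1e-6, 1.0)
        if i == 0:
            w = np.where(u[sel] <= i + 1, 1.0, w)
        if i == starts[-1]:
            w = np.where(u[sel] >= i + 2, 1.0, w)
        acc[sel] += w[:, None] * curve
        wacc[sel] += w
    dense = acc / wacc[:, None]
    # endpoints are clamped: every window's Bezier interpolates its end controls
    dense[0] = pts[0]
    dense[-1] = pts[-1]
    return _build_centerline(dense)


def resample(c: Centerline, step: float) -> Centerline:
    """Uniform arc-length resampling; first and last points preserved."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(int(round(c.length / step)), 1) + 1
    s_new = np.linspace(0.0, c.length, n)
    pts = np.column_stack(
        [np.interp(s_new, c.arc_lengths, c.points[:, i]) for i in range(3)]
    )
    return _build_centerline(pts)
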