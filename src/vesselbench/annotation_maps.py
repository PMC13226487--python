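"""From annotated skeletons to supervision probability maps and region masks.

The training target for a vessel-segmentation network is rendered from the
centerline and per-point radii: the skeleton is smoothed (branch points and
endpoints held fixed), resampled at one-voxel arc-length intervals, and a
Gaussian kernel whose width is matched to the local vessel radius is stamped
at every resampled point.  The kernel width is chosen so that the 0.404
iso-level of the rendered map coincides with the vessel wall:

    sigma_p = r_p / sqrt(2 ln(1 / boundary_level))

which makes the strict-foreground region S2 (map > 0.404) the vessel
interior and S1 (map > 0.012, about 2.2 r) the surrounding transition halo.
Kernels are composed with a voxelwise maximum so centerline voxels are
exactly 1, and truncated at 3 sigma (value ~0.011, below the outer
threshold, so the truncation is invisible to the region masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep

from .core_model import Skeleton, SkeletonNode, VascularGraph, VoxelSize, Volume, build_graph

__all__ = [
    "ResampledCenterline",
    "RegionMasks",
    "T1_DEFAULT",
    "T2_DEFAULT",
    "smooth_skeleton",
    "resample_centerline",
    "resample_polyline",
    "render_probability_map",
    "extract_regions",
]

T1_DEFAULT = 0.012
T2_DEFAULT = 0.404


@dataclass
class ResampledCenterline:
    """One graph edge resampled at ~unit voxel-index arc-length spacing."""

    points: np.ndarray  # (n, 3) continuous (x, y, z) voxel coords
    radii: np.ndarray  # (n,) physical um
    edge: tuple[int, int, int]  # (u, v, key) provenance in the vascular graph


@dataclass
class RegionMasks:
    """Loss regions: S1/S2 from the ground truth, S2* from the prediction."""

    S1: np.ndarray
    S2: np.ndarray
    S2star: np.ndarray
    t1: float = T1_DEFAULT
    t2: float = T2_DEFAULT


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along a polyline; ends use shrinking windows."""
    n = len(points)
    half = window // 2
    out = np.empty_like(points)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def smooth_skeleton(
    skel: Skeleton, window: int = 5, spline_degree: int = 3
) -> Skeleton:
    """Smooth each edge polyline, holding branch points and endpoints fixed.

    Hybrid strategy: interior points of each edge are replaced by a centered
    moving average (window ``window``), then a degree-``spline_degree``
    B-spline is fitted through the smoothed sequence and re-evaluated at
    uniform parameters, with the first and last points clamped back to the
    original endpoint/branch coordinates.  Topology, node count and node ids
    are unchanged; edges shorter than ``window`` are returned as-is.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    graph = build_graph(skel)
    new_pos: dict[int, np.ndarray] = {}
    for u, v, key, data in graph.graph.edges(keys=True, data=True):
        path = data["path"]
        if len(path) < max(window, 4):
            continue
        pts = np.stack([skel.node(i).pos for i in path])
        smoothed = pts.copy()
        smoothed[1:-1] = _moving_average(pts, window)[1:-1]
        k = min(spline_degree, len(path) - 1)
        try:
            tck, _ = splprep(smoothed.T, k=k, s=0.0)
            u_new = np.linspace(0.0, 1.0, len(path))
            smoothed = np.stack(splev(u_new, tck)).T
        except (ValueError, TypeError):
            pass  # degenerate geometry (e.g. repeated points): keep averages
        smoothed[0] = pts[0]
        smoothed[-1] = pts[-1]
        for node_id, p in zip(path[1:-1], smoothed[1:-1]):
            new_pos[node_id] = p
    nodes = [
        SkeletonNode(n.id, n.node_type, new_pos.get(n.id, n.pos).copy(), n.radius, n.parent)
        for n in skel.nodes
    ]
    return Skeleton(nodes, [tuple(fl) for fl in skel.fusion_links])


def resample_polyline(
    points: np.ndarray, radii: np.ndarray, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resample one polyline (voxel-index space) at <= ``step``.

    Both endpoints are always included; positions and radii are linearly
    interpolated.  A zero-length polyline collapses to a single point.
    """
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(points) == 1:
        return points.copy(), radii.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return points[:1].copy(), radii[:1].copy()
    n = int(np.ceil(total / step)) + 1
    targets = np.linspace(0.0, total, n)
    out = np.stack([np.interp(targets, arc, points[:, a]) for a in range(3)], axis=1)
    out_r = np.interp(targets, arc, radii)
    return out, out_r


def resample_centerline(
    skel: Skeleton, step: float = 1.0, graph: VascularGraph | None = None
) -> list[ResampledCenterline]:
    """Resample every graph edge of a skeleton at ~one-voxel intervals."""
    if graph is None:
        graph = build_graph(skel)
    out: list[ResampledCenterline] = []
    for u, v, key, data in sorted(graph.graph.edges(keys=True, data=True)):
        path = data["path"]
        pts = np.stack([skel.node(i).pos for i in path])
        rad = np.array([skel.node(i).radius for i in path])
        rp, rr = resample_polyline(pts, rad, step)
        out.append(ResampledCenterline(rp, rr, (u, v, key)))
    # isolated single nodes still contribute a point
    for nid in graph.graph.nodes:
        if graph.graph.degree(nid) == 0:
            n = skel.node(nid)
            out.append(
                ResampledCenterline(
                    n.pos[None, :].copy(), np.array([n.radius]), (nid, nid, -1)
                )
            )
    return out


def render_probability_map(
    centerlines: list[ResampledCenterline],
    shape: tuple[int, int, int],
    voxel_size: VoxelSize | None = None,
    boundary_level: float = T2_DEFAULT,
) -> Volume:
    """Stamp radius-matched Gaussian kernels at every centerline point.

    map(v) = max_p exp(-d_phys(v, p)^2 / (2 sigma_p^2)) with
    sigma_p = r_p / sqrt(2 ln(1/boundary_level)), so the map crosses
    ``boundary_level`` exactly at physical distance r_p from an isolated
    point.  Composition across points is a voxelwise maximum; kernels are
    truncated at 3 sigma.  Points with r = 0 contribute a single-voxel
    impulse of value 1.
    """
    if not (0 < boundary_level < 1):
        raise ValueError("boundary_level must be in (0, 1)")
    vs = voxel_size or VoxelSize()
    nz, ny, nx = shape
    dims_xyz = np.array([nx, ny, nz])
    svec = vs.xyz
    denom = np.sqrt(2.0 * np.log(1.0 / boundary_level))
    out = np.zeros(shape, dtype=np.float64)
    for cl in centerlines:
        for p, r in zip(cl.points, cl.radii):
            if np.any(p < -0.5) or np.any(p > dims_xyz - 0.5):
                raise ValueError(f"centerline point {p} outside volume {shape}")
            if r <= 0:
                idx = np.clip(np.round(p).astype(int), 0, dims_xyz - 1)
                out[idx[2], idx[1], idx[0]] = 1.0
                continue
            sigma = r / denom
            reach = 3.0 * sigma
            half = np.ceil(reach / svec).astype(int)
            lo = np.maximum(np.round(p).astype(int) - half, 0)
            hi = np.minimum(np.round(p).astype(int) + half, dims_xyz - 1)
            if np.any(lo > hi):
                continue
            xs = (np.arange(lo[0], hi[0] + 1) - p[0]) * svec[0]
            ys = (np.arange(lo[1], hi[1] + 1) - p[1]) * svec[1]
            zs = (np.arange(lo[2], hi[2] + 1) - p[2]) * svec[2]
            d2 = (
                zs[:, None, None] ** 2
                + ys[None, :, None] ** 2
                + xs[None, None, :] ** 2
            )
            patch = np.exp(-d2 / (2.0 * sigma * sigma))
            patch[d2 > reach * reach] = 0.0
            sub = (
                slice(lo[2], hi[2] + 1),
                slice(lo[1], hi[1] + 1),
                slice(lo[0], hi[0] + 1),
            )
            np.maximum(out[sub], patch, out=out[sub])
    return Volume(out, vs)


def extract_regions(
    gt_map: Volume | np.ndarray,
    pred_map: Volume | np.ndarray,
    t1: float = T1_DEFAULT,
    t2: float = T2_DEFAULT,
) -> RegionMasks:
    """Threshold ground truth and prediction into the loss regions.

    S1 = {gt > t1}, S2 = {gt > t2}, S2* = {pred > t2}; strict inequalities.
    With t2 > t1, S2 is a subset of S1 by construction.
    """
    gt = gt_map.data if isinstance(gt_map, Volume) else np.asarray(gt_map)
    pred = pred_map.data if isinstance(pred_map, Volume) else np.asarray(pred_map)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    return RegionMasks(S1=gt > t1, S2=gt > t2, S2star=pred > t2, t1=t1, t2=t2)
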