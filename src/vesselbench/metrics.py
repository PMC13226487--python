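"""Quantitative evaluation of vascular reconstructions.

Centerline and branch-point matching use the nearest-neighbour rule: a
point p of the predicted set P matches the reference set G when its nearest
neighbour in G is closer than a threshold (3 voxels for skeleton points,
5 for branch points; Euclidean distance in voxel-index space).  Recall is
the matched fraction of G against P, precision the matched fraction of P
against G, and F1 their harmonic mean.  Matching is threshold-on-nearest-
neighbour, not one-to-one assignment, so duplicated predictions can inflate
precision; an optional Hungarian one-to-one mode is provided for control
experiments.

Also here: graph statistics (node/edge/degree/component counts), branch
angles, vessel density on a sub-block grid (mm of centerline per mm^3 of
tissue), skeleton-point intensity and radius statistics, SNR, and the
review-region proposer that flags local windows containing either two or
more endpoints or at least one branch point — the places where topology is
most likely to need human correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .annotation_maps import resample_centerline, resample_polyline
from .core_model import Skeleton, VascularGraph, VoxelSize, Volume, build_graph
from .lumen_fill import Segmentation, _as_segmentation

__all__ = [
    "MatchParams",
    "MatchResult",
    "DensityGrid",
    "GraphStats",
    "SkeletonStats",
    "ReviewROI",
    "match_points",
    "resampled_points",
    "evaluate_skeleton",
    "extract_branch_points",
    "extract_endpoints",
    "evaluate_branch_points",
    "branch_angles",
    "vessel_density",
    "skeleton_intensity_stats",
    "snr",
    "graph_stats",
    "smartvision_candidates",
]

THRE_SKELETON = 3.0
THRE_BRANCH = 5.0


@dataclass
class MatchParams:
    """Distance threshold (voxel-index units) and matching options."""

    thre: float = THRE_SKELETON
    squared: bool = False  # compare squared distance against thre instead
    inclusive: bool = False  # use <= instead of the strict <
    one_to_one: bool = False  # Hungarian assignment instead of nearest-neighbour

    def __post_init__(self) -> None:
        if self.thre <= 0:
            raise ValueError("thre must be positive")


@dataclass
class MatchResult:
    recall: float
    precision: float
    f1: float
    n_gt: int
    n_pred: int
    matched_gt: int
    matched_pred: int
    degenerate: bool = False  # empty point set(s) involved


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty((0, 3))
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    return pts


def _f1(recall: float, precision: float) -> float:
    return 2 * recall * precision / (recall + precision) if recall + precision else 0.0


def match_points(
    P, G, params: MatchParams | None = None
) -> MatchResult:
    """Nearest-neighbour threshold matching between two 3D point sets.

    ``P`` is the prediction, ``G`` the reference.  With default params a
    point matches when its nearest-neighbour Euclidean distance is strictly
    below ``thre``.  Degenerate inputs (either set empty) yield zero scores
    with the ``degenerate`` flag set.
    """
    params = params or MatchParams()
    P = _as_points(P)
    G = _as_points(G)
    if len(P) == 0 or len(G) == 0:
        return MatchResult(0.0, 0.0, 0.0, len(G), len(P), 0, 0, degenerate=True)

    def hit(dist: np.ndarray) -> np.ndarray:
        d = dist**2 if params.squared else dist
        return d <= params.thre if params.inclusive else d < params.thre

    if params.one_to_one:
        diff = np.linalg.norm(P[:, None, :] - G[None, :, :], axis=2)
        row, col = linear_sum_assignment(diff)
        good = hit(diff[row, col])
        matched_pred = matched_gt = int(good.sum())
    else:
        d_p = cKDTree(G).query(P)[0]
        d_g = cKDTree(P).query(G)[0]
        matched_pred = int(hit(d_p).sum())
        matched_gt = int(hit(d_g).sum())
    recall = matched_gt / len(G)
    precision = matched_pred / len(P)
    return MatchResult(
        recall, precision, _f1(recall, precision),
        len(G), len(P), matched_gt, matched_pred,
    )


def resampled_points(skel: Skeleton, step: float = 1.0) -> np.ndarray:
    """All centerline sample points of a skeleton at ~``step`` spacing."""
    centerlines = resample_centerline(skel, step=step)
    if not centerlines:
        return np.empty((0, 3))
    return np.concatenate([c.points for c in centerlines])


def evaluate_skeleton(
    pred: Skeleton, gt: Skeleton, step: float = 1.0,
    params: MatchParams | None = None,
) -> MatchResult:
    """Centerline-level F1: resample both skeletons, match at thre = 3."""
    params = params or MatchParams(thre=THRE_SKELETON)
    return match_points(resampled_points(pred, step), resampled_points(gt, step), params)


def extract_branch_points(
    skel: Skeleton, graph: VascularGraph | None = None
) -> np.ndarray:
    """(n, 3) positions of graph nodes with degree >= 3."""
    graph = graph or build_graph(skel)
    pts = [
        skel.node(n).pos for n in graph.graph.nodes if graph.graph.degree(n) >= 3
    ]
    return np.stack(pts) if pts else np.empty((0, 3))


def extract_endpoints(
    skel: Skeleton, graph: VascularGraph | None = None
) -> np.ndarray:
    """(n, 3) positions of graph nodes with degree 1."""
    graph = graph or build_graph(skel)
    pts = [skel.node(n).pos for n in graph.graph.nodes if graph.graph.degree(n) == 1]
    return np.stack(pts) if pts else np.empty((0, 3))


def evaluate_branch_points(
    pred: Skeleton, gt: Skeleton, params: MatchParams | None = None
) -> MatchResult:
    """Branch-point localization F1 at thre = 5."""
    params = params or MatchParams(thre=THRE_BRANCH)
    return match_points(extract_branch_points(pred), extract_branch_points(gt), params)


# ---------------------------------------------------------------------------
# Branch angles
# ---------------------------------------------------------------------------


@dataclass
class BranchAngle:
    node_id: int
    angle_deg: float
    pair_kind: str  # 'child-child' or 'parent-child'
    edges: tuple[tuple[int, int, int], tuple[int, int, int]]


def branch_angles(
    skel: Skeleton,
    k: int = 5,
    voxel_size: VoxelSize | None = None,
    graph: VascularGraph | None = None,
) -> list[BranchAngle]:
    """Angles between edge pairs at every branch node.

    Each incident edge's direction is the unit vector (physical um
    coordinates) from the branch node to the edge's k-th resampled point
    (or the far end of shorter edges); one angle per unordered edge pair,
    labelled child-child or parent-child by the tree orientation of the
    adjacent skeleton node.
    """
    vs = voxel_size or VoxelSize()
    graph = graph or build_graph(skel)
    out: list[BranchAngle] = []
    for node in graph.graph.nodes:
        if graph.graph.degree(node) < 3:
            continue
        npos = skel.node(node).pos * vs.xyz
        dirs: list[tuple[np.ndarray, str, tuple[int, int, int]]] = []
        for u, v, key in graph.graph.edges(node, keys=True):
            data = graph.graph.edges[u, v, key]
            path = data["path"]
            if path[0] != node:
                path = path[::-1]
            pts = np.stack([skel.node(i).pos for i in path])
            rad = np.array([skel.node(i).radius for i in path])
            rp, _ = resample_polyline(pts, rad, step=1.0)
            target = rp[min(k, len(rp) - 1)]
            vec = target * vs.xyz - npos
            norm = np.linalg.norm(vec)
            if norm == 0:
                continue
            neighbour = path[1] if len(path) > 1 else path[0]
            kind = "parent" if skel.node(node).parent == neighbour else "child"
            out_edge = (u, v, key)
            dirs.append((vec / norm, kind, out_edge))
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                cosang = float(np.clip(dirs[i][0] @ dirs[j][0], -1.0, 1.0))
                kinds = sorted((dirs[i][1], dirs[j][1]))
                pair_kind = (
                    "child-child" if kinds == ["child", "child"] else "parent-child"
                )
                out.append(
                    BranchAngle(
                        node_id=node,
                        angle_deg=float(np.degrees(np.arccos(cosang))),
                        pair_kind=pair_kind,
                        edges=(dirs[i][2], dirs[j][2]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Density / intensity / SNR statistics
# ---------------------------------------------------------------------------


@dataclass
class DensityGrid:
    """Per-sub-block centerline densities in mm/mm^3."""

    densities: np.ndarray  # grid indexed (gz, gy, gx)
    cell_volumes_mm3: np.ndarray
    mean: float
    sd: float
    total_length_mm: float


def vessel_density(
    skel: Skeleton,
    block_shape: tuple[int, int, int],
    voxel_size: VoxelSize | None = None,
    cell: int = 64,
) -> DensityGrid:
    """Local vessel density: centerline length per unit volume per sub-block.

    The skeleton is resampled at one-voxel steps; each inter-sample
    segment's physical length is assigned to the sub-block containing its
    midpoint.  Sub-blocks are ``cell``-voxel cubes; blocks not divisible by
    ``cell`` get boundary cells with their exact partial physical volume.
    """
    vs = voxel_size or VoxelSize()
    nz, ny, nx = block_shape
    grid_shape = (int(np.ceil(nz / cell)), int(np.ceil(ny / cell)), int(np.ceil(nx / cell)))
    # exact physical cell volumes (um^3 -> mm^3), boundary cells cropped
    ext_z = np.minimum(cell, nz - cell * np.arange(grid_shape[0])) * vs.sz
    ext_y = np.minimum(cell, ny - cell * np.arange(grid_shape[1])) * vs.sy
    ext_x = np.minimum(cell, nx - cell * np.arange(grid_shape[2])) * vs.sx
    volumes = (
        ext_z[:, None, None] * ext_y[None, :, None] * ext_x[None, None, :] * 1e-9
    )
    lengths = np.zeros(grid_shape)
    total = 0.0
    for cl in resample_centerline(skel, step=1.0):
        pts = cl.points
        if len(pts) < 2:
            continue
        seg_len = np.linalg.norm(np.diff(pts * vs.xyz[None, :], axis=0), axis=1) * 1e-3
        mids = 0.5 * (pts[:-1] + pts[1:])  # (x, y, z)
        gx = np.clip((mids[:, 0] // cell).astype(int), 0, grid_shape[2] - 1)
        gy = np.clip((mids[:, 1] // cell).astype(int), 0, grid_shape[1] - 1)
        gz = np.clip((mids[:, 2] // cell).astype(int), 0, grid_shape[0] - 1)
        np.add.at(lengths, (gz, gy, gx), seg_len)
        total += float(seg_len.sum())
    densities = lengths / volumes
    return DensityGrid(
        densities=densities,
        cell_volumes_mm3=volumes,
        mean=float(densities.mean()),
        sd=float(densities.std()),
        total_length_mm=total,
    )


@dataclass
class SkeletonStats:
    intensity_mean: float
    intensity_sd: float
    radius_mean: float
    radius_sd: float
    n_points: int
    empty: bool = False


def skeleton_intensity_stats(vol: Volume | np.ndarray, skel: Skeleton) -> SkeletonStats:
    """Mean/SD of trilinearly sampled intensity and radius at skeleton points."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    centerlines = resample_centerline(skel, step=1.0)
    if not centerlines:
        return SkeletonStats(0.0, 0.0, 0.0, 0.0, 0, empty=True)
    pts = np.concatenate([c.points for c in centerlines])
    radii = np.concatenate([c.radii for c in centerlines])
    coords = np.stack([pts[:, 2], pts[:, 1], pts[:, 0]])  # zyx for ndimage
    vals = ndimage.map_coordinates(data.astype(float), coords, order=1, mode="nearest")
    return SkeletonStats(
        intensity_mean=float(vals.mean()),
        intensity_sd=float(vals.std()),
        radius_mean=float(radii.mean()),
        radius_sd=float(radii.std()),
        n_points=len(pts),
    )


def snr(
    vol: Volume | np.ndarray,
    gt_mask: Segmentation | np.ndarray,
    dilation: int = 3,
    skel: Skeleton | None = None,
) -> float:
    """Signal-to-noise ratio: vessel signal / background standard deviation.

    Signal is the mean intensity at resampled skeleton points when a
    skeleton is given, else the foreground mean.  Background voxels are
    those outside the mask dilated ``dilation`` times (guard band against
    partial-volume voxels).  A noiseless background returns +inf.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    mask = _as_segmentation(gt_mask).binary
    if not mask.any() or mask.all():
        raise ValueError("mask must be non-empty and not cover the whole volume")
    if skel is not None:
        signal = skeleton_intensity_stats(data, skel).intensity_mean
    else:
        signal = float(data[mask].mean())
    guard = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3)), iterations=dilation)
    background = data[~guard]
    if background.size == 0:
        raise ValueError("dilated mask covers the whole volume; no background left")
    bg_sd = float(background.std())
    if bg_sd == 0:
        return float("inf")
    return signal / bg_sd


# ---------------------------------------------------------------------------
# Graph statistics
# ---------------------------------------------------------------------------


@dataclass
class GraphStats:
    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    n_components: int


def graph_stats(graph: VascularGraph) -> GraphStats:
    g = graph.graph
    degrees = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    assert sum(degrees) == 2 * g.number_of_edges(), "degree-sum identity violated"
    return GraphStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree_histogram=dict(sorted(hist.items())),
        n_components=nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )


# ---------------------------------------------------------------------------
# Review-region proposal
# ---------------------------------------------------------------------------


@dataclass
class ReviewROI:
    corner: tuple[int, int, int]  # (x, y, z) minimum corner
    size: tuple[int, int, int]  # (sx, sy, sz) extent in voxels

    def contains(self, pt: np.ndarray) -> bool:
        c = np.array(self.corner)
        s = np.array(self.size)
        return bool(np.all(pt >= c) & np.all(pt < c + s))


def _axis_starts(extent: int, window: int, stride: int) -> np.ndarray:
    if window >= extent:
        return np.array([0])
    starts = np.arange(0, extent - window + 1, stride)
    if starts[-1] != extent - window:
        starts = np.append(starts, extent - window)
    return starts


def smartvision_candidates(
    skel: Skeleton,
    shape: tuple[int, int, int],
    window: int = 32,
    stride: int = 16,
) -> list[ReviewROI]:
    """Propose local regions whose connectivity likely needs review.

    A sliding window over the volume is flagged when it contains two or
    more skeleton endpoints (possible broken vessel) or at least one branch
    point (topology to verify).  Overlapping flagged windows are merged to
    their bounding boxes; ROIs are returned sorted by corner.
    """
    graph = build_graph(skel)
    endpoints = extract_endpoints(skel, graph)
    branches = extract_branch_points(skel, graph)
    nz, ny, nx = shape
    flagged: list[tuple[np.ndarray, np.ndarray]] = []  # (corner xyz, size xyz)
    for z0 in _axis_starts(nz, window, stride):
        for y0 in _axis_starts(ny, window, stride):
            for x0 in _axis_starts(nx, window, stride):
                corner = np.array([x0, y0, z0], dtype=float)
                size = np.array(
                    [min(window, nx - x0), min(window, ny - y0), min(window, nz - z0)]
                )
                def inside(pts: np.ndarray) -> int:
                    if len(pts) == 0:
                        return 0
                    ok = np.all(pts >= corner, axis=1) & np.all(
                        pts < corner + size, axis=1
                    )
                    return int(ok.sum())
                if inside(endpoints) >= 2 or inside(branches) >= 1:
                    flagged.append((corner.astype(int), size.astype(int)))
    # merge overlapping boxes into bounding boxes, to a fixed point
    boxes = [(c, c + s) for c, s in flagged]
    changed = True
    while changed:
        changed = False
        merged: list[tuple[np.ndarray, np.ndarray]] = []
        for lo, hi in boxes:
            for i, (mlo, mhi) in enumerate(merged):
                if np.all(lo < mhi) and np.all(mlo < hi):  # overlap
                    merged[i] = (np.minimum(lo, mlo), np.maximum(hi, mhi))
                    changed = True
                    break
            else:
                merged.append((lo, hi))
        boxes = merged
    rois = [
        ReviewROI(tuple(int(v) for v in lo), tuple(int(v) for v in hi - lo))
        for lo, hi in boxes
    ]
    rois.sort(key=lambda r: r.corner)
    return rois
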