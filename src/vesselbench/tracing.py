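"""Centerline extraction from binary vessel segmentations.

Two tracers are provided:

* :func:`voxel_scoop` — front-propagation ("scooping") skeletonization.
  Each connected component is seeded at its Euclidean-distance-transform
  maximum; the tracer repeatedly advances the 26-connected shell of
  unvisited foreground, partitions each shell into connected clusters, and
  places a skeleton node at every cluster centroid (radius = distance
  transform there).  A cluster touching more than one active front becomes
  a front merge: one contact is kept as the parent link, the others become
  fusion links, which is how anastomoses (cycles) are recorded.

* :func:`thinning_trace` — topology-preserving 3D thinning to a one-voxel
  skeleton, followed by voxel-graph analysis: skeleton voxels with one
  26-neighbour are endpoints, clusters of voxels with three or more are
  collapsed to junction nodes at their centroid, and degree-2 runs become
  edges.  Cycles surviving thinning are closed with fusion links.

:func:`prune_spurs` removes short terminal twigs that both tracers emit on
thick vessels (a node placed per shell or per voxel of a bulbous surface),
then merges the surviving degree-2 paths, iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .core_model import (
    Skeleton,
    VoxelSize,
    build_graph,
    skeleton_from_adjacency,
)
from .lumen_fill import Segmentation, _as_segmentation

__all__ = ["ScoopParams", "voxel_scoop", "thinning_trace", "prune_spurs"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class ScoopParams:
    connectivity: int = 26
    min_spur_len: int = 5
    seed_policy: str = "edt-max"
    physical_edt: bool = False  # anisotropy-aware distance transform

    def __post_init__(self) -> None:
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is implemented")
        if self.min_spur_len < 1:
            raise ValueError("min_spur_len must be >= 1")


def _edt(mask: np.ndarray, voxel_size: VoxelSize, physical: bool) -> np.ndarray:
    sampling = voxel_size.zyx if physical else None
    return ndimage.distance_transform_edt(mask, sampling=sampling)


def voxel_scoop(
    seg: Segmentation | np.ndarray, params: ScoopParams | None = None
) -> Skeleton:
    """Trace centerlines by propagating and clustering voxel shells.

    Every foreground voxel is visited exactly once.  Returns a skeleton with
    one node per shell cluster; node positions are cluster centroids in
    (x, y, z) voxel coordinates (snapped to the nearest cluster voxel if the
    centroid of a concave cluster falls outside the mask), radii are the
    distance-transform value at the node.  Front merges produce fusion
    links.  Spur pruning is left to :func:`prune_spurs`.
    """
    params = params or ScoopParams()
    seg = _as_segmentation(seg)
    mask = seg.binary
    if not mask.any():
        return Skeleton()

    edt = _edt(mask, seg.voxel_size, params.physical_edt)
    shape = np.array(mask.shape)
    visited = np.zeros(mask.shape, dtype=bool)
    owner = np.full(mask.shape, -1, dtype=np.int64)

    nodes: dict[int, tuple[np.ndarray, float]] = {}  # id -> (pos xyz, radius)
    edges: list[tuple[int, int]] = []
    fusion: list[tuple[int, int]] = []
    next_id = 1

    def new_node(voxels_zyx: np.ndarray) -> int:
        nonlocal next_id
        centroid = voxels_zyx.mean(axis=0)
        idx = np.round(centroid).astype(int)
        if not mask[tuple(idx)]:
            # concave cluster: snap to the member voxel nearest the centroid
            d = np.linalg.norm(voxels_zyx - centroid, axis=1)
            idx = voxels_zyx[int(np.argmin(d))]
            centroid = idx.astype(float)
        nid = next_id
        next_id += 1
        pos_xyz = centroid[::-1].copy()  # (z, y, x) -> (x, y, z)
        nodes[nid] = (pos_xyz, float(edt[tuple(idx)]))
        visited[tuple(voxels_zyx.T)] = True
        owner[tuple(voxels_zyx.T)] = nid
        return nid

    def neighbours(voxels_zyx: np.ndarray) -> np.ndarray:
        cand = (voxels_zyx[:, None, :] + _OFFSETS26[None, :, :]).reshape(-1, 3)
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        if len(cand) == 0:
            return cand
        return np.unique(cand, axis=0)

    remaining = mask & ~visited
    while remaining.any():
        # seed the next component at its distance-transform maximum
        flat = np.where(remaining.ravel(), edt.ravel(), -1.0)
        seed = np.array(np.unravel_index(int(np.argmax(flat)), mask.shape))
        seed_vox = seed[None, :]
        root = new_node(seed_vox)
        active: list[tuple[int, np.ndarray]] = [(root, seed_vox)]

        while active:
            all_vox = np.concatenate([v for _, v in active])
            cand = neighbours(all_vox)
            if len(cand):
                keep = mask[tuple(cand.T)] & ~visited[tuple(cand.T)]
                cand = cand[keep]
            if len(cand) == 0:
                break
            # label candidate voxels into connected clusters (cropped bbox)
            lo = cand.min(axis=0)
            hi = cand.max(axis=0)
            box = np.zeros(hi - lo + 1, dtype=bool)
            box[tuple((cand - lo).T)] = True
            labels, n_clusters = ndimage.label(box, structure=_STRUCT26)
            new_active: list[tuple[int, np.ndarray]] = []
            for c in range(1, n_clusters + 1):
                vox = np.argwhere(labels == c) + lo
                # find which active fronts this cluster touches
                nb = neighbours(vox)
                nb_owner = owner[tuple(nb.T)]
                nb_owner = nb_owner[nb_owner >= 0]
                active_ids = {aid for aid, _ in active}
                contacts, counts = np.unique(nb_owner, return_counts=True)
                front_contacts = [
                    (int(cnt), int(cid))
                    for cid, cnt in zip(contacts, counts)
                    if cid in active_ids
                ]
                nid = new_node(vox)
                if front_contacts:
                    front_contacts.sort(reverse=True)
                    parent = front_contacts[0][1]
                    edges.append((parent, nid))
                    for _, other in front_contacts[1:]:
                        fusion.append((nid, other))
                else:  # touched only older shells (rare concavities)
                    older = [int(c) for c in contacts]
                    if older:
                        edges.append((older[0], nid))
                new_active.append((nid, vox))
            active = new_active
        remaining = mask & ~visited

    skel, id_map = skeleton_from_adjacency(nodes, edges, return_id_map=True)
    for a, b in fusion:
        na, nb = id_map[a], id_map[b]
        if na != nb and frozenset((na, nb)) not in skel.fusion_links:
            skel.add_fusion_link(na, nb)
    return skel


# ---------------------------------------------------------------------------
# Thinning-based tracing
# ---------------------------------------------------------------------------


def thinning_trace(seg: Segmentation | np.ndarray) -> Skeleton:
    """Topology-preserving thinning followed by voxel-graph tracing.

    The binary mask is thinned to a one-voxel-wide skeleton; skeleton voxels
    are classified by their 26-neighbour count (1 = endpoint, >= 3 =
    junction), 26-connected junction-voxel clusters collapse to a single
    node at their centroid, and maximal degree-2 voxel runs become edges.
    Radii come from the distance transform of the *input* mask.  Cycles in
    the thinned skeleton are closed with fusion links.
    """
    seg = _as_segmentation(seg)
    mask = seg.binary
    if not mask.any():
        return Skeleton()
    sk = skeletonize(mask).astype(bool)
    if not sk.any():  # tiny objects can thin away entirely; keep their peak
        edt_in = _edt(mask, seg.voxel_size, physical=False)
        peak = np.array(np.unravel_index(int(np.argmax(edt_in)), mask.shape))
        sk = np.zeros_like(mask)
        sk[tuple(peak)] = True
    edt = _edt(mask, seg.voxel_size, physical=False)

    vox = np.argwhere(sk)  # (n, 3) z, y, x
    index = {tuple(v): i for i, v in enumerate(vox)}
    n = len(vox)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, v in enumerate(vox):
        for off in _OFFSETS26:
            key = tuple(v + off)
            j = index.get(key)
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)

    deg = np.array([len(a) for a in adj])
    junction = deg >= 3
    # cluster junction voxels (26-connected among themselves)
    cluster_of = np.full(n, -1, dtype=int)
    n_clusters = 0
    for i in np.flatnonzero(junction):
        if cluster_of[i] >= 0:
            continue
        stack = [i]
        cluster_of[i] = n_clusters
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if junction[nb] and cluster_of[nb] < 0:
                    cluster_of[nb] = n_clusters
                    stack.append(nb)
        n_clusters += 1

    # reduced-graph node per junction cluster; per endpoint / isolated voxel
    nodes: dict[int, tuple[np.ndarray, float]] = {}
    red_of_voxel: dict[int, int] = {}
    next_red = 0
    for c in range(n_clusters):
        members = np.flatnonzero(cluster_of == c)
        centroid = vox[members].mean(axis=0)
        nearest = members[
            int(np.argmin(np.linalg.norm(vox[members] - centroid, axis=1)))
        ]
        nodes[next_red] = (centroid[::-1].copy(), float(edt[tuple(vox[nearest])]))
        for m in members:
            red_of_voxel[m] = next_red
        next_red += 1
    for i in range(n):
        if deg[i] != 2 and not junction[i]:  # endpoints (deg 1) and isolated (0)
            nodes[next_red] = (vox[i][::-1].astype(float), float(edt[tuple(vox[i])]))
            red_of_voxel[i] = next_red
            next_red += 1

    edges: list[tuple[int, int]] = []
    used: set[tuple[int, int]] = set()

    def add_chain(path_vox: list[int], a: int, b: int) -> None:
        nonlocal next_red
        prev = a
        for pv in path_vox:
            nodes[next_red] = (vox[pv][::-1].astype(float), float(edt[tuple(vox[pv])]))
            edges.append((prev, next_red))
            prev = next_red
            next_red += 1
        edges.append((prev, b))

    terminal = {i for i in range(n) if i in red_of_voxel}
    for start in sorted(terminal):
        for first in sorted(adj[start]):
            if (start, first) in used:
                continue
            used.add((start, first))
            used.add((first, start))
            if first in terminal:
                a, b = red_of_voxel[start], red_of_voxel[first]
                if a != b or deg[start] == 0:
                    edges.append((a, b))
                continue
            path = [first]
            prev, cur = start, first
            while cur not in terminal:
                nxts = [x for x in adj[cur] if x != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                used.add((cur, nxt))
                used.add((nxt, cur))
                if nxt in terminal:
                    cur = nxt
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            if cur in terminal:
                add_chain(path, red_of_voxel[start], red_of_voxel[cur])
            else:  # open run ending blind (shouldn't happen): make endpoint
                leaf_vox = path[-1]
                nodes[next_red] = (
                    vox[leaf_vox][::-1].astype(float),
                    float(edt[tuple(vox[leaf_vox])]),
                )
                leaf = next_red
                next_red += 1
                add_chain(path[:-1], red_of_voxel[start], leaf)

    # leftover pure cycles: every voxel degree 2, none terminal
    visited_cycle: set[int] = set()
    for i in range(n):
        if i in red_of_voxel or deg[i] != 2 or i in visited_cycle:
            continue
        if any((i, nb) in used for nb in adj[i]):
            continue
        anchor = next_red
        nodes[anchor] = (vox[i][::-1].astype(float), float(edt[tuple(vox[i])]))
        red_of_voxel[i] = anchor
        next_red += 1
        visited_cycle.add(i)
        path = []
        prev, cur = i, adj[i][0]
        used.add((i, cur))
        used.add((cur, i))
        while cur != i:
            visited_cycle.add(cur)
            path.append(cur)
            nxt = next(x for x in adj[cur] if x != prev)
            used.add((cur, nxt))
            used.add((nxt, cur))
            prev, cur = cur, nxt
        add_chain(path, anchor, anchor)

    return skeleton_from_adjacency(nodes, edges)


# ---------------------------------------------------------------------------
# Spur pruning
# ---------------------------------------------------------------------------


def prune_spurs(
    skel: Skeleton,
    min_len: int = 5,
    radius_factor: float = 1.5,
    voxel_size: VoxelSize | None = None,
) -> Skeleton:
    """Remove short terminal twigs, iterated to a fixed point.

    A terminal edge (one endpoint of graph degree 1, the other a branch
    point of degree >= 3) is dropped when its node count is below
    ``min_len`` *or* its physical length is below ``radius_factor`` times
    the vessel radius at the attaching branch point — twigs shorter than the
    vessel is wide are artefacts of node placement on thick-vessel surfaces.
    Unbranched chains (both ends degree 1) are never touched.  Surviving
    degree-2 junctions merge into single edges on rebuild.
    """
    vs = voxel_size or VoxelSize()
    current = skel
    for _ in range(100):
        graph = build_graph(current)
        g = graph.graph
        removed = False
        kept_paths: list[list[int]] = []
        for u, v, key, data in g.edges(keys=True, data=True):
            path = data["path"]
            du, dv = g.degree(u), g.degree(v)
            is_terminal = (du == 1 and dv >= 3) or (dv == 1 and du >= 3)
            if is_terminal:
                branch = u if du >= 3 else v
                pts = np.stack([current.node(i).pos for i in path])
                phys_len = float(
                    np.sum(np.linalg.norm(np.diff(pts * vs.xyz, axis=0), axis=1))
                )
                branch_radius = current.node(branch).radius
                if len(path) < min_len or phys_len < radius_factor * branch_radius:
                    removed = True
                    continue
            kept_paths.append(path)
        if not removed:
            return current
        # rebuild a skeleton from the surviving polylines
        nodes: dict[int, tuple[np.ndarray, float]] = {}
        edges: list[tuple[int, int]] = []
        for path in kept_paths:
            for nid in path:
                node = current.node(nid)
                nodes[nid] = (node.pos.copy(), node.radius)
            edges.extend(zip(path[:-1], path[1:]))
        if not nodes:  # everything pruned away: keep the largest old path
            return Skeleton()
        current = skeleton_from_adjacency(nodes, edges)
    return current
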