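"""Core domain types and I/O for vascular skeletons and 3D volumes.

Skeletons follow SWC semantics (id, type, x, y, z, radius, parent) with one
extension: *fusion links*, unordered node-id pairs that close cycles
(anastomoses) which a pure SWC parent forest cannot represent.  Fusion links
are serialized as ``#FUSION i j`` comment lines so that any standard SWC
reader still parses the file as a forest.

Coordinate conventions
----------------------
* Skeleton node positions are continuous, 0-based voxel-index coordinates in
  ``(x, y, z)`` order (sub-voxel positions allowed).
* Volume arrays are indexed ``(z, y, x)``.
* Radii are physical micrometres; the voxel size (canonically 1 x 1 x 2 um
  for the imaging modality targeted here) converts between index and
  physical space.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
import tifffile

__all__ = [
    "VoxelSize",
    "Volume",
    "SkeletonNode",
    "Skeleton",
    "VascularGraph",
    "SwcError",
    "read_swc",
    "write_swc",
    "read_volume",
    "write_volume",
    "build_graph",
    "skeleton_from_adjacency",
]

DEFAULT_VOXEL_SIZE_UM = (1.0, 1.0, 2.0)


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel edge lengths in micrometres, (sx, sy, sz)."""

    sx: float = 1.0
    sy: float = 1.0
    sz: float = 2.0

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0 and self.sz > 0):
            raise ValueError(f"voxel size must be strictly positive, got {self}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.sx, self.sy, self.sz], dtype=float)

    @property
    def zyx(self) -> np.ndarray:
        return np.array([self.sz, self.sy, self.sx], dtype=float)


@dataclass
class Volume:
    """A 3D scalar grid indexed (z, y, x) with physical voxel size."""

    data: np.ndarray
    voxel_size: VoxelSize = field(default_factory=VoxelSize)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be rank 3, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SkeletonNode:
    id: int
    node_type: int
    pos: np.ndarray  # (x, y, z) continuous voxel-index coordinates
    radius: float  # physical um
    parent: int  # parent id or -1

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError("node position must be a 3-vector (x, y, z)")
        if self.radius < 0:
            raise ValueError(f"node {self.id}: radius must be >= 0")


class Skeleton:
    """A forest of skeleton nodes plus optional cycle-closing fusion links."""

    def __init__(
        self,
        nodes: Iterable[SkeletonNode] = (),
        fusion_links: Iterable[tuple[int, int]] = (),
    ) -> None:
        self.nodes: list[SkeletonNode] = list(nodes)
        self._index = {n.id: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node ids in skeleton")
        self.fusion_links: set[frozenset[int]] = set()
        for a, b in fusion_links:
            self.add_fusion_link(a, b)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def node(self, node_id: int) -> SkeletonNode:
        return self.nodes[self._index[node_id]]

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._index

    # -- mutation -----------------------------------------------------------
    def add_node(self, node: SkeletonNode) -> SkeletonNode:
        if node.id in self._index:
            raise ValueError(f"duplicate node id {node.id}")
        self._index[node.id] = len(self.nodes)
        self.nodes.append(node)
        return node

    def add_fusion_link(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("fusion link may not be a self-link")
        if a not in self._index or b not in self._index:
            raise ValueError(f"fusion link ({a}, {b}) references unknown node id")
        self.fusion_links.add(frozenset((a, b)))

    # -- derived views ------------------------------------------------------
    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = defaultdict(list)
        for n in self.nodes:
            if n.parent != -1:
                out[n.parent].append(n.id)
        return out

    def roots(self) -> list[int]:
        return [n.id for n in self.nodes if n.parent == -1]

    def positions(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) positions in node order."""
        if not self.nodes:
            return np.empty((0, 3))
        return np.stack([n.pos for n in self.nodes])

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes], dtype=float)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for n in self.nodes:
            if n.parent != -1 and n.parent not in self._index:
                raise ValueError(f"node {n.id}: parent {n.parent} does not exist")
            if n.parent == n.id:
                raise ValueError(f"node {n.id} is its own parent")
        self._topological_order()  # raises on parent-link cycles

    def _topological_order(self) -> list[int]:
        """Node ids with every parent before its children; raises on cycles."""
        order: list[int] = []
        state: dict[int, int] = {}  # 0 in-progress, 1 done
        for n in self.nodes:
            chain = []
            cur = n.id
            while cur != -1 and cur not in state:
                chain.append(cur)
                state[cur] = 0
                cur = self.node(cur).parent
            if cur != -1 and state.get(cur) == 0:
                raise ValueError(f"cycle in parent links involving node {cur}")
            for node_id in reversed(chain):
                state[node_id] = 1
                order.append(node_id)
        return order


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


class SwcError(ValueError):
    """Malformed or structurally invalid SWC content."""


def read_swc(path: str | Path) -> Skeleton:
    """Parse a 7-column SWC file into a :class:`Skeleton`.

    ``#`` lines are comments, except ``#FUSION i j`` lines which encode
    cycle-closing fusion links.  Coordinates and radii are taken as stored
    (by default: voxel-index coordinates and micrometre radii).
    """
    path = Path(path)
    nodes: list[SkeletonNode] = []
    fusion: list[tuple[int, int]] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line[1:].split()
                if tok and tok[0].upper() == "FUSION":
                    try:
                        fusion.append((int(tok[1]), int(tok[2])))
                    except (IndexError, ValueError) as exc:
                        raise SwcError(
                            f"{path}:{lineno}: malformed FUSION comment: {line!r}"
                        ) from exc
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SwcError(
                    f"{path}:{lineno}: expected 7 columns, got {len(cols)}: {line!r}"
                )
            try:
                nid = int(cols[0])
                ntype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise SwcError(f"{path}:{lineno}: could not parse: {line!r}") from exc
            if nid in seen:
                raise SwcError(f"{path}:{lineno}: duplicate node id {nid}")
            seen.add(nid)
            nodes.append(SkeletonNode(nid, ntype, np.array([x, y, z]), r, parent))
    for n in nodes:
        if n.parent != -1 and n.parent not in seen:
            raise SwcError(f"{path}: node {n.id} references missing parent {n.parent}")
    try:
        return Skeleton(nodes, fusion)
    except ValueError as exc:
        raise SwcError(f"{path}: {exc}") from exc


def write_swc(skel: Skeleton, path: str | Path) -> Path:
    """Write a skeleton as 7-column SWC, parents strictly before children.

    Floats are printed with ``repr`` (shortest exact decimal), so a
    write/read round trip reproduces coordinates and radii bit-faithfully.
    Fusion links go out as ``#FUSION i j`` comment lines.
    """
    path = Path(path)
    order = skel._topological_order()
    with open(path, "w") as fh:
        fh.write("# SWC vascular skeleton (vesselbench)\n")
        fh.write("# columns: id type x y z radius parent\n")
        for pair in sorted(tuple(sorted(fl)) for fl in skel.fusion_links):
            fh.write(f"#FUSION {pair[0]} {pair[1]}\n")
        for nid in order:
            n = skel.node(nid)
            x, y, z = (float(c) for c in n.pos)
            fh.write(
                f"{n.id} {n.node_type} {x!r} {y!r} {z!r} "
                f"{float(n.radius)!r} {n.parent}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Volume I/O: multi-page TIFF (+ JSON sidecar) and raw-encoded NRRD
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "uint16": np.uint16,
    "float": np.float32,
    "double": np.float64,
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path, voxel_size: VoxelSize | None = None) -> Volume:
    """Read a 3D volume from multi-page TIFF or NRRD.

    Voxel size comes from (in order of precedence): the explicit argument,
    the NRRD ``space directions`` header, a ``<name>.json`` sidecar, or the
    1 x 1 x 2 um default (with a warning).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        vs = voxel_size
        if vs is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                vs = VoxelSize(*meta["voxel_size_um"])
    elif suffix == ".nrrd":
        data, header_vs = _read_nrrd(path)
        vs = voxel_size if voxel_size is not None else header_vs
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a rank-3 volume, got shape {data.shape}")
    if vs is None:
        warnings.warn(
            f"{path}: no voxel size metadata found; assuming "
            f"{DEFAULT_VOXEL_SIZE_UM} um",
            stacklevel=2,
        )
        vs = VoxelSize(*DEFAULT_VOXEL_SIZE_UM)
    return Volume(data, vs)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as TIFF (with JSON voxel-size sidecar) or NRRD.

    8-bit data round-trips losslessly; floating volumes are stored as
    32-bit floats.
    """
    path = Path(path)
    data = vol.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "voxel_size_um": [
                        vol.voxel_size.sx,
                        vol.voxel_size.sy,
                        vol.voxel_size.sz,
                    ],
                    "axis_order": "zyx",
                }
            )
        )
    elif suffix == ".nrrd":
        _write_nrrd(path, data, vol.voxel_size)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    return path


def _write_nrrd(path: Path, data: np.ndarray, vs: VoxelSize) -> None:
    # Minimal raw-encoded NRRD writer; axis order in the file is x-fastest,
    # which matches C-contiguous (z, y, x) arrays directly.
    type_name = {np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
                 np.dtype(np.float32): "float", np.dtype(np.float64): "double"}.get(
        data.dtype
    )
    if type_name is None:
        raise ValueError(f"unsupported NRRD dtype: {data.dtype}")
    nz, ny, nx = data.shape
    header = (
        "NRRD0004\n"
        f"type: {type_name}\n"
        "dimension: 3\n"
        "space dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"space directions: ({vs.sx},0,0) (0,{vs.sy},0) (0,0,{vs.sz})\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())


def _read_nrrd(path: Path) -> tuple[np.ndarray, VoxelSize | None]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, value = text.split(":", 1)
            fields[key.strip().lower()] = value.strip()
        payload = fh.read()
    if fields.get("encoding", "raw") != "raw":
        raise ValueError(f"{path}: only raw NRRD encoding is supported")
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = [int(s) for s in fields["sizes"].split()]
    if len(sizes) != 3:
        raise ValueError(f"{path}: expected a rank-3 volume, sizes={sizes}")
    nx, ny, nz = sizes
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    if arr.size != nx * ny * nz:
        raise ValueError(f"{path}: payload size does not match header sizes")
    data = arr.reshape(nz, ny, nx).astype(dtype)
    vs: VoxelSize | None = None
    if "space directions" in fields:
        vecs = []
        for chunk in fields["space directions"].replace(") (", ")|(").split("|"):
            nums = chunk.strip().strip("()").split(",")
            vecs.append([float(v) for v in nums])
        diag = [vecs[0][0], vecs[1][1], vecs[2][2]]
        if all(d > 0 for d in diag):
            vs = VoxelSize(*diag)
    return data, vs


# ---------------------------------------------------------------------------
# Graph abstraction
# ---------------------------------------------------------------------------


@dataclass
class VascularGraph:
    """Topological abstraction of a skeleton.

    Graph nodes are skeleton branch points (structural degree >= 3),
    endpoints (degree 1) and isolated nodes; each graph edge is a maximal
    degree-2 skeleton path between two graph nodes, stored as the ordered
    list of skeleton node ids (``path`` edge attribute, endpoints included).
    Fusion links participate in the adjacency exactly like parent links, so
    anastomoses become ordinary graph cycles.
    """

    graph: nx.MultiGraph
    skeleton: Skeleton

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node_id: int) -> int:
        return self.graph.degree(node_id)

    def node_position(self, node_id: int) -> np.ndarray:
        return self.skeleton.node(node_id).pos

    def edge_polyline(self, u: int, v: int, key: int = 0) -> np.ndarray:
        """(n, 3) positions (x, y, z) along one edge's skeleton path."""
        path = self.graph.edges[u, v, key]["path"]
        return np.stack([self.skeleton.node(i).pos for i in path])

    def edge_radii(self, u: int, v: int, key: int = 0) -> np.ndarray:
        path = self.graph.edges[u, v, key]["path"]
        return np.array([self.skeleton.node(i).radius for i in path])

    def to_json(self) -> dict:
        return {
            "nodes": [
                {
                    "id": int(n),
                    "pos": [float(c) for c in self.node_position(n)],
                    "degree": int(self.degree(n)),
                }
                for n in sorted(self.graph.nodes)
            ],
            "edges": [
                {"u": int(u), "v": int(v), "path": [int(i) for i in d["path"]]}
                for u, v, d in sorted(
                    self.graph.edges(data=True), key=lambda e: (e[0], e[1])
                )
            ],
        }


def _structural_adjacency(skel: Skeleton) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {n.id: set() for n in skel.nodes}
    for n in skel.nodes:
        if n.parent != -1:
            adj[n.id].add(n.parent)
            adj[n.parent].add(n.id)
    for link in skel.fusion_links:
        a, b = tuple(link)
        adj[a].add(b)
        adj[b].add(a)
    return adj


def build_graph(skel: Skeleton) -> VascularGraph:
    """Abstract a skeleton into its branch-point/endpoint graph.

    The structural degree of a skeleton node counts its parent link, child
    links and fusion links.  Nodes of degree != 2 become graph nodes; maximal
    runs of degree-2 nodes become edges.  Components that are pure cycles
    (every node degree 2) are anchored at their smallest node id and emitted
    as a single self-loop edge, so the degree-sum identity still holds.
    """
    adj = _structural_adjacency(skel)
    g = nx.MultiGraph()
    junctions = {i for i, nb in adj.items() if len(nb) != 2}
    for j in junctions:
        g.add_node(j)

    used: set[tuple[int, int]] = set()  # directed half-edges already walked

    def walk(start: int, first: int) -> list[int]:
        path = [start, first]
        used.add((start, first))
        used.add((first, start))
        prev, cur = start, first
        while cur not in junctions and cur != start:
            nxt = next(iter(adj[cur] - {prev}), None)
            if nxt is None:  # defensive; degree-2 interior always has one
                break
            used.add((cur, nxt))
            used.add((nxt, cur))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    for j in sorted(junctions):
        for nb in sorted(adj[j]):
            if (j, nb) in used:
                continue
            path = walk(j, nb)
            g.add_edge(path[0], path[-1], path=path)

    # leftover pure cycles: no junction anywhere on the component
    leftover = {
        i
        for i, nb in adj.items()
        if len(nb) == 2 and all((i, n) not in used for n in nb)
    }
    while leftover:
        anchor = min(leftover)
        g.add_node(anchor)
        first = sorted(adj[anchor])[0]
        path = walk(anchor, first)
        g.add_edge(anchor, anchor, path=path)
        leftover -= set(path)

    return VascularGraph(graph=g, skeleton=skel)


def skeleton_from_adjacency(
    nodes: dict[int, tuple[Sequence[float], float]],
    edges: Iterable[tuple[int, int]],
    node_type: int = 2,
    return_id_map: bool = False,
) -> Skeleton | tuple[Skeleton, dict[int, int]]:
    """Build a :class:`Skeleton` from an undirected node/edge description.

    A BFS spanning forest supplies the parent links; every non-tree edge
    becomes a fusion link.  Node ids are renumbered densely from 1 in BFS
    order (smallest original id first), which also guarantees parents precede
    children.  With ``return_id_map`` the original-to-new id mapping is
    returned alongside the skeleton.
    """
    adj: dict[int, set[int]] = {i: set() for i in nodes}
    for a, b in edges:
        if a == b:
            continue
        adj[a].add(b)
        adj[b].add(a)

    skel = Skeleton()
    new_id: dict[int, int] = {}
    counter = 1
    visited: set[int] = set()
    tree_edges: set[frozenset[int]] = set()
    for root in sorted(nodes):
        if root in visited:
            continue
        visited.add(root)
        queue = deque([root])
        new_id[root] = counter
        pos, radius = nodes[root]
        skel.add_node(SkeletonNode(counter, node_type, np.asarray(pos, float), radius, -1))
        counter += 1
        while queue:
            cur = queue.popleft()
            for nb in sorted(adj[cur]):
                if nb in visited:
                    continue
                visited.add(nb)
                tree_edges.add(frozenset((cur, nb)))
                new_id[nb] = counter
                pos, radius = nodes[nb]
                skel.add_node(
                    SkeletonNode(
                        counter, node_type, np.asarray(pos, float), radius, new_id[cur]
                    )
                )
                counter += 1
                queue.append(nb)
    for a, b in edges:
        if a == b or frozenset((a, b)) in tree_edges:
            continue
        if frozenset((new_id[a], new_id[b])) not in skel.fusion_links:
            skel.add_fusion_link(new_id[a], new_id[b])
    if return_id_map:
        return skel, new_id
    return skel
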