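"""Synthetic vascular phantoms with exact ground-truth skeletons.

The generator emulates the salient features of fMOST-style mouse-brain
vasculature at the canonical 1 x 1 x 2 um voxel size: vessel radii from
~2 um (capillaries) to ~20 um (trunk vessels), hollow lumens in large
vessels (the dye lines only the wall), dense low-contrast capillary meshes
with anastomoses, and weak signals with foreground means down to ~10 on the
8-bit scale.  Every phantom carries its exact centerline skeleton, so
tracing and evaluation code can be tested against known truth.

Also here: the block-tiling and representative-block selection utilities
used to curate training blocks from large volumes (gray-level histogram
features, K-means clustering, proportional sampling across clusters).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core_model import (
    Skeleton,
    SkeletonNode,
    VoxelSize,
    Volume,
    write_swc,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "generate_skeleton",
    "render_volume",
    "FixtureCase",
    "make_fixture_suite",
    "Block",
    "tile_blocks",
    "select_training_blocks",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic vascular volume.

    shape is (nz, ny, nx) voxels; radii and the hollow threshold are
    physical micrometres; intensities are on the 8-bit scale.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: VoxelSize = field(default_factory=VoxelSize)
    n_trees: int = 3
    radius_range: tuple[float, float] = (2.0, 20.0)
    branch_prob: float = 0.02
    tortuosity: float = 0.15
    hollow_radius_threshold: float = 6.0
    lumen_fraction: float = 0.5
    foreground_intensity: float = 120.0
    background_level: float = 15.0
    noise_sd: float = 5.0
    seed: int = 0
    steps_per_tree: int = 300

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        r_min, r_max = self.radius_range
        if not (0 < r_min <= r_max):
            raise ValueError(f"need 0 < r_min <= r_max, got {self.radius_range}")
        if not (0 <= self.lumen_fraction < 1):
            raise ValueError("lumen_fraction must be in [0, 1)")
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must be a probability")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction")
    return v / n


def _margins_vox(radius_um: float, vs: VoxelSize) -> np.ndarray:
    # safety margin per (x, y, z) axis, in voxel-index units
    return radius_um / vs.xyz + 1.0


def generate_skeleton(spec: PhantomSpec) -> Skeleton:
    """Grow random branching vessel trees by stepwise tip extension.

    Tips advance one voxel-index unit per step with the direction perturbed
    by ``tortuosity``; each step the new tip node bifurcates with probability
    ``branch_prob`` (child radius 0.6-0.95 of the parent, floored at r_min).
    ``steps_per_tree`` is a *total* step budget shared by all branches of a
    tree, so the number of bifurcation events in an unobstructed tree is
    Binomial(steps, branch_prob).  Tips die when the next node would leave
    the radius-aware volume bounds.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    extent = np.array([nx, ny, nz], dtype=float)  # (x, y, z)
    r_min, r_max = spec.radius_range

    def in_bounds(pos: np.ndarray, radius: float) -> bool:
        m = _margins_vox(radius, spec.voxel_size)
        return bool(np.all(pos >= m) and np.all(pos <= extent - 1 - m))

    skel = Skeleton()
    next_id = 1
    placed_any = False
    for _ in range(spec.n_trees):
        radius = float(rng.uniform(r_min, r_max))
        m = _margins_vox(radius, spec.voxel_size)
        low, high = m, extent - 1 - m
        if np.any(low >= high):
            # tree too fat for this volume; retry with the thinnest allowed
            radius = r_min
            m = _margins_vox(radius, spec.voxel_size)
            low, high = m, extent - 1 - m
            if np.any(low >= high):
                continue
        pos = rng.uniform(low, high)
        direction = _unit(rng.normal(size=3))
        root = SkeletonNode(next_id, 2, pos, radius, -1)
        skel.add_node(root)
        next_id += 1
        placed_any = True

        # each tip: (position, direction, radius, parent node id)
        tips: deque[tuple[np.ndarray, np.ndarray, float, int]] = deque(
            [(pos, direction, radius, root.id)]
        )
        budget = spec.steps_per_tree
        while tips and budget > 0:
            budget -= 1
            tip_pos, tip_dir, tip_r, parent = tips.popleft()
            new_dir = _unit(tip_dir + spec.tortuosity * rng.normal(size=3))
            new_pos = tip_pos + new_dir
            if not in_bounds(new_pos, tip_r):
                continue  # tip dies at the boundary
            node = SkeletonNode(next_id, 2, new_pos, tip_r, parent)
            skel.add_node(node)
            next_id += 1
            tips.append((new_pos, new_dir, tip_r, node.id))
            if rng.uniform() < spec.branch_prob:
                # bifurcate at the *previous* node: both children exist as
                # soon as the event fires, so event count stays binomial
                child_r = max(r_min, tip_r * rng.uniform(0.6, 0.95))
                child_dir = _unit(new_dir + 0.8 * rng.normal(size=3))
                child_pos = tip_pos + child_dir
                if in_bounds(child_pos, child_r):
                    child = SkeletonNode(next_id, 2, child_pos, child_r, parent)
                    skel.add_node(child)
                    next_id += 1
                    tips.append((child_pos, child_dir, child_r, child.id))
    if not placed_any:
        raise ValueError(
            f"volume shape {spec.shape} too small to place any tree of radius "
            f">= {r_min} um"
        )
    return skel


def _dense_samples(skel: Skeleton, step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Sample every parent-child segment at <= `step` voxel spacing.

    Returns (points (n, 3) xyz, radii (n,)) with linear radius interpolation.
    """
    pts: list[np.ndarray] = []
    rad: list[np.ndarray] = []
    for n in skel.nodes:
        if n.parent == -1:
            pts.append(n.pos[None, :])
            rad.append(np.array([n.radius]))
            continue
        p = skel.node(n.parent)
        seg = n.pos - p.pos
        length = float(np.linalg.norm(seg))
        k = max(1, int(np.ceil(length / step)))
        t = np.linspace(0.0, 1.0, k + 1)[1:]  # parent endpoint covered elsewhere
        pts.append(p.pos[None, :] + t[:, None] * seg[None, :])
        rad.append(p.radius + t * (n.radius - p.radius))
    if not pts:
        return np.empty((0, 3)), np.empty(0)
    return np.concatenate(pts), np.concatenate(rad)


def render_volume(skel: Skeleton, spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Render a skeleton into an 8-bit image and a solid binary mask.

    A voxel is mask foreground iff its anisotropy-aware physical distance to
    the centerline is <= the local radius.  Vessels wider than
    ``hollow_radius_threshold`` are rendered hollow in the *image*: voxels
    closer than ``lumen_fraction * radius`` to the centerline stay at
    background level (the mask remains solid).  The image is
    background + foreground_intensity * indicator + N(0, noise_sd), rounded
    and clipped to [0, 255].
    """
    nz, ny, nx = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    lumen = np.zeros(spec.shape, dtype=bool)
    svec = spec.voxel_size.xyz  # (sx, sy, sz)

    points, radii = _dense_samples(skel)
    dims_xyz = np.array([nx, ny, nz])
    for p, r in zip(points, radii):
        if r <= 0:
            idx = np.clip(np.round(p).astype(int), 0, dims_xyz - 1)
            mask[idx[2], idx[1], idx[0]] = True
            continue
        half = np.ceil(r / svec).astype(int) + 1  # (x, y, z) half extents
        lo = np.maximum(np.round(p).astype(int) - half, 0)
        hi = np.minimum(np.round(p).astype(int) + half, dims_xyz - 1)
        if np.any(lo > hi):
            continue
        xs = np.arange(lo[0], hi[0] + 1)
        ys = np.arange(lo[1], hi[1] + 1)
        zs = np.arange(lo[2], hi[2] + 1)
        dx = (xs - p[0]) * svec[0]
        dy = (ys - p[1]) * svec[1]
        dz = (zs - p[2]) * svec[2]
        d2 = (
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        )
        sub = (slice(lo[2], hi[2] + 1), slice(lo[1], hi[1] + 1), slice(lo[0], hi[0] + 1))
        mask[sub] |= d2 <= r * r
        if r > spec.hollow_radius_threshold and spec.lumen_fraction > 0:
            rl = spec.lumen_fraction * r
            lumen[sub] |= d2 < rl * rl

    indicator = mask & ~lumen
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 9001]))
    img = np.full(spec.shape, spec.background_level, dtype=float)
    img[indicator] += spec.foreground_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Volume(img, spec.voxel_size), Volume(mask, spec.voxel_size)


# ---------------------------------------------------------------------------
# Deterministic named fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureCase:
    name: str
    spec: PhantomSpec
    skeleton: Skeleton
    image: Volume
    mask: Volume
    meta: dict


class _SkeletonBuilder:
    """Incrementally build a skeleton from explicit polylines."""

    def __init__(self) -> None:
        self.skel = Skeleton()
        self._next = 1

    def path(
        self,
        points: Sequence[Sequence[float]],
        radius: float | Sequence[float],
        attach_to: int | None = None,
    ) -> list[int]:
        """Append a polyline; first point parents to ``attach_to`` (or root)."""
        radii = np.broadcast_to(np.atleast_1d(radius), (len(points),))
        ids = []
        parent = -1 if attach_to is None else attach_to
        for pt, r in zip(points, radii):
            node = SkeletonNode(self._next, 2, np.asarray(pt, float), float(r), parent)
            self.skel.add_node(node)
            ids.append(node.id)
            parent = node.id
            self._next += 1
        return ids

    def fuse(self, a: int, b: int) -> None:
        self.skel.add_fusion_link(a, b)


def _line(p0, p1, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    return np.asarray(p0, float)[None, :] + t[:, None] * (
        np.asarray(p1, float) - np.asarray(p0, float)
    )[None, :]


def _fixture_straight_tube() -> FixtureCase:
    spec = PhantomSpec(
        shape=(64, 64, 64),
        radius_range=(3.0, 3.0),
        hollow_radius_threshold=1e9,
        foreground_intensity=150.0,
        background_level=20.0,
        noise_sd=0.0,
        seed=11,
    )
    b = _SkeletonBuilder()
    b.path(_line([6, 32, 32], [57, 32, 32], 52), radius=3.0)
    img, mask = render_volume(b.skel, spec)
    return FixtureCase(
        "straight_tube", spec, b.skel, img, mask,
        {"radius_um": 3.0, "axis": "x", "center_yz": [32, 32]},
    )


def _fixture_y_junction() -> FixtureCase:
    spec = PhantomSpec(
        shape=(64, 64, 64),
        radius_range=(3.0, 3.0),
        hollow_radius_threshold=1e9,
        foreground_intensity=150.0,
        background_level=20.0,
        noise_sd=0.0,
        seed=12,
    )
    b = _SkeletonBuilder()
    stem = b.path(_line([6, 32, 32], [28, 32, 32], 23), radius=3.0)
    c = 1.0 / np.sqrt(2.0)
    n = 26
    length = 25.0
    up = _line(
        [28 + c * length / (n - 1), 32 + c * length / (n - 1), 32],
        [28 + c * length, 32 + c * length, 32],
        n - 1,
    )
    dn = _line(
        [28 + c * length / (n - 1), 32 - c * length / (n - 1), 32],
        [28 + c * length, 32 - c * length, 32],
        n - 1,
    )
    b.path(up, radius=3.0, attach_to=stem[-1])
    b.path(dn, radius=3.0, attach_to=stem[-1])
    img, mask = render_volume(b.skel, spec)
    return FixtureCase(
        "y_junction", spec, b.skel, img, mask,
        {
            "branch_point": [28.0, 32.0, 32.0],
            "limb_angle_deg": 90.0,
            "n_endpoints": 3,
        },
    )


def _fixture_hollow_trunk() -> FixtureCase:
    spec = PhantomSpec(
        shape=(40, 48, 96),
        radius_range=(10.0, 10.0),
        hollow_radius_threshold=6.0,
        lumen_fraction=0.5,
        foreground_intensity=150.0,
        background_level=20.0,
        noise_sd=0.0,
        seed=13,
    )
    b = _SkeletonBuilder()
    b.path(_line([8, 24, 20], [87, 24, 20], 80), radius=10.0)
    img, mask = render_volume(b.skel, spec)
    return FixtureCase(
        "hollow_trunk", spec, b.skel, img, mask,
        {"radius_um": 10.0, "lumen_radius_um": 5.0, "center_yz": [24, 20]},
    )


def _fixture_capillary_mesh() -> FixtureCase:
    spec = PhantomSpec(
        shape=(32, 64, 64),
        radius_range=(2.0, 2.0),
        hollow_radius_threshold=1e9,
        foreground_intensity=45.0,
        background_level=15.0,
        noise_sd=3.0,
        seed=14,
    )
    b = _SkeletonBuilder()
    # a closed capillary loop (anastomosis) plus a free-hanging capillary
    a_ids = b.path(_line([10, 22, 16], [54, 22, 16], 45), radius=2.0)
    rung1_top = a_ids[4]  # node at x = 14 on tube A
    rung1 = b.path(_line([14, 23, 16], [14, 42, 16], 20), radius=2.0,
                   attach_to=rung1_top)
    b_left = b.path(_line([13, 42, 16], [10, 42, 16], 4), radius=2.0,
                    attach_to=rung1[-1])
    b_right = b.path(_line([15, 42, 16], [54, 42, 16], 40), radius=2.0,
                     attach_to=rung1[-1])
    rung2_bottom = b_right[35]  # node at x = 50 on tube B
    rung2 = b.path(_line([50, 41, 16], [50, 23, 16], 19), radius=2.0,
                   attach_to=rung2_bottom)
    # close the cycle back onto tube A at x = 50 (a_ids[40])
    b.fuse(rung2[-1], a_ids[40])
    b.path(_line([20, 50, 24], [48, 54, 26], 29), radius=2.0)
    img, mask = render_volume(b.skel, spec)
    return FixtureCase(
        "capillary_mesh", spec, b.skel, img, mask,
        {"n_fusion_links": 1, "radius_um": 2.0},
    )


def _fixture_weak_signal() -> FixtureCase:
    spec = PhantomSpec(
        shape=(48, 48, 64),
        radius_range=(2.5, 2.5),
        hollow_radius_threshold=1e9,
        foreground_intensity=8.0,
        background_level=2.0,
        noise_sd=2.0,
        seed=15,
    )
    b = _SkeletonBuilder()
    b.path(_line([6, 24, 24], [57, 24, 24], 52), radius=2.5)
    b.path(_line([10, 10, 12], [50, 38, 34], 49), radius=2.5)
    img, mask = render_volume(b.skel, spec)
    return FixtureCase(
        "weak_signal", spec, b.skel, img, mask,
        {"foreground_mean": 10.0, "noise_sd": 2.0},
    )


_FIXTURE_FACTORIES = {
    "straight_tube": _fixture_straight_tube,
    "y_junction": _fixture_y_junction,
    "hollow_trunk": _fixture_hollow_trunk,
    "capillary_mesh": _fixture_capillary_mesh,
    "weak_signal": _fixture_weak_signal,
}


def make_fixture_suite(outdir: str | Path | None = None) -> dict[str, FixtureCase]:
    """Build the five deterministic named fixtures used throughout the tests.

    straight_tube (r = 3 um), y_junction (symmetric 90 degree fork),
    hollow_trunk (r = 10 um annulus), capillary_mesh (dense r = 2 um tubes
    with one anastomosis), weak_signal (foreground mean 10).  If ``outdir``
    is given, each fixture's image, mask, ground-truth SWC and JSON metadata
    are written there.
    """
    suite = {name: make() for name, make in _FIXTURE_FACTORIES.items()}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, case in suite.items():
            write_volume(case.image, outdir / f"{name}_image.tiff")
            write_volume(case.mask, outdir / f"{name}_mask.tiff")
            write_swc(case.skeleton, outdir / f"{name}_gt.swc")
            meta = dict(case.meta)
            meta["spec"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(case.spec).items()
            }
            (outdir / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))
    return suite


# ---------------------------------------------------------------------------
# Block tiling and representative-block selection
# ---------------------------------------------------------------------------


@dataclass
class Block:
    index: tuple[int, int, int]  # (iz, iy, ix) grid position
    offset: tuple[int, int, int]  # (z, y, x) start voxel
    data: np.ndarray


def _starts(extent: int, block: int, k: int) -> np.ndarray:
    if block > extent:
        raise ValueError(f"block size {block} exceeds volume extent {extent}")
    if k < 1:
        raise ValueError("need at least one block per axis")
    if k == 1:
        return np.array([0], dtype=int)
    return np.rint(np.linspace(0.0, extent - block, k)).astype(int)


def tile_blocks(
    vol: Volume,
    block: int | tuple[int, int, int],
    n_blocks_per_axis: int | tuple[int, int, int],
) -> list[Block]:
    """Tile a volume into overlapping blocks with evenly spaced offsets.

    ``block`` and ``n_blocks_per_axis`` are per-axis in (z, y, x) order (a
    scalar applies to all axes).  Start offsets are evenly spaced from 0 to
    extent - block and rounded to integers; blocks overlap whenever
    k * block > extent, and their union covers the volume whenever
    k * block >= extent.
    """
    shape = vol.shape
    bsz = np.broadcast_to(np.atleast_1d(block), (3,)).astype(int)
    ks = np.broadcast_to(np.atleast_1d(n_blocks_per_axis), (3,)).astype(int)
    starts = [_starts(shape[a], int(bsz[a]), int(ks[a])) for a in range(3)]
    out: list[Block] = []
    for iz, z0 in enumerate(starts[0]):
        for iy, y0 in enumerate(starts[1]):
            for ix, x0 in enumerate(starts[2]):
                data = vol.data[
                    z0 : z0 + bsz[0], y0 : y0 + bsz[1], x0 : x0 + bsz[2]
                ]
                out.append(Block((iz, iy, ix), (int(z0), int(y0), int(x0)), data))
    return out


def _gray_histogram(data: np.ndarray, bins: int = 256) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        hist, _ = np.histogram(data, bins=bins, range=(0, 256))
    else:
        hist, _ = np.histogram(data, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    return hist / total if total else hist.astype(float)


def select_training_blocks(
    blocks: Sequence[Block | np.ndarray],
    k_clusters: int,
    n_select: int,
    seed: int = 0,
) -> list[int]:
    """Pick representative block indices via histogram K-means.

    Each block is described by its normalized 256-bin gray-level histogram;
    K-means (k-means++ init, fixed seed) groups the blocks, and the selection
    is drawn across clusters proportionally to cluster size (largest
    remainder for the leftover quota).  Deterministic given ``seed``.
    """
    if len(blocks) == 0:
        raise ValueError("no blocks to select from")
    if n_select > len(blocks):
        raise ValueError("cannot select more blocks than available")
    k_clusters = min(k_clusters, len(blocks))
    arrays = [b.data if isinstance(b, Block) else np.asarray(b) for b in blocks]
    feats = np.stack([_gray_histogram(a) for a in arrays])
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)

    rng = np.random.default_rng(seed)
    members = {c: np.flatnonzero(labels == c) for c in range(k_clusters)}
    sizes = np.array([len(members[c]) for c in range(k_clusters)], dtype=float)
    raw = n_select * sizes / sizes.sum()
    quota = np.floor(raw).astype(int)
    remainder = raw - quota
    # largest-remainder allocation of the leftover picks
    for c in np.argsort(-remainder, kind="stable"):
        if quota.sum() >= n_select:
            break
        if quota[c] < sizes[c]:
            quota[c] += 1
    # cap at cluster size and push any residue to clusters with spare room
    quota = np.minimum(quota, sizes.astype(int))
    while quota.sum() < n_select:
        spare = np.flatnonzero(quota < sizes)
        c = spare[np.argmax(sizes[spare] - quota[spare])]
        quota[c] += 1

    selected: list[int] = []
    for c in range(k_clusters):
        take = int(quota[c])
        if take == 0:
            continue
        chosen = rng.choice(members[c], size=take, replace=False)
        selected.extend(int(i) for i in chosen)
    return sorted(selected)
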