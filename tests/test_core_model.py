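"""SWC round trips, volume I/O and skeleton graph abstraction."""

import numpy as np
import pytest

from vesselbench.core_model import (
    Skeleton,
    SkeletonNode,
    SwcError,
    VoxelSize,
    Volume,
    build_graph,
    read_swc,
    read_volume,
    skeleton_from_adjacency,
    write_swc,
    write_volume,
)
from vesselbench.phantom import PhantomSpec, generate_skeleton


def chain(n, start_id=1, radius=2.0):
    nodes = [
        SkeletonNode(start_id + i, 2, np.array([float(i), 0.0, 0.0]), radius,
                     -1 if i == 0 else start_id + i - 1)
        for i in range(n)
    ]
    return Skeleton(nodes)


class TestVoxelSize:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            VoxelSize(1.0, 0.0, 2.0)

    def test_axis_orders(self):
        vs = VoxelSize(1, 1, 2)
        assert vs.xyz.tolist() == [1, 1, 2]
        assert vs.zyx.tolist() == [2, 1, 1]


class TestSwcIO:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# comment\n1 2 0 0 0 2.5 -1\n2 2 1 0 0 2.5 1\n3 2 1 1 0 2.5 1\n")
        skel = read_swc(p)
        assert len(skel) == 3
        assert skel.node(1).parent == -1
        assert skel.node(3).parent == 1
        assert skel.node(2).radius == 2.5

    def test_comment_only_file_is_empty_skeleton(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# nothing here\n# at all\n")
        assert len(read_swc(p)) == 0

    @pytest.mark.parametrize(
        "content,match",
        [
            ("1 2 0 0 0 1", "7 columns"),
            ("1 2 0 0 zero 1 -1", "parse"),
            ("1 2 0 0 0 1 -1\n1 2 1 0 0 1 -1", "duplicate"),
            ("1 2 0 0 0 1 99", "parent"),
        ],
    )
    def test_malformed_inputs_raise(self, tmp_path, content, match):
        p = tmp_path / "bad.swc"
        p.write_text(content + "\n")
        with pytest.raises(SwcError, match=match):
            read_swc(p)

    def test_three_node_chain_encoding(self, tmp_path):
        p = write_swc(chain(3), tmp_path / "c.swc")
        rows = [l.split() for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [r[6] for r in rows] == ["-1", "1", "2"]

    def test_empty_skeleton_header_only(self, tmp_path):
        p = write_swc(Skeleton(), tmp_path / "e.swc")
        assert all(l.startswith("#") for l in p.read_text().splitlines())

    def test_round_trip_random_tree_bit_faithful(self, tmp_path):
        rng = np.random.default_rng(42)
        nodes = [SkeletonNode(1, 2, rng.uniform(0, 50, 3), rng.uniform(1, 5), -1)]
        for i in range(2, 51):
            parent = int(rng.integers(1, i))
            nodes.append(
                SkeletonNode(i, 2, rng.uniform(0, 50, 3), rng.uniform(1, 5), parent)
            )
        skel = Skeleton(nodes, fusion_links=[(5, 17)])
        back = read_swc(write_swc(skel, tmp_path / "r.swc"))
        assert len(back) == 50
        for n in skel.nodes:
            m = back.node(n.id)
            assert m.pos.tolist() == n.pos.tolist()  # exact, repr round trip
            assert m.radius == n.radius
            assert m.parent == n.parent
        assert back.fusion_links == {frozenset((5, 17))}

    def test_write_refuses_parent_cycle(self, tmp_path):
        skel = chain(3)
        skel.nodes[0].parent = 3  # 1 -> 3 -> 2 -> 1
        with pytest.raises(ValueError, match="cycle"):
            write_swc(skel, tmp_path / "cyc.swc")


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".tiff", ".nrrd"])
    def test_uint8_round_trip(self, tmp_path, suffix):
        data = np.arange(4 * 4 * 4, dtype=np.uint8).reshape(4, 4, 4)
        vol = Volume(data, VoxelSize(1, 1, 2))
        back = read_volume(write_volume(vol, tmp_path / f"v{suffix}"))
        np.testing.assert_array_equal(back.data, data)
        assert back.voxel_size == vol.voxel_size

    def test_zero_volume_round_trip(self, tmp_path):
        vol = Volume(np.zeros((4, 4, 4), dtype=np.uint8))
        back = read_volume(write_volume(vol, tmp_path / "z.tiff"))
        np.testing.assert_array_equal(back.data, vol.data)

    def test_cross_format_equality(self, tmp_path, straight_tube):
        img = straight_tube.image
        a = read_volume(write_volume(img, tmp_path / "a.tiff"))
        b = read_volume(write_volume(img, tmp_path / "b.nrrd"))
        np.testing.assert_array_equal(a.data, b.data)
        assert a.voxel_size == b.voxel_size

    def test_float_written_as_float32(self, tmp_path):
        vol = Volume(np.random.default_rng(0).uniform(size=(3, 3, 3)))
        back = read_volume(write_volume(vol, tmp_path / "f.nrrd"))
        assert back.data.dtype == np.float32

    def test_missing_voxel_size_warns_and_defaults(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "raw.tiff", np.zeros((3, 3, 3), np.uint8))
        with pytest.warns(UserWarning, match="voxel size"):
            vol = read_volume(tmp_path / "raw.tiff")
        assert vol.voxel_size == VoxelSize(1, 1, 2)

    def test_rank_mismatch_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "flat.tiff", np.zeros((5, 5), np.uint8))
        with pytest.raises(ValueError, match="rank-3"):
            read_volume(tmp_path / "flat.tiff", voxel_size=VoxelSize())


class TestBuildGraph:
    def test_unbranched_chain(self):
        g = build_graph(chain(10))
        assert g.n_nodes == 2 and g.n_edges == 1
        assert sorted(d for _, d in g.graph.degree()) == [1, 1]
        assert len(g.graph.edges[1, 10, 0]["path"]) == 10

    def test_y_shape(self):
        # one node with two children, all limbs length 5
        nodes = [SkeletonNode(1, 2, np.array([0.0, 0, 0]), 1, -1)]
        nid = 2
        for i in range(1, 6):
            nodes.append(SkeletonNode(nid, 2, np.array([float(i), 0, 0]), 1, nid - 1))
            nid += 1
        center = nid - 1
        for dy in (1.0, -1.0):
            prev = center
            for i in range(1, 6):
                nodes.append(
                    SkeletonNode(nid, 2, np.array([5.0 + i, dy * i, 0]), 1, prev)
                )
                prev = nid
                nid += 1
        g = build_graph(Skeleton(nodes))
        degs = sorted(d for _, d in g.graph.degree())
        assert degs == [1, 1, 1, 3]
        assert g.n_edges == 3

    def test_fusion_link_creates_cycle(self):
        # Y-shape with the two limb endpoints fused: Euler formula check
        nodes = [SkeletonNode(1, 2, np.array([0.0, 0, 0]), 1, -1)]
        nodes.append(SkeletonNode(2, 2, np.array([1.0, 0, 0]), 1, 1))
        for nid, dy in ((3, 1.0), (4, -1.0)):
            nodes.append(SkeletonNode(nid, 2, np.array([2.0, dy, 0]), 1, 2))
        skel = Skeleton(nodes, fusion_links=[(3, 4)])
        g = build_graph(skel)
        degree_sum = sum(d for _, d in g.graph.degree())
        assert degree_sum == 2 * g.n_edges
        import networkx as nx

        cycles = g.n_edges - g.n_nodes + nx.number_connected_components(g.graph)
        assert cycles == 1

    def test_empty_skeleton(self):
        g = build_graph(Skeleton())
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_isolated_node_kept(self):
        skel = Skeleton([SkeletonNode(7, 2, np.array([1.0, 2, 3]), 1, -1)])
        g = build_graph(skel)
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_pure_cycle_anchored(self):
        # 4-node ring closed by a fusion link: all structural degrees are 2
        nodes = [
            SkeletonNode(1, 2, np.array([0.0, 0, 0]), 1, -1),
            SkeletonNode(2, 2, np.array([1.0, 0, 0]), 1, 1),
            SkeletonNode(3, 2, np.array([1.0, 1, 0]), 1, 2),
            SkeletonNode(4, 2, np.array([0.0, 1, 0]), 1, 3),
        ]
        g = build_graph(Skeleton(nodes, fusion_links=[(1, 4)]))
        assert g.n_nodes == 1 and g.n_edges == 1  # self-loop
        assert sum(d for _, d in g.graph.degree()) == 2 * g.n_edges

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_sum_identity_on_random_phantoms(self, seed):
        spec = PhantomSpec(shape=(48, 48, 48), radius_range=(2.0, 4.0),
                           branch_prob=0.08, seed=seed, steps_per_tree=150)
        skel = generate_skeleton(spec)
        g = build_graph(skel)
        assert sum(d for _, d in g.graph.degree()) == 2 * g.n_edges

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_euler_relation(self, seed):
        import networkx as nx

        spec = PhantomSpec(shape=(48, 48, 48), radius_range=(2.0, 4.0),
                           branch_prob=0.08, seed=seed, steps_per_tree=150)
        g = build_graph(generate_skeleton(spec))  # no fusion links: a forest
        ncomp = nx.number_connected_components(g.graph)
        assert g.n_edges == g.n_nodes - ncomp


class TestSkeletonFromAdjacency:
    def test_extra_edges_become_fusion_links(self):
        nodes = {i: ((float(i), 0.0, 0.0), 1.0) for i in range(4)}
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]  # a square ring
        skel, id_map = skeleton_from_adjacency(nodes, edges, return_id_map=True)
        assert len(skel) == 4
        assert len(skel.fusion_links) == 1
        assert set(id_map) == set(nodes)

    def test_parents_precede_children(self):
        nodes = {i: ((float(i), 0.0, 0.0), 1.0) for i in range(6)}
        edges = [(5, 4), (4, 3), (3, 2), (2, 1), (1, 0)]
        skel = skeleton_from_adjacency(nodes, edges)
        for n in skel.nodes:
            assert n.parent == -1 or n.parent < n.id
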