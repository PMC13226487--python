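"""Matching metrics, graph statistics, density, SNR and review regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselbench.core_model import Skeleton, SkeletonNode, build_graph
from vesselbench.metrics import (
    MatchParams,
    branch_angles,
    evaluate_branch_points,
    evaluate_skeleton,
    extract_branch_points,
    extract_endpoints,
    graph_stats,
    match_points,
    skeleton_intensity_stats,
    smartvision_candidates,
    snr,
    vessel_density,
)
from vesselbench.core_model import VoxelSize


def brute_force_match(P, G, thre):
    """All-pairs oracle for the nearest-neighbour threshold rule."""
    P, G = np.atleast_2d(P), np.atleast_2d(G)
    hit_p = sum(
        1 for p in P if min(np.linalg.norm(p - g) for g in G) < thre
    )
    hit_g = sum(
        1 for g in G if min(np.linalg.norm(g - p) for p in P) < thre
    )
    recall = hit_g / len(G)
    precision = hit_p / len(P)
    f1 = 2 * recall * precision / (recall + precision) if recall + precision else 0.0
    return recall, precision, f1


def chain(points, radius=2.0, start_id=1):
    nodes = [
        SkeletonNode(start_id + i, 2, np.asarray(p, float), radius,
                     -1 if i == 0 else start_id + i - 1)
        for i, p in enumerate(points)
    ]
    return Skeleton(nodes)


class TestMatchPoints:
    def test_identical_sets_are_perfect(self):
        pts = np.random.default_rng(0).uniform(0, 50, (30, 3))
        res = match_points(pts, pts, MatchParams(thre=3))
        assert res.recall == res.precision == res.f1 == 1.0

    def test_hand_case_half_matched(self):
        P = [(0, 0, 0), (10, 0, 0)]
        G = [(0, 0, 0), (0, 10, 0)]
        res = match_points(P, G, MatchParams(thre=3))
        assert (res.recall, res.precision, res.f1) == (0.5, 0.5, 0.5)

    def test_huge_threshold_matches_everything(self):
        rng = np.random.default_rng(1)
        res = match_points(rng.uniform(0, 9, (8, 3)), rng.uniform(0, 9, (5, 3)),
                           MatchParams(thre=1e9))
        assert res.recall == res.precision == 1.0

    def test_empty_sets_flagged_degenerate(self):
        res = match_points(np.empty((0, 3)), np.empty((0, 3)))
        assert res.degenerate and res.f1 == 0.0
        res = match_points(np.empty((0, 3)), [(1, 1, 1)])
        assert res.degenerate and res.recall == 0.0

    def test_strict_inequality_at_exact_threshold(self):
        res = match_points([(0, 0, 0)], [(3.0, 0, 0)], MatchParams(thre=3))
        assert res.f1 == 0.0  # distance == thre: no match under '<'
        res = match_points([(0, 0, 0)], [(3.0, 0, 0)],
                           MatchParams(thre=3, inclusive=True))
        assert res.f1 == 1.0

    def test_squared_reading_flag(self):
        # distance 2 -> squared 4: fails thre=3 under the squared reading
        res = match_points([(0, 0, 0)], [(2.0, 0, 0)],
                           MatchParams(thre=3, squared=True))
        assert res.f1 == 0.0

    def test_one_to_one_mode_penalizes_duplicates(self):
        G = [(0, 0, 0)]
        P = [(0.1, 0, 0), (0.2, 0, 0), (0, 0.1, 0)]
        nn = match_points(P, G, MatchParams(thre=3))
        hung = match_points(P, G, MatchParams(thre=3, one_to_one=True))
        assert nn.precision == 1.0
        assert hung.precision == pytest.approx(1 / 3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60), m=st.integers(1, 60))
    def test_matches_all_pairs_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 20, (n, 3))
        G = rng.uniform(0, 20, (m, 3))
        res = match_points(P, G, MatchParams(thre=3))
        recall, precision, f1 = brute_force_match(P, G, 3)
        assert res.recall == pytest.approx(recall)
        assert res.precision == pytest.approx(precision)
        assert res.f1 == pytest.approx(f1)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_recall_precision_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(0, 20, (25, 3))
        G = rng.uniform(0, 20, (40, 3))
        params = MatchParams(thre=3)
        assert match_points(P, G, params).recall == pytest.approx(
            match_points(G, P, params).precision
        )


class TestEvaluateSkeleton:
    def test_self_match_is_one(self, y_junction):
        assert evaluate_skeleton(y_junction.skeleton, y_junction.skeleton).f1 == 1.0

    def test_uniform_shift_beyond_threshold_scores_zero(self):
        pts = [(float(i), 10.0, 10.0) for i in range(5, 25)]
        a = chain(pts)
        b = chain([(x, y + 10.0, z) for x, y, z in pts])
        assert evaluate_skeleton(a, b).f1 == 0.0

    def test_empty_prediction_degenerate(self, y_junction):
        res = evaluate_skeleton(Skeleton(), y_junction.skeleton)
        assert res.degenerate and res.recall == 0.0


class TestBranchEndpointExtraction:
    def test_chain_has_two_endpoints_no_branches(self):
        skel = chain([(i, 0, 0) for i in range(6)])
        assert len(extract_branch_points(skel)) == 0
        assert len(extract_endpoints(skel)) == 2

    def test_y_junction_counts(self, y_junction):
        assert len(extract_branch_points(y_junction.skeleton)) == 1
        assert len(extract_endpoints(y_junction.skeleton)) == 3

    def test_two_disjoint_chains(self):
        a = chain([(i, 0, 0) for i in range(5)])
        b = chain([(i, 10, 0) for i in range(5)], start_id=100)
        merged = Skeleton(list(a.nodes) + list(b.nodes))
        assert len(extract_branch_points(merged)) == 0
        assert len(extract_endpoints(merged)) == 4

    def test_spurious_branch_point_arithmetic(self, y_junction):
        gt = y_junction.skeleton
        # prediction: the true skeleton plus a far-away spurious Y
        extra = []
        nid = 1000
        extra.append(SkeletonNode(nid, 2, np.array([5.0, 5.0, 5.0]), 1, -1))
        for d in ((1.0, 0.0), (0.0, 1.0), (-1.0, -1.0)):
            prev = 1000
            for i in range(1, 7):
                nid += 1
                extra.append(SkeletonNode(
                    nid, 2, np.array([5.0 + d[0] * i, 5.0 + d[1] * i, 5.0]), 1, prev
                ))
                prev = nid
        pred = Skeleton(list(gt.nodes) + extra)
        res = evaluate_branch_points(pred, gt)
        assert res.recall == 1.0
        assert res.precision == pytest.approx(0.5)
        assert res.f1 == pytest.approx(2 / 3)


class TestBranchAngles:
    def test_symmetric_y_angle_ninety_degrees(self, y_junction):
        angles = branch_angles(y_junction.skeleton, voxel_size=VoxelSize(1, 1, 2))
        cc = [a.angle_deg for a in angles if a.pair_kind == "child-child"]
        assert len(cc) == 1
        assert cc[0] == pytest.approx(90.0, abs=2.0)

    def test_straight_chain_has_no_angles(self):
        skel = chain([(i, 0, 0) for i in range(10)])
        assert branch_angles(skel) == []

    def test_collinear_branch_geometry(self):
        # three edges from one node, two collinear: 180 + two 90s
        nodes = [SkeletonNode(1, 2, np.array([10.0, 10, 10]), 1, -1)]
        nid = 2
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0)):
            prev = 1
            for i in range(1, 8):
                nodes.append(SkeletonNode(
                    nid, 2,
                    np.array([10.0 + d[0] * i, 10.0 + d[1] * i, 10.0 + d[2] * i]),
                    1, prev,
                ))
                prev = nid
                nid += 1
        angles = branch_angles(Skeleton(nodes), voxel_size=VoxelSize(1, 1, 1))
        degs = sorted(round(a.angle_deg) for a in angles)
        assert degs == [90, 90, 180]


class TestVesselDensity:
    def test_empty_skeleton_all_zero(self):
        grid = vessel_density(Skeleton(), (192, 192, 192))
        assert grid.densities.shape == (3, 3, 3)
        assert grid.mean == 0.0

    def test_closed_form_single_cell_crossing(self):
        # straight x-axis centerline spanning one full 64-cell at 1x1x2 um
        skel = chain([(0.0, 10, 10), (64.0, 10, 10)])
        grid = vessel_density(skel, (64, 64, 64), VoxelSize(1, 1, 2), cell=64)
        expected = 0.064 / (64 * 64 * 128 * 1e-9)
        assert grid.densities[0, 0, 0] == pytest.approx(expected, rel=1e-3)
        assert grid.densities[0, 0, 0] == pytest.approx(122.07, rel=1e-3)

    def test_192_block_has_27_cells(self):
        grid = vessel_density(Skeleton(), (192, 192, 192))
        assert grid.densities.size == 27

    def test_length_conservation(self, capillary_mesh):
        skel = capillary_mesh.skeleton
        grid = vessel_density(skel, capillary_mesh.spec.shape,
                              capillary_mesh.spec.voxel_size)
        recon = float((grid.densities * grid.cell_volumes_mm3).sum())
        assert recon == pytest.approx(grid.total_length_mm, rel=1e-9)
        # and the total equals the resampled physical arc length
        from vesselbench.annotation_maps import resample_centerline

        total = 0.0
        vs = capillary_mesh.spec.voxel_size
        for cl in resample_centerline(skel):
            seg = np.diff(cl.points * vs.xyz[None, :], axis=0)
            total += np.linalg.norm(seg, axis=1).sum() * 1e-3
        assert grid.total_length_mm == pytest.approx(total, rel=0.01)


class TestIntensityStats:
    def test_constant_volume(self):
        skel = chain([(float(i), 5, 5) for i in range(3, 12)])
        stats = skeleton_intensity_stats(np.full((16, 16, 16), 10.0), skel)
        assert stats.intensity_mean == pytest.approx(10.0)
        assert stats.intensity_sd == pytest.approx(0.0)

    def test_weak_signal_fixture_mean(self, weak_signal):
        stats = skeleton_intensity_stats(weak_signal.image, weak_signal.skeleton)
        assert stats.intensity_mean == pytest.approx(10.0, abs=1.0)

    def test_radius_stats_match_generator(self, capillary_mesh):
        stats = skeleton_intensity_stats(capillary_mesh.image, capillary_mesh.skeleton)
        assert stats.radius_mean == pytest.approx(2.0, rel=0.01)
        assert stats.radius_sd == pytest.approx(0.0, abs=1e-9)

    def test_empty_skeleton_flagged(self):
        stats = skeleton_intensity_stats(np.zeros((4, 4, 4)), Skeleton())
        assert stats.empty


class TestSnr:
    @staticmethod
    def noisy_volume(fg=100.0, bg=10.0, sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        vol = rng.normal(bg, sd, size=(32, 32, 32))
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[12:20, 12:20, 12:20] = True
        vol[mask] = fg
        return vol, mask

    def test_constructed_snr(self):
        vol, mask = self.noisy_volume()
        value = snr(vol, mask)
        assert value == pytest.approx(20.0, rel=0.1)

    def test_noiseless_background_infinite(self):
        vol = np.zeros((16, 16, 16))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[6:10, 6:10, 6:10] = True
        vol[mask] = 50.0
        assert snr(vol, mask) == float("inf")

    def test_linearity_in_signal(self):
        vol, mask = self.noisy_volume(fg=100.0)
        vol2 = vol.copy()
        vol2[mask] = 200.0
        assert snr(vol2, mask) == pytest.approx(2 * snr(vol, mask), rel=1e-6)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            snr(np.ones((4, 4, 4)), np.zeros((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            snr(np.ones((4, 4, 4)), np.ones((4, 4, 4), dtype=bool))


class TestGraphStats:
    def test_chain(self):
        stats = graph_stats(build_graph(chain([(i, 0, 0) for i in range(8)])))
        assert (stats.n_nodes, stats.n_edges) == (2, 1)
        assert stats.degree_histogram == {1: 2}
        assert stats.n_components == 1

    def test_y_junction(self, y_junction):
        stats = graph_stats(build_graph(y_junction.skeleton))
        assert (stats.n_nodes, stats.n_edges) == (4, 3)
        assert stats.degree_histogram == {1: 3, 3: 1}

    def test_two_components(self):
        a = chain([(i, 0, 0) for i in range(5)])
        b = chain([(i, 10, 0) for i in range(5)], start_id=50)
        stats = graph_stats(build_graph(Skeleton(list(a.nodes) + list(b.nodes))))
        assert stats.n_components == 2


class TestSmartVision:
    def test_unbroken_chain_no_interior_rois(self):
        skel = chain([(float(i), 32.0, 32.0) for i in range(2, 62)])
        rois = smartvision_candidates(skel, (64, 64, 64), window=16, stride=8)
        # single endpoints never trigger; at most end windows could pair them
        assert len(rois) == 0

    def test_broken_chain_gap_flagged(self):
        pts = [(float(i), 32.0, 32.0) for i in range(2, 30)]
        a = chain(pts)
        b = chain([(float(i), 32.0, 32.0) for i in range(34, 62)], start_id=100)
        skel = Skeleton(list(a.nodes) + list(b.nodes))
        rois = smartvision_candidates(skel, (64, 64, 64), window=16, stride=8)
        assert len(rois) >= 1
        gap_mid = np.array([31.5, 32.0, 32.0])
        assert any(r.contains(gap_mid) for r in rois)

    def test_y_junction_branch_flagged(self, y_junction):
        rois = smartvision_candidates(
            y_junction.skeleton, y_junction.spec.shape, window=16, stride=8
        )
        bp = np.array(y_junction.meta["branch_point"])
        assert any(r.contains(bp) for r in rois)
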