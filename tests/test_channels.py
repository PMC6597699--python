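"""Cross-section measurement and HT-channel classification."""

import numpy as np
import pytest

import htchannel as hc
from htchannel.channels import (
    ChannelCandidate,
    DetectionParams,
    NodeMetrics,
    compute_node_metrics,
    cross_section_area,
    find_channel_runs,
    ht_index,
    node_tangent,
)
from htchannel.skeleton import SkeletonGraph


def path_graph(positions, extra_edges=()):
    """SkeletonGraph helper: chain along given positions plus extras."""
    n = len(positions)
    edges = [(i, i + 1) for i in range(n - 1)] + list(extra_edges)
    return SkeletonGraph(
        node_positions=np.asarray(positions, dtype=float),
        edges=[(min(a, b), max(a, b)) for a, b in edges],
        node_vertex_map=[np.array([i]) for i in range(n)],
        node_face_map=[np.arange(10 * i, 10 * i + 10) for i in range(n)],
    )


class TestNodeTangent:
    def test_degree2_uses_neighbor_direction(self):
        g = path_graph([[0, 0, -5], [0, 0, 0], [0, 0, 5]])
        t, branch = node_tangent(g, 1)
        np.testing.assert_allclose(np.abs(t), [0, 0, 1])
        assert not branch

    def test_endpoint_points_toward_neighbor(self):
        g = path_graph([[0, 0, 0], [0, 3, 4]])
        t, branch = node_tangent(g, 0)
        np.testing.assert_allclose(t, [0, 0.6, 0.8])
        assert not branch

    def test_branch_node_uses_principal_direction(self):
        pos = [[0, 0, 0], [10, 0, 0], [-10, 0, 0], [0, 5, 0]]
        g = SkeletonGraph(
            node_positions=np.asarray(pos, float),
            edges=[(0, 1), (0, 2), (0, 3)],
            node_vertex_map=[np.array([i]) for i in range(4)],
            node_face_map=[np.array([i]) for i in range(4)],
        )
        t, branch = node_tangent(g, 0)
        assert branch
        assert abs(t[0]) > 0.99  # dominant +/- x

    def test_isolated_node_undefined(self):
        g = SkeletonGraph(np.zeros((1, 3)), [], [np.array([0])], [np.array([], dtype=int)])
        t, branch = node_tangent(g, 0)
        assert t is None and not branch


class TestCrossSection:
    @pytest.mark.parametrize("r", [3.0, 5.0, 8.0])
    def test_cylinder_area_within_10pct_of_analytic(self, r):
        cyl = hc.make_cylinder_mask(r, 40.0, 1.0)
        area, oot = cross_section_area(cyl, np.array([0, 0, 20.0]), np.array([0, 0, 1.0]))
        assert not oot
        assert abs(area - np.pi * r**2) / (np.pi * r**2) < 0.10

    def test_plane_through_background_is_zero(self):
        cyl = hc.make_cylinder_mask(3.0, 20.0, 1.0)
        area, oot = cross_section_area(cyl, np.array([0, 0, -50.0]), np.array([0, 0, 1.0]))
        assert area == 0.0 and oot

    def test_only_connected_region_counted(self):
        # two parallel cylinders: plane crosses both, but only the local one counts
        grid = np.zeros((40, 15, 30), dtype=bool)
        x, y, z = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
        c1 = np.sqrt((x - 10.0) ** 2 + (y - 7.0) ** 2) <= 4
        c2 = np.sqrt((x - 30.0) ** 2 + (y - 7.0) ** 2) <= 4
        mask = hc.BinaryMask(c1 | c2, (1.0, 1.0, 1.0))
        area, _ = cross_section_area(mask, np.array([10.0, 7.0, 15.0]), np.array([0, 0, 1.0]))
        assert area < 1.5 * np.pi * 16  # near one cylinder's area, not two

    def test_point_slightly_off_tissue_recovers_within_one_voxel(self):
        cyl = hc.make_cylinder_mask(5.0, 20.0, 1.0)
        area, oot = cross_section_area(
            cyl, np.array([5.6, 0.0, 10.0]), np.array([0, 0, 1.0])
        )
        assert oot and area > 0


class TestRuns:
    def _metrics(self, graph, narrow_ids, faces_per_node=10):
        out = []
        for i in range(graph.n_nodes):
            deg = graph.degree(i)
            out.append(
                NodeMetrics(
                    node_id=i,
                    tangent=np.array([0.0, 0, 1]),
                    cross_section_area_mm2=10.0 if i in narrow_ids else 500.0,
                    face_count=faces_per_node,
                    is_narrow=i in narrow_ids,
                    is_branch=deg >= 3,
                )
            )
        return out

    def test_no_narrow_nodes_gives_empty_list(self):
        g = path_graph([[0, 0, float(z)] for z in range(5)])
        assert find_channel_runs(g, self._metrics(g, set())) == []

    def test_contiguous_narrow_nodes_form_single_run(self):
        g = path_graph([[0, 0, 2.0 * z] for z in range(10)])
        runs = find_channel_runs(g, self._metrics(g, {4, 5, 6, 7}))
        assert len(runs) == 1
        assert runs[0].node_path == [4, 5, 6, 7]
        assert runs[0].length_mm == pytest.approx(6.0)

    def test_short_runs_rejected_by_min_segments(self):
        # narrow {2,3} then wide, then narrow {5,6,7}: only the 3-run survives
        g = path_graph([[0, 0, float(z)] for z in range(9)])
        runs = find_channel_runs(g, self._metrics(g, {2, 3, 5, 6, 7}))
        assert len(runs) == 1
        assert runs[0].node_path == [5, 6, 7]

    def test_runs_split_at_branch_nodes(self):
        # Y-graph: chain 0-1-2-3-4 with a spur 2-5 making node 2 a branch
        pos = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3], [0, 0, 4], [5, 0, 2.0]])
        g = SkeletonGraph(
            node_positions=pos,
            edges=[(0, 1), (1, 2), (2, 3), (3, 4), (2, 5)],
            node_vertex_map=[np.array([i]) for i in range(6)],
            node_face_map=[np.arange(3) for _ in range(6)],
        )
        runs = find_channel_runs(g, self._metrics(g, {0, 1, 2, 3, 4, 5}))
        # branch node 2 excluded: {0,1}, {3,4} and {5} are all too short
        assert runs == []

    def test_runs_are_node_disjoint(self, phantom_case):
        case = phantom_case("rough-channel")
        seen = set()
        for c in case.candidates:
            assert not (seen & set(c.node_path))
            seen |= set(c.node_path)

    def test_narrow_count_monotone_in_area_threshold(self, phantom_case):
        case = phantom_case("smooth-channel")
        counts = []
        for thr in (30.0, 90.0, 300.0):
            m = compute_node_metrics(case.viable, case.graph, DetectionParams(area_threshold_mm2=thr))
            counts.append(sum(x.is_narrow for x in m))
        assert counts == sorted(counts)


class TestHTIndex:
    def test_definition_arithmetic(self):
        assert ht_index(100, 4.0) == 25.0

    def test_threshold_is_strict(self):
        g = path_graph([[0, 0, float(z)] for z in range(4)])
        metrics = [
            NodeMetrics(i, np.array([0.0, 0, 1]), 10.0, 25, True) for i in range(4)
        ]
        runs = find_channel_runs(g, metrics)  # 100 faces over 3 mm -> 33.3
        assert runs[0].is_ht
        metrics = [
            NodeMetrics(i, np.array([0.0, 0, 1]), 10.0, 26, True) for i in range(4)
        ]
        runs = find_channel_runs(g, metrics)  # 104 faces over 4 mm? 3 mm path -> 34.7
        assert runs[0].ht_index == pytest.approx(104 / 3)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ht_index(10, 0.0)

    def test_face_subdivision_quadruples_index(self):
        # 1:4 subdividing every channel face quadruples faces per mm
        total_faces, length = 120, 10.0
        assert ht_index(4 * total_faces, length) == 4 * ht_index(total_faces, length)


class TestEndToEnd:
    def test_smooth_channel_viable_but_not_ht(self, phantom_case):
        cands = phantom_case("smooth-channel").candidates
        assert len(cands) == 1 and not cands[0].is_ht

    def test_rough_channel_is_ht(self, phantom_case):
        cands = phantom_case("rough-channel").candidates
        assert len(cands) == 1 and cands[0].is_ht

    def test_roughness_increases_ht_index(self, phantom_case):
        from dataclasses import replace

        from htchannel.phantoms import preset_spec

        smooth = phantom_case("smooth-channel").candidates[0]
        rough = phantom_case("rough-channel").candidates[0]
        half_spec = preset_spec("rough-channel")
        half_spec = replace(
            half_spec, channel=replace(half_spec.channel, roughness_amplitude_mm=0.6)
        )
        half = phantom_case(half_spec).candidates[0]
        assert smooth.ht_index <= half.ht_index <= rough.ht_index

    def test_channel_table_schema(self, phantom_case):
        from htchannel.channels import channel_table

        df = channel_table(phantom_case("rough-channel").candidates)
        assert list(df.columns[:3]) == ["channel_id", "n_nodes", "length_mm"]
        assert bool(df.is_ht.any())
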