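"""Laplacian contraction and skeletal-graph construction."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage

import htchannel as hc
from htchannel.meshing import normalize_to_unit_cube
from htchannel.skeleton import ContractionParams, contract, thin_to_graph


def n_cycles(G):
    return len(G.edges) - len(G.nodes) + nx.number_connected_components(G)


def containment_fraction(graph, mask, dilate_voxels=2):
    dil = ndimage.binary_dilation(mask.grid, iterations=dilate_voxels)
    idx = np.floor(
        (graph.node_positions - np.asarray(mask.origin)) / np.asarray(mask.spacing) + 0.5
    ).astype(int)
    shape = np.asarray(mask.grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    inside = np.zeros(len(idx), dtype=bool)
    inside[ok] = dil[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return inside.mean()


class TestContraction:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            ContractionParams(volume_ratio_stop=1.5)
        with pytest.raises(ValueError):
            ContractionParams(w_h0=-1.0)
        with pytest.raises(ValueError):
            ContractionParams(w_l0="nonsense")

    def test_zero_iterations_is_identity(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_sphere_mask(5.0, 1.0)), 2000, 0.5, 100)
        norm, _ = normalize_to_unit_cube(mesh)
        state = contract(norm, ContractionParams(max_iterations=0))
        np.testing.assert_array_equal(state.points, norm.vertices)

    def test_unnormalized_mesh_rejected(self):
        mesh = hc.mask_to_mesh(hc.make_sphere_mask(5.0, 1.0))
        with pytest.raises(ValueError):
            contract(mesh)

    def test_cylinder_collapses_to_axis(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_cylinder_mask(3.0, 60.0, 1.0)), 4000, 0.5, 100)
        norm, tf = normalize_to_unit_cube(mesh)
        state = contract(norm)
        mm = tf.invert(state.points)
        mid = (mm[:, 2] > 6) & (mm[:, 2] < 54)  # middle 80% of the length
        assert mid.sum() > 100
        axis_dist = np.linalg.norm(mm[mid][:, :2], axis=1)
        assert axis_dist.max() < 1.0  # within one voxel of the analytic axis

    def test_sphere_collapses_toward_centroid(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_sphere_mask(10.0, 1.0)), 3000, 0.5, 100)
        norm, _ = normalize_to_unit_cube(mesh)
        state = contract(norm)
        diag0 = np.linalg.norm(norm.vertices.max(0) - norm.vertices.min(0))
        diag1 = np.linalg.norm(state.points.max(0) - state.points.min(0))
        assert 1 - diag1 / diag0 > 0.90

    def test_area_history_non_increasing_within_tolerance(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_cylinder_mask(3.0, 40.0, 1.0)), 3000, 0.5, 100)
        norm, _ = normalize_to_unit_cube(mesh)
        state = contract(norm)
        hist = np.asarray(state.area_history)
        assert (np.diff(hist) <= 0.05).all()
        assert hist[-1] < hist[0]


class TestThinning:
    def test_cylinder_gives_path_graph(self, skeleton_of):
        g = skeleton_of("cyl", hc.make_cylinder_mask(3.0, 60.0, 1.0))
        degs = sorted(g.degree(i) for i in range(g.n_nodes))
        assert degs[:2] == [1, 1] and all(d == 2 for d in degs[2:])

    def test_torus_gives_single_cycle(self, skeleton_of):
        g = skeleton_of("torus", hc.make_torus_mask(20.0, 4.0, 1.0))
        assert n_cycles(g.to_networkx()) == 1

    def test_sphere_gives_no_cycle(self, skeleton_of):
        g = skeleton_of("sphere", hc.make_sphere_mask(10.0, 1.0))
        assert n_cycles(g.to_networkx()) == 0

    def test_two_components_give_two_subgraphs(self, skeleton_of, two_blob_mask):
        g = skeleton_of("blobs", two_blob_mask)
        assert nx.number_connected_components(g.to_networkx()) == 2

    def test_vertex_maps_partition_mesh_vertices(self, skeleton_of):
        g = skeleton_of("cyl", hc.make_cylinder_mask(3.0, 60.0, 1.0))
        all_ids = np.concatenate(g.node_vertex_map)
        assert len(all_ids) == len(np.unique(all_ids))
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_cylinder_mask(3.0, 60.0, 1.0)), 4000, 0.5, 100)
        assert len(all_ids) == mesh.n_vertices

    def test_face_maps_partition_mesh_faces(self, skeleton_of):
        g = skeleton_of("torus", hc.make_torus_mask(20.0, 4.0, 1.0))
        all_faces = np.concatenate([f for f in g.node_face_map if len(f)])
        assert len(all_faces) == len(np.unique(all_faces))

    def test_no_self_loops_or_duplicate_edges(self, skeleton_of):
        g = skeleton_of("torus", hc.make_torus_mask(20.0, 4.0, 1.0))
        assert all(a != b for a, b in g.edges)
        assert len(g.edges) == len(set(g.edges))

    def test_tube_skeleton_contained_in_dilated_mask(self, skeleton_of):
        for key, mask in [
            ("cyl", hc.make_cylinder_mask(3.0, 60.0, 1.0)),
            ("torus", hc.make_torus_mask(20.0, 4.0, 1.0)),
        ]:
            g = skeleton_of(key, mask)
            assert containment_fraction(g, mask) >= 0.95

    def test_deterministic_given_seed(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_cylinder_mask(3.0, 40.0, 1.0)), 3000, 0.5, 100)
        g1 = hc.skeletonize(mesh, seed=7)
        g2 = hc.skeletonize(mesh, seed=7)
        np.testing.assert_array_equal(g1.node_positions, g2.node_positions)
        assert g1.edges == g2.edges
        for a, b in zip(g1.node_vertex_map, g2.node_vertex_map):
            np.testing.assert_array_equal(a, b)

    def test_oversized_radius_gives_single_node(self):
        mesh = hc.clean_mesh(hc.mask_to_mesh(hc.make_sphere_mask(5.0, 1.0)), 2000, 0.5, 100)
        g = hc.skeletonize(mesh, ContractionParams(sample_radius_mm=500.0), seed=0)
        assert g.n_nodes == 1

    def test_empty_mesh_rejected(self):
        from htchannel.meshing import SurfaceMesh

        with pytest.raises(ValueError):
            hc.skeletonize(SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)), seed=0)


class TestLShapedTube:
    def test_l_tube_skeleton_endpoints_and_length(self):
        # L-shaped tube: two orthogonal arms of 30 mm, r = 3 mm
        grid = np.zeros((44, 14, 44), dtype=bool)
        x, y, z = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
        arm1 = (np.sqrt((y - 7.0) ** 2 + (z - 7.0) ** 2) <= 3) & (x >= 7) & (x <= 37)
        arm2 = (np.sqrt((y - 7.0) ** 2 + (x - 37.0) ** 2) <= 3) & (z >= 7) & (z <= 37)
        mask = hc.BinaryMask(arm1 | arm2, (1.0, 1.0, 1.0))
        mesh = hc.clean_mesh(hc.mask_to_mesh(mask), 4000, 0.5, 100)
        g = hc.skeletonize(mesh, seed=0)
        G = g.to_networkx()
        degs = sorted(d for _, d in G.degree())
        assert degs.count(1) == 2  # two endpoints
        assert n_cycles(G) == 0
        total = sum(
            np.linalg.norm(g.node_positions[a] - g.node_positions[b]) for a, b in g.edges
        )
        centerline = 30.0 + 30.0  # designed arm lengths
        assert abs(total - centerline) / centerline < 0.15


class TestWriters:
    def test_json_and_graphml_roundtrip_topology(self, tmp_path, skeleton_of):
        import json

        from htchannel.skeleton import write_skeleton_graphml, write_skeleton_json

        g = skeleton_of("cyl", hc.make_cylinder_mask(3.0, 60.0, 1.0))
        write_skeleton_json(g, tmp_path / "s.json")
        payload = json.loads((tmp_path / "s.json").read_text())
        assert len(payload["nodes"]) == g.n_nodes
        assert len(payload["edges"]) == len(g.edges)
        write_skeleton_graphml(g, tmp_path / "s.graphml")
        back = nx.read_graphml(tmp_path / "s.graphml")
        assert len(back.nodes) == g.n_nodes
        assert len(back.edges) == len(g.edges)
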