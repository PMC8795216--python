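"""Segmentation, skeletonization and minimum-cost path tracing."""
import networkx as nx
import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from flowtrace import geometry, phantom, preprocess
from flowtrace.geometry import (COST_EPS_HU, MarkerSet, SkeletonGraph,
                                VesselMask, assemble_paths, min_cost_path,
                                restrict_to_roi, segment_vessels, skeletonize)
from conftest import straight_tube_spec, y_tree_spec


@pytest.fixture(scope="module")
def ytree_tmip(ytree_rendered):
    return preprocess.compute_tmip(ytree_rendered)


@pytest.fixture(scope="module")
def ytree_mask(ytree, ytree_tmip):
    return segment_vessels(ytree_tmip, threshold_hu=240.0)


@pytest.fixture(scope="module")
def ytree_skel(ytree_mask):
    return skeletonize(ytree_mask)


class TestSegmentVessels:
    def test_threshold_recovers_ground_truth_mask(self, ytree, ytree_tmip):
        gt, _ = phantom.rasterize_tree(ytree)
        mask = segment_vessels(ytree_tmip, threshold_hu=240.0)
        covered = (mask.data & gt).sum() / gt.sum()
        assert covered >= 0.95
        from scipy import ndimage
        dilated = ndimage.binary_dilation(gt, iterations=1)
        assert not (mask.data & ~dilated).any()

    def test_threshold_above_max_is_error(self, ytree_tmip):
        with pytest.raises(ValueError, match="empty"):
            segment_vessels(ytree_tmip, threshold_hu=1e5)

    def test_supplied_mask_passes_through(self, ytree, ytree_tmip):
        gt, _ = phantom.rasterize_tree(ytree)
        supplied = VesselMask(gt, ytree.spacing)
        out = segment_vessels(ytree_tmip, method="supplied",
                              supplied_mask=supplied)
        assert out is supplied

    def test_supplied_mask_grid_mismatch_rejected(self, ytree_tmip):
        bad = VesselMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            segment_vessels(ytree_tmip, method="supplied", supplied_mask=bad)

    def test_small_components_removed(self):
        data = np.zeros((12, 12, 12))
        data[2:8, 2:5, 2:5] = 400.0  # 54 voxels, survives
        data[10, 10, 10] = 400.0     # speck, removed
        tmip = preprocess.Volume3D(data, (1, 1, 1))
        mask = segment_vessels(tmip, threshold_hu=200.0,
                               min_component_voxels=27)
        assert mask.data[3, 3, 3] and not mask.data[10, 10, 10]


class TestRoi:
    def test_full_roi_is_identity(self, ytree_mask):
        out = restrict_to_roi(ytree_mask, np.ones(ytree_mask.data.shape, bool))
        np.testing.assert_array_equal(out.data, ytree_mask.data)

    def test_empty_roi_warns(self, ytree_mask):
        with pytest.warns(UserWarning, match="ROI"):
            out = restrict_to_roi(ytree_mask,
                                  np.zeros(ytree_mask.data.shape, bool))
        assert not out.data.any()

    def test_halfspace_roi_keeps_matching_truth_points(self, ytree,
                                                       ytree_mask):
        _, truth = phantom.rasterize_tree(ytree)
        roi = np.zeros(ytree_mask.data.shape, bool)
        roi[:, :18, :] = True  # keeps only the lower part of the mother
        out = restrict_to_roi(ytree_mask, roi)
        for tr in truth:
            for p in tr["points_mm"]:
                v = tuple(int(round(c)) for c in p)
                if ytree_mask.data[v]:
                    assert out.data[v] == roi[v]


class TestSkeletonize:
    def test_straight_tube_gives_single_chain_on_axis(self):
        spec = straight_tube_spec(5.0, length_mm=40.0, radius_mm=2.0)
        gt, _ = phantom.rasterize_tree(spec)
        skel = skeletonize(VesselMask(gt, spec.spacing))
        degrees = [d for _, d in skel.graph.degree]
        assert max(degrees) <= 2
        nodes = np.array(list(skel.graph.nodes))
        # every skeleton voxel within 1.5 voxels of the analytic axis
        assert np.all(np.hypot(nodes[:, 1] - 4, nodes[:, 2] - 4) <= 1.5)
        eps = skel.endpoints()
        xs = sorted(n[0] for n in eps)
        assert abs(xs[0] - 3) <= 3 and abs(xs[-1] - 43) <= 3

    def test_single_voxel_mask(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        skel = skeletonize(VesselMask(data, (1, 1, 1)))
        assert list(skel.graph.nodes) == [(2, 2, 2)]

    def test_y_tree_topology(self, ytree_skel):
        assert len(ytree_skel.endpoints()) == 3
        assert len(ytree_skel.branch_nodes()) == 1

    def test_component_count_preserved(self):
        spec = straight_tube_spec(5.0, length_mm=20.0)
        gt, _ = phantom.rasterize_tree(spec)
        two = np.zeros((30, 30, 9), bool)
        two[:gt.shape[0], :9, :] = gt[:, :, :]
        two[5:25, 20:23, 3:6] = True  # second blob
        skel = skeletonize(VesselMask(two, (1, 1, 1)))
        from skimage import measure
        assert (nx.number_connected_components(skel.graph)
                == measure.label(two, connectivity=3).max() == 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(VesselMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))


def _chain_graph(n, spacing=(1, 1, 1)):
    g = nx.Graph()
    for i in range(n - 1):
        g.add_edge((i, 0, 0), (i + 1, 0, 0), length_mm=1.0)
    return SkeletonGraph(g, spacing, (n, 1, 1))


class TestMinCostPath:
    def test_uniform_chain_returns_chain_with_euclidean_arclength(self):
        skel = _chain_graph(10)
        tmip = preprocess.Volume3D(np.full((10, 1, 1), 300.0), (1, 1, 1))
        path = min_cost_path(tmip, skel, (0, 0, 0), (9, 0, 0))
        assert path.voxels == [(i, 0, 0) for i in range(10)]
        np.testing.assert_allclose(path.arclength_mm, np.arange(10.0))
        assert path.total_cost == pytest.approx(9 * COST_EPS_HU)

    def test_follows_bright_s_curve_and_matches_dijkstra_oracle(self):
        # planar grid graph with a bright 4-connected S-shaped route
        n = 20
        img = np.full((n, n, 1), 50.0)
        curve = [(i, 2, 0) for i in range(10)]
        curve += [(9, j, 0) for j in range(3, 17)]
        curve += [(i, 16, 0) for i in range(10, n)]
        for v in curve:
            img[v] = 400.0
        g = nx.Graph()
        for i in range(n):
            for j in range(n):
                if i + 1 < n:
                    g.add_edge((i, j, 0), (i + 1, j, 0), length_mm=1.0)
                if j + 1 < n:
                    g.add_edge((i, j, 0), (i, j + 1, 0), length_mm=1.0)
        skel = SkeletonGraph(g, (1, 1, 1), (n, n, 1))
        tmip = preprocess.Volume3D(img, (1, 1, 1))
        path = min_cost_path(tmip, skel, curve[0], curve[-1])
        oracle = _oracle_cost(g, tmip, curve[0], curve[-1])
        assert path.total_cost == pytest.approx(oracle)
        assert set(curve) <= set(path.voxels)

    def test_equal_cost_tie_breaks_deterministically(self):
        # symmetric diamond: two equal-cost routes; the route through the
        # lexicographically smaller middle node must win
        g = nx.Graph()
        a, b, c, d = (0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 0, 0)
        for u, v in [(a, b), (b, d), (a, c), (c, d)]:
            g.add_edge(u, v, length_mm=1.0)
        skel = SkeletonGraph(g, (1, 1, 1), (3, 2, 1))
        tmip = preprocess.Volume3D(np.full((3, 2, 1), 100.0), (1, 1, 1))
        path = min_cost_path(tmip, skel, a, d)
        assert path.voxels == [a, b, d]

    def test_disconnected_endpoints_raise(self):
        g = nx.Graph()
        g.add_edge((0, 0, 0), (1, 0, 0), length_mm=1.0)
        g.add_edge((5, 0, 0), (6, 0, 0), length_mm=1.0)
        skel = SkeletonGraph(g, (1, 1, 1), (8, 1, 1))
        tmip = preprocess.Volume3D(np.full((8, 1, 1), 100.0), (1, 1, 1))
        with pytest.raises(ValueError, match="no path"):
            min_cost_path(tmip, skel, (0, 0, 0), (6, 0, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_sparse_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        img = rng.uniform(50, 450, (n, n, n))
        g = nx.Graph()
        corners = {(0, 0, 0), (n - 1, n - 1, n - 1)}
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if rng.random() < 0.15 and (i, j, k) not in corners:
                        continue  # knock out some nodes
                    for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                        m = (i + off[0], j + off[1], k + off[2])
                        if all(c < n for c in m):
                            g.add_edge((i, j, k), m,
                                       length_mm=float(rng.uniform(0.5, 2)))
        src, dst = (0, 0, 0), (n - 1, n - 1, n - 1)
        skel = SkeletonGraph(g, (1, 1, 1), (n, n, n))
        tmip = preprocess.Volume3D(img, (1, 1, 1))
        if src not in g or dst not in g:
            return  # corner isolated by knockout; nothing to compare
        if not nx.has_path(g, src, dst):
            with pytest.raises(ValueError, match="no path"):
                min_cost_path(tmip, skel, src, dst)
            return
        path = min_cost_path(tmip, skel, src, dst)
        assert path.total_cost == pytest.approx(
            _oracle_cost(g, tmip, src, dst))


def _oracle_cost(g, tmip, src, dst):
    """Independent shortest-path cost via scipy.sparse.csgraph."""
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    imax = max(tmip.data[n] for n in nodes)
    mat = lil_matrix((len(nodes), len(nodes)))
    for u, v, data in g.edges(data=True):
        w = data["length_mm"] * (imax - 0.5 * (tmip.data[u] + tmip.data[v])
                                 + COST_EPS_HU)
        mat[index[u], index[v]] = w
        mat[index[v], index[u]] = w
    dist = csgraph_dijkstra(mat.tocsr(), indices=index[src])
    return dist[index[dst]]


class TestAssemblePaths:
    def test_single_distal_marker_single_path(self, ytree, ytree_tmip,
                                              ytree_skel):
        markers = MarkerSet((20, 6, 6), (20, 12, 6), [(12, 28, 6)])
        paths = assemble_paths(ytree_tmip, ytree_skel, markers)
        assert len(paths) == 1
        p = paths[0]
        assert p.breakpoints == []
        assert set(p.segment_ids) == {"proximal", "thrombus", "mother"}
        assert np.all(np.diff(p.arclength_mm) > 0)

    def test_two_distal_markers_share_prefix_until_bifurcation(
            self, ytree, ytree_tmip, ytree_skel):
        markers = MarkerSet((20, 6, 6), (20, 12, 6),
                            [(12, 28, 6), (28, 28, 6)])
        paths = assemble_paths(ytree_tmip, ytree_skel, markers)
        assert len(paths) == 2
        assert "daughter1" in paths[0].segment_ids
        assert "daughter2" in paths[1].segment_ids
        bp1, bp2 = paths[0].breakpoints[0], paths[1].breakpoints[0]
        assert bp1[1] == bp2[1]
        # divergence close to the true junction at (20, 20, 6)
        assert np.linalg.norm(np.subtract(bp1[1], (20, 20, 6))) <= 3
        shared1 = [v for v, s in zip(paths[0].voxels, paths[0].segment_ids)
                   if s in ("proximal", "thrombus", "mother")]
        shared2 = [v for v, s in zip(paths[1].voxels, paths[1].segment_ids)
                   if s in ("proximal", "thrombus", "mother")]
        assert shared1 == shared2

    def test_distal_marker_before_thrombus_rejected(self, ytree_tmip,
                                                    ytree_skel):
        markers = MarkerSet((20, 6, 6), (20, 16, 6), [(20, 10, 6)])
        with pytest.raises(ValueError, match="proximal"):
            assemble_paths(ytree_tmip, ytree_skel, markers)

    def test_snap_failure_names_the_marker(self, ytree_tmip, ytree_skel):
        markers = MarkerSet((2, 2, 2), (20, 12, 6), [(12, 28, 6)])
        with pytest.raises(ValueError, match="proximal"):
            assemble_paths(ytree_tmip, ytree_skel, markers)

    def test_paths_depend_only_on_tmip_not_frame_order(self, ytree,
                                                       ytree_rendered,
                                                       ytree_skel):
        rng = np.random.default_rng(1)
        perm = rng.permutation(ytree_rendered.n_frames)
        dyn_p = preprocess.DynamicCTA(ytree_rendered.data[..., perm],
                                      ytree.spacing, ytree.dt)
        markers = MarkerSet((20, 6, 6), (20, 12, 6), [(12, 28, 6)])
        t1 = preprocess.compute_tmip(ytree_rendered)
        t2 = preprocess.compute_tmip(dyn_p)
        p1 = assemble_paths(t1, ytree_skel, markers)
        p2 = assemble_paths(t2, ytree_skel, markers)
        assert p1[0].voxels == p2[0].voxels
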