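"""Skeletonization, spatial-graph construction, radii, pruning, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vesselvol as vv
from vesselvol.errors import DataError
from vesselvol.graph import GraphEdge, GraphNode, SpatialGraph, resample_chain


def _mask(data, spacing=(1.0, 1.0, 1.0), unit="mm"):
    return vv.BinaryMask(np.asarray(data, bool), spacing, unit=unit)


# -- skeletonize ------------------------------------------------------------


def test_skeleton_is_subset_and_preserves_components(noisy_tube):
    import scipy.ndimage as ndi

    mask = noisy_tube["mask"]
    sk = vv.skeletonize(mask)
    assert not np.any(sk.data & ~mask.data)
    s26 = np.ones((3, 3, 3))
    assert ndi.label(sk.data, structure=s26)[1] == ndi.label(mask.data, structure=s26)[1]


def test_skeleton_of_straight_tube_is_single_on_axis_path(noisy_tube):
    """All skeleton voxels lie within 1 voxel of the analytic axis and form
    one open path (two endpoints, no branches)."""
    graph = noisy_tube["graph"]
    truth = noisy_tube["truth"]
    assert len(graph.edges) == 1
    assert len(graph.endpoints()) == 2
    assert len(graph.branch_nodes()) == 0
    axis_p0 = truth.tubes[0].curve.p0
    axis_p1 = truth.tubes[0].curve.p1
    pts = graph.edges[0].points
    # distance of each chain point to the (x-aligned) axis line
    d = np.sqrt((pts[:, 1] - axis_p0[1]) ** 2 + (pts[:, 2] - axis_p0[2]) ** 2)
    spacing = noisy_tube["grid"].spacing[0]
    assert d.max() <= spacing + 1e-9


def test_skeleton_of_solid_sphere_collapses_to_center_cluster():
    x, y, z = np.indices((17, 17, 17))
    ball = (x - 8) ** 2 + (y - 8) ** 2 + (z - 8) ** 2 <= 36
    sk = vv.skeletonize(_mask(ball))
    pts = np.argwhere(sk.data)
    assert 1 <= len(pts) <= 10
    assert np.linalg.norm(pts.mean(axis=0) - 8, ord=np.inf) <= 2.0


def test_skeletonize_empty_mask_is_error():
    with pytest.raises(DataError):
        vv.skeletonize(_mask(np.zeros((4, 4, 4))))


def test_symmetric_even_width_tube_still_yields_a_skeleton():
    """Perfectly symmetric even-diameter tubes can be fully eroded by
    thinning; the component-preservation guarantee must kick in."""
    x, y, z = np.indices((40, 16, 16)).astype(float)
    t = np.clip(x, 7, 33)
    d = np.sqrt((x - t) ** 2 + (y - 7.5) ** 2 + (z - 7.5) ** 2)
    sk = vv.skeletonize(_mask(d <= 4.0))
    assert sk.data.sum() >= 1


# -- build_graph ------------------------------------------------------------


def test_straight_tube_arc_length_covers_axis_minus_end_retraction(noisy_tube):
    """Thinning retracts open tube ends by up to ~r/2 + 1 voxel; the chain
    must cover the rest of the axis and never exceed it by more than one
    voxel diagonal."""
    graph = noisy_tube["graph"]
    truth = noisy_tube["truth"]
    L = truth.tubes[0].curve.length
    r = truth.tubes[0].profile.radius
    spacing = noisy_tube["grid"].spacing[0]
    diag = np.sqrt(3) * spacing
    length = graph.edges[0].length
    assert L - 2 * (r / 2 + spacing) <= length <= L + diag


def test_y_phantom_graph_topology(y_phantom):
    graph = y_phantom["graph"]
    assert len(graph.endpoints()) == 3
    assert len(graph.branch_nodes()) == 1
    assert len(graph.edges) == 3
    assert graph.cycle_count() == 0


def test_ring_graph_is_single_cycle_with_true_circumference(ring_phantom):
    graph = ring_phantom["graph"]
    truth = ring_phantom["truth"]
    assert len(graph.endpoints()) == 0
    assert graph.cycle_count() == 1
    assert len(graph.edges) == 1
    assert graph.edges[0].is_cycle
    circumference = truth.extras["circumference"]
    assert graph.total_length == pytest.approx(circumference, rel=0.02)


def test_chain_steps_bounded_by_voxel_diagonal(noisy_tube, y_phantom):
    for fx in (noisy_tube, y_phantom):
        spacing = np.asarray(fx["grid"].spacing)
        diag = np.linalg.norm(spacing)
        for e in fx["graph"].edges:
            steps = np.linalg.norm(np.diff(e.points, axis=0), axis=1)
            assert steps.max() <= diag + 1e-9


def test_node_degrees_match_incident_edge_ends(y_phantom):
    graph = y_phantom["graph"]
    counts = {nid: 0 for nid in graph.nodes}
    for e in graph.edges:
        counts[e.node_a] += 1
        counts[e.node_b] += 1
    for nid, node in graph.nodes.items():
        assert node.degree == counts[nid]


def test_graph_json_roundtrip(y_phantom, tmp_path):
    graph = y_phantom["graph"]
    path = tmp_path / "graph.json"
    graph.to_json(path)
    back = SpatialGraph.from_json(path)
    assert set(back.nodes) == set(graph.nodes)
    assert len(back.edges) == len(graph.edges)
    for e1, e2 in zip(graph.edges, back.edges):
        np.testing.assert_allclose(e1.points, e2.points)
        np.testing.assert_allclose(e1.radii, e2.radii)


# -- estimate_radii ---------------------------------------------------------


def test_tube_radius_recovered_within_half_voxel(noisy_tube):
    """Median |r - 60 um| over interior points <= 0.5 voxel (7.5 um)."""
    graph = noisy_tube["graph"]
    spacing = noisy_tube["grid"].spacing[0]
    radii = graph.edges[0].radii[3:-3]  # exclude retracted chain ends
    err = np.abs(radii - 60.0)
    assert np.median(err) <= 0.5 * spacing


def test_thin_line_mask_gives_subvoxel_radii():
    data = np.zeros((20, 9, 9), dtype=bool)
    data[3:17, 4, 4] = True  # one-voxel-thick line
    mask = _mask(data, spacing=(2.0, 2.0, 2.0))
    graph = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask)), mask)
    for e in graph.edges:
        assert np.all(e.radii <= np.linalg.norm(mask.spacing))


def test_stenosis_dip_recovered_in_radius_profile():
    grid, truth = vv.preset_stenosis(
        radius_voxels=5.5, length_voxels=120, severity=0.2, blur_sigma_voxels=0.5
    )
    mask = vv.threshold_segment(grid, 127.5)
    graph = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask)), mask)
    e = graph.edges[0]
    r0 = truth.tubes[0].profile.radius
    lo, hi = truth.extras["stenosis_plateau"]
    x0 = truth.tubes[0].curve.p0[0]
    in_plateau = (e.points[:, 0] >= x0 + lo) & (e.points[:, 0] <= x0 + hi)
    outside = (e.points[:, 0] < x0 + lo - 400) | (e.points[:, 0] > x0 + hi + 400)
    spacing = grid.spacing[0]
    assert np.median(e.radii[in_plateau]) == pytest.approx(0.8 * r0, abs=0.5 * spacing)
    assert np.median(e.radii[outside & (e.radii > 0)]) == pytest.approx(r0, abs=0.5 * spacing)


def test_radii_invariant_under_whole_voxel_translation(noisy_tube):
    mask = noisy_tube["mask"]
    shifted = np.roll(mask.data, shift=(2, 1, 1), axis=(0, 1, 2))
    mask2 = vv.BinaryMask(shifted, mask.spacing, mask.origin, mask.unit)
    g1 = noisy_tube["graph"]
    g2 = vv.estimate_radii(vv.build_graph(vv.skeletonize(mask2)), mask2)
    r1 = np.sort(np.concatenate([e.radii for e in g1.edges]))
    r2 = np.sort(np.concatenate([e.radii for e in g2.edges]))
    np.testing.assert_allclose(r1, r2)


# -- prune_spurs ------------------------------------------------------------


def _graph_with_spur(spur_len=2.0):
    """Hand-built graph: a 20-long trunk with a short terminal spur."""
    trunk1 = np.column_stack([np.arange(0.0, 11.0), np.zeros(11), np.zeros(11)])
    trunk2 = np.column_stack([np.arange(10.0, 21.0), np.zeros(11), np.zeros(11)])
    n_spur = int(spur_len) + 1
    spur = np.column_stack(
        [np.full(n_spur, 10.0), np.arange(0.0, float(n_spur)), np.zeros(n_spur)]
    )
    nodes = {
        0: GraphNode(0, trunk1[0], 1),
        1: GraphNode(1, trunk1[-1], 3),
        2: GraphNode(2, trunk2[-1], 1),
        3: GraphNode(3, spur[-1], 1),
    }
    edges = [  # radii 3: the spur is shorter than 2x the junction radius
        GraphEdge(0, 0, 1, trunk1, np.full(11, 3.0)),
        GraphEdge(1, 1, 2, trunk2, np.full(11, 3.0)),
        GraphEdge(2, 1, 3, spur, np.full(n_spur, 3.0)),
    ]
    return SpatialGraph(nodes, edges, (1.0, 1.0, 1.0), "mm")


def test_prune_removes_short_spur_and_merges_trunk():
    pruned = vv.prune_spurs(_graph_with_spur(spur_len=2.0), min_length=5.0)
    assert len(pruned.edges) == 1
    assert pruned.edges[0].length == pytest.approx(20.0)
    assert len(pruned.nodes) == 2


def test_prune_zero_min_length_is_identity():
    g = _graph_with_spur()
    pruned = vv.prune_spurs(g, min_length=0.0)
    assert len(pruned.edges) == len(g.edges)
    assert len(pruned.nodes) == len(g.nodes)


def test_prune_is_idempotent_at_fixpoint():
    once = vv.prune_spurs(_graph_with_spur(), min_length=5.0)
    twice = vv.prune_spurs(once, min_length=5.0)
    assert len(twice.edges) == len(once.edges)
    for e1, e2 in zip(once.edges, twice.edges):
        np.testing.assert_allclose(e1.points, e2.points)


def test_prune_never_removes_cycle_edges(ring_phantom):
    pruned = vv.prune_spurs(ring_phantom["graph"], min_length=1e9)
    assert len(pruned.edges) == 1
    assert pruned.edges[0].is_cycle


def test_prune_keeps_isolated_vessel():
    """A lone open tube (both ends free) is not a spur and must survive."""
    pts = np.column_stack([np.arange(0.0, 4.0), np.zeros(4), np.zeros(4)])
    g = SpatialGraph(
        {0: GraphNode(0, pts[0], 1), 1: GraphNode(1, pts[-1], 1)},
        [GraphEdge(0, 0, 1, pts, np.ones(4))],
        (1.0, 1.0, 1.0),
        "mm",
    )
    pruned = vv.prune_spurs(g, min_length=100.0)
    assert len(pruned.edges) == 1


# -- resample_chain ---------------------------------------------------------


def test_resample_straight_chain_exact_multiples():
    pts = np.column_stack([np.linspace(0, 100, 51), np.zeros(51), np.zeros(51)])
    new_pts, _ = resample_chain(pts, None, step=10.0)
    assert len(new_pts) == 11
    np.testing.assert_allclose(new_pts[:, 0], np.arange(0, 101, 10.0), atol=1e-9)


def test_resample_preserves_constant_radius_and_endpoints():
    pts = np.column_stack([np.linspace(0, 30, 16), np.zeros(16), np.zeros(16)])
    new_pts, new_r = resample_chain(pts, np.full(16, 3.3), step=2.0)
    assert np.all(new_r == pytest.approx(3.3))
    np.testing.assert_allclose(new_pts[0], pts[0])
    np.testing.assert_allclose(new_pts[-1], pts[-1])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 2.0))
def test_resample_length_within_one_step_of_original(seed, step):
    """On curvature-resolved chains (step well below the bending scale) the
    resampled polyline length stays within one step of the original."""
    rng = np.random.default_rng(seed)
    radius = rng.uniform(2.0, 5.0)
    pitch = rng.uniform(0.5, 2.0)
    t = np.linspace(0, 4 * np.pi, 200)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), pitch * t])
    new_pts, _ = resample_chain(pts, None, step=step)
    orig = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    new = np.linalg.norm(np.diff(new_pts, axis=0), axis=1).sum()
    assert new <= orig + 1e-9  # chords never exceed the polyline
    assert orig - new <= step + 1e-9


def test_resample_short_chain_reduces_to_endpoints():
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    new_pts, _ = resample_chain(pts, None, step=10.0)
    assert len(new_pts) == 2
    np.testing.assert_allclose(new_pts, [[0, 0, 0], [2, 0, 0]])
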