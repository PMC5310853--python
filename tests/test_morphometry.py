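"""Diameters at landmarks, segment extraction, cylindrical volumetry, export."""

import numpy as np
import pytest
from scipy.integrate import quad

import vesselvol as vv
from vesselvol.errors import AmbiguousRouteError, DataError, LandmarkMissError
from vesselvol.graph import GraphEdge, GraphNode, SpatialGraph
from vesselvol.morphometry import (
    Arm,
    Landmark,
    VesselSegment,
    export_colorcoded,
    extract_segment,
    measure_diameter_at,
    segment_volume,
    snap_landmark,
    volume_per_length,
)


def _straight_segment(radius, length, step, unit="mm", radii=None):
    """Hand-built single-arm segment along x with the given radius profile."""
    n = int(round(length / step)) + 1
    pts = np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)])
    r = np.full(n, radius) if radii is None else np.asarray(radii)
    arm = Arm("distal", length, length, False, pts, r)
    return VesselSegment("anchor", pts[0], [arm], step, unit)


# -- diameters --------------------------------------------------------------


def test_diameter_on_mca_scale_tube(vaso_report):
    """A tube of true radius 82.5 um reads a diameter of 165 um within one
    voxel equivalent (15 um)."""
    assert vaso_report["sham_diameter_um"] == pytest.approx(165.0, abs=15.0)


def test_landmark_exactly_on_chain_point_returns_stored_diameter(noisy_tube):
    graph = noisy_tube["graph"]
    e = graph.edges[0]
    idx = len(e.points) // 2
    lm = Landmark("on_point", tuple(e.points[idx]), snap_radius=1.0)
    assert measure_diameter_at(graph, lm) == 2.0 * e.radii[idx]


def test_far_landmark_raises_miss_error_naming_distance(noisy_tube):
    lm = Landmark("far", (1e5, 1e5, 1e5), snap_radius=1000.0)
    with pytest.raises(LandmarkMissError, match="snap radius"):
        measure_diameter_at(noisy_tube["graph"], lm)


def test_snap_tie_break_is_deterministic(noisy_tube):
    graph = noisy_tube["graph"]
    lm = Landmark("mid", tuple(graph.edges[0].points[10]), snap_radius=100.0)
    s1 = snap_landmark(graph, lm)
    s2 = snap_landmark(graph, lm)
    assert (s1.edge_id, s1.point_index) == (s2.edge_id, s2.point_index)


# -- segment extraction -----------------------------------------------------


def test_two_arm_segment_has_requested_total_length(long_tube):
    """Anchor mid-tube with 500 + 800 um arms: total length within one step."""
    truth = long_tube["truth"]
    axis = truth.tubes[0].curve
    anchor = Landmark("anchor", axis.point(900)[0], 150.0)
    arm_a = Landmark("endA", axis.point(0)[0], 150.0)
    arm_b = Landmark("endB", axis.point(1800)[0], 150.0)
    seg = extract_segment(long_tube["graph"], anchor, [(arm_a, 500.0), (arm_b, 800.0)])
    step = min(long_tube["grid"].spacing)
    assert seg.total_length == pytest.approx(1300.0, abs=step)
    assert not seg.truncated
    assert set(seg.arm_volumes) == {"endA", "endB"}


def test_zero_length_arm_gives_anchor_only(long_tube):
    truth = long_tube["truth"]
    axis = truth.tubes[0].curve
    anchor = Landmark("anchor", axis.point(900)[0], 150.0)
    direction = Landmark("endB", axis.point(1800)[0], 150.0)
    seg = extract_segment(long_tube["graph"], anchor, [(direction, 0.0)])
    assert len(seg.arms[0].points) == 1
    assert seg.total_length == 0.0


def test_truncation_is_flagged_when_vessel_ends_early(long_tube):
    truth = long_tube["truth"]
    axis = truth.tubes[0].curve
    anchor = Landmark("anchor", axis.point(900)[0], 150.0)
    direction = Landmark("endB", axis.point(1800)[0], 150.0)
    seg = extract_segment(long_tube["graph"], anchor, [(direction, 5000.0)])
    assert seg.truncated
    assert seg.arms[0].achieved_length < 5000.0


def test_y_phantom_arm_follows_requested_branch(y_phantom):
    """From the junction toward branch 2, every path point lies on branch 2."""
    truth = y_phantom["truth"]
    junction = truth.extras["junction"]
    b2 = truth.tubes[2].curve  # second branch
    anchor = Landmark("junction", tuple(junction), snap_radius=60.0)
    target = Landmark("b2_end", b2.point(b2.length * 0.9)[0], snap_radius=60.0)
    seg = extract_segment(y_phantom["graph"], anchor, [(target, 200.0)])
    pts = seg.arms[0].points
    # distance of each point to the branch-2 axis segment
    d0, d1 = b2.p0, b2.p1
    u = (d1 - d0) / np.linalg.norm(d1 - d0)
    rel = pts - d0
    proj = np.clip(rel @ u, 0, np.linalg.norm(d1 - d0))
    dist = np.linalg.norm(rel - proj[:, None] * u, axis=1)
    assert dist.max() <= 2 * min(y_phantom["grid"].spacing)


def test_ambiguous_route_demands_waypoint():
    """Two mirror-symmetric equal-length routes between anchor and target."""
    top = np.array([[0.0, 0, 0], [1, 1, 0], [3, 1, 0], [4, 0, 0]])
    bottom = np.array([[0.0, 0, 0], [1, -1, 0], [3, -1, 0], [4, 0, 0]])
    stub_a = np.array([[-2.0, 0, 0], [0.0, 0, 0]])
    stub_b = np.array([[4.0, 0, 0], [6.0, 0, 0]])
    nodes = {
        0: GraphNode(0, np.array([0.0, 0, 0]), 3),
        1: GraphNode(1, np.array([4.0, 0, 0]), 3),
        2: GraphNode(2, np.array([-2.0, 0, 0]), 1),
        3: GraphNode(3, np.array([6.0, 0, 0]), 1),
    }
    edges = [
        GraphEdge(0, 0, 1, top, np.ones(4)),
        GraphEdge(1, 0, 1, bottom, np.ones(4)),
        GraphEdge(2, 2, 0, stub_a, np.ones(2)),
        GraphEdge(3, 1, 3, stub_b, np.ones(2)),
    ]
    g = SpatialGraph(nodes, edges, (1.0, 1.0, 1.0), "mm")
    anchor = Landmark("a", (-2.0, 0, 0), 0.5)
    target = Landmark("t", (6.0, 0, 0), 0.5)
    with pytest.raises(AmbiguousRouteError, match="waypoint"):
        extract_segment(g, anchor, [(target, 8.0)], step=0.5)


# -- cylindrical volumes ----------------------------------------------------


def test_cylinder_volume_identity_machine_precision():
    """Constant radius 0.1 mm over 3.5 mm: volume = pi r^2 L in ul."""
    seg = _straight_segment(radius=0.1, length=3.5, step=0.01, unit="mm")
    expected = np.pi * 0.1**2 * 3.5
    assert segment_volume(seg) == pytest.approx(expected, rel=1e-12)


def test_subsegment_rows_satisfy_cylinder_identity():
    seg = _straight_segment(radius=0.2, length=2.0, step=0.05, unit="mm")
    t = seg.subsegments
    np.testing.assert_allclose(
        t["volume_ul"], np.pi * t["radius"] ** 2 * t["length"], rtol=1e-14
    )


@pytest.mark.parametrize("k", [0.5, 0.8, 1.0, 1.7])
def test_quadratic_volume_scaling_in_radius(k):
    """Scaling all radii by k scales the volume by exactly k^2 — diameter
    enters volumetry squared, the sensitivity advantage of the method."""
    rng = np.random.default_rng(4)
    radii = rng.uniform(0.05, 0.15, size=71)
    base = _straight_segment(0.1, 3.5, 0.05, radii=radii)
    scaled = _straight_segment(0.1, 3.5, 0.05, radii=k * radii)
    assert segment_volume(scaled) == pytest.approx(k**2 * segment_volume(base), rel=1e-12)


def test_volume_additivity_under_split():
    rng = np.random.default_rng(8)
    radii = rng.uniform(0.05, 0.15, size=101)
    whole = _straight_segment(0.1, 5.0, 0.05, radii=radii)
    for cut in (20, 50, 77):
        left = _straight_segment(0.1, cut * 0.05, 0.05, radii=radii[: cut + 1])
        right = _straight_segment(0.1, 5.0 - cut * 0.05, 0.05, radii=radii[cut:])
        total = segment_volume(left) + segment_volume(right)
        assert total == pytest.approx(segment_volume(whole), rel=1e-9)


def test_stenotic_profile_volume_matches_quadrature():
    """Radius 60 um tapering to 48 um over 0.5 mm in a 3.5 mm segment:
    subsegment sum matches the integral of pi r(s)^2 ds within 2%."""
    profile = vv.FocalStenosis(radius=60.0, fraction=0.2, center=1750.0, width=250.0, taper=125.0)
    step = 15.0
    n = int(3500 / step) + 1
    s = np.linspace(0, 3500.0, n)
    seg = _straight_segment(60.0, 3500.0, step, unit="um", radii=profile(s))
    oracle, _ = quad(lambda t: np.pi * float(profile(t)[0]) ** 2, 0, 3500.0, limit=200)
    assert segment_volume(seg) == pytest.approx(oracle * 1e-9, rel=0.02)


def test_volume_per_length_of_clinical_scale_cylinder():
    """An M1-scale cylinder of radius 0.67 mm yields ~1.41 ul/mm."""
    seg = _straight_segment(radius=0.67, length=10.0, step=0.1, unit="mm")
    assert volume_per_length(seg) == pytest.approx(np.pi * 0.67**2, rel=1e-9)


def test_volume_per_length_is_intensive():
    long = _straight_segment(0.3, 8.0, 0.1)
    short = _straight_segment(0.3, 4.0, 0.1)
    assert volume_per_length(long) == pytest.approx(volume_per_length(short), rel=1e-9)


def test_stenotic_volume_per_length_bounded_by_extreme_areas():
    profile = vv.FocalStenosis(radius=60.0, fraction=0.3, center=500.0, width=300.0, taper=100.0)
    step = 10.0
    s = np.arange(0, 1001.0, step)
    seg = _straight_segment(60.0, 1000.0, step, unit="um", radii=profile(s))
    vpl = volume_per_length(seg)  # ul per mm
    a_max = np.pi * 60.0**2 * 1e-9 * 1e3  # ul/mm at full radius
    a_min = np.pi * 42.0**2 * 1e-9 * 1e3
    assert a_min < vpl < a_max


def test_empty_subsegment_table_is_error():
    seg = VesselSegment("anchor", np.zeros(3), [], 1.0, "mm")
    with pytest.raises(DataError):
        segment_volume(seg)


# -- export -----------------------------------------------------------------


def test_export_csv_and_vtk_are_consistent(long_tube, tmp_path):
    truth = long_tube["truth"]
    axis = truth.tubes[0].curve
    anchor = Landmark("anchor", axis.point(900)[0], 150.0)
    arm_a = Landmark("endA", axis.point(0)[0], 150.0)
    arm_b = Landmark("endB", axis.point(1800)[0], 150.0)
    seg = extract_segment(long_tube["graph"], anchor, [(arm_a, 500.0), (arm_b, 800.0)])
    vtk_path = tmp_path / "seg.vtk"
    csv_path = tmp_path / "seg.csv"
    table = export_colorcoded(seg, vtk_path=vtk_path, csv_path=csv_path)

    assert len(table) == len(seg.path)  # one CSV row per resampled point
    assert table["subsegment_volume_ul"].sum() == pytest.approx(segment_volume(seg), abs=0.0)

    from vesselvol.vtkio import read_vtk_polylines

    pts, lines, scalars = read_vtk_polylines(vtk_path)
    np.testing.assert_allclose(scalars["diameter"], table["diameter"], rtol=1e-6)
    np.testing.assert_allclose(pts, seg.path, rtol=1e-6)

    import pandas as pd

    on_disk = pd.read_csv(csv_path)
    assert len(on_disk) == len(table)
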