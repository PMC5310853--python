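"""Centerline extraction: skeleton, spatial graph, and per-point radii.

A binary vessel mask is thinned to a unit-width, topology-preserving
skeleton; skeleton voxels with exactly two 26-neighbors form edge chains,
all others (endpoints, branch voxels, isolated voxels) become nodes.
Adjacent branch voxels are merged into a single node at their centroid so
a bifurcation is one node regardless of how the thinning resolved it.
Cycles (e.g. the circle of Willis) are first-class: a closed loop with no
branch voxel is represented as a single cyclic edge anchored at a
deterministic synthetic node.

Per-point radii are inscribed-sphere radii: the anisotropy-aware Euclidean
distance transform of the mask (distance to the nearest background voxel,
in physical units) sampled at each chain point. Anisotropic spacing is
handled by a physically-scaled EDT, never by resampling the image.

Chain coordinates are lightly smoothed (moving average, endpoints pinned)
before any arc-length use: raw voxel-center polylines overestimate curve
length by ~5% through staircase steps, while the smoothed chains of a
digitized ring recover the true circumference to ~0.1%.
"""

from __future__ import annotations

import copy
import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import DataError
from .grid import BinaryMask
from .segmentation import STRUCT_26

_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=int
)


@dataclass
class GraphNode:
    id: int
    position: np.ndarray  # physical (x, y, z)
    degree: int


@dataclass
class GraphEdge:
    """An ordered centerline chain between two nodes (possibly the same)."""

    id: int
    node_a: int
    node_b: int
    points: np.ndarray  # (N, 3) physical coordinates
    radii: np.ndarray | None = None  # (N,) physical radii, set by estimate_radii

    @property
    def length(self) -> float:
        """Polyline arc length in physical units."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def is_cycle(self) -> bool:
        return self.node_a == self.node_b


@dataclass
class SpatialGraph:
    """Centerline graph with physical coordinates and per-point radii."""

    nodes: dict[int, GraphNode]
    edges: list[GraphEdge]
    spacing: tuple[float, float, float]
    unit: str
    provenance: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges))

    @property
    def has_radii(self) -> bool:
        return all(e.radii is not None for e in self.edges)

    def endpoints(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.degree == 1]

    def branch_nodes(self) -> list[int]:
        return [n.id for n in self.nodes.values() if n.degree >= 3]

    def cycle_count(self) -> int:
        """Number of independent cycles (first Betti number)."""
        import networkx as nx

        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, key=e.id)
        n_components = nx.number_connected_components(g) if g.number_of_nodes() else 0
        return g.number_of_edges() - g.number_of_nodes() + n_components

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "unit": self.unit,
            "spacing": list(self.spacing),
            "provenance": self.provenance,
            "nodes": [
                {"id": n.id, "position": list(map(float, n.position)), "degree": n.degree}
                for n in self.nodes.values()
            ],
            "edges": [
                {
                    "id": e.id,
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "points": np.asarray(e.points).tolist(),
                    "radii": None if e.radii is None else np.asarray(e.radii).tolist(),
                }
                for e in self.edges
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SpatialGraph":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        nodes = {
            n["id"]: GraphNode(n["id"], np.asarray(n["position"], float), n["degree"])
            for n in doc["nodes"]
        }
        edges = [
            GraphEdge(
                e["id"],
                e["node_a"],
                e["node_b"],
                np.asarray(e["points"], float),
                None if e["radii"] is None else np.asarray(e["radii"], float),
            )
            for e in doc["edges"]
        ]
        return cls(nodes, edges, tuple(doc["spacing"]), doc["unit"], doc.get("provenance", {}))

    def to_vtk(self, path) -> None:
        """Write all edge chains as VTK legacy polylines with a point scalar
        "radius" (zeros when radii are not yet estimated)."""
        from .vtkio import write_vtk_polylines

        points, lines, radii = [], [], []
        for e in self.edges:
            start = len(points)
            points.extend(np.asarray(e.points, float))
            r = e.radii if e.radii is not None else np.zeros(len(e.points))
            radii.extend(np.asarray(r, float))
            lines.append(list(range(start, start + len(e.points))))
        write_vtk_polylines(path, np.asarray(points), lines, {"radius": np.asarray(radii)})


# -- skeletonization --------------------------------------------------------


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin a mask to a unit-width skeleton, preserving topology.

    Uses 3D topology-preserving iterative thinning (simple-point removal):
    the skeleton is a subset of the foreground, keeps the 26-connected
    component count, and introduces no cavities.
    """
    if not mask.data.any():
        raise DataError("cannot skeletonize an empty mask")
    sk = _sk_skeletonize(mask.data)
    # Highly symmetric objects (even-width tubes centered between voxel
    # rows) can be eroded away entirely by simple-point thinning. Guarantee
    # component-count preservation: any foreground component left without a
    # skeleton voxel contributes its deepest (max-EDT) voxel instead.
    labels, n = ndi.label(mask.data, structure=STRUCT_26)
    if n > 0:
        have = np.zeros(n + 1, dtype=bool)
        have[np.unique(labels[sk])] = True
        missing = [c for c in range(1, n + 1) if not have[c]]
        if missing:
            edt = ndi.distance_transform_edt(mask.data, sampling=mask.spacing)
            for c in missing:
                comp = labels == c
                vals = np.where(comp, edt, -1.0)
                sk[np.unravel_index(np.argmax(vals), vals.shape)] = True
    return BinaryMask.like(mask, sk)


# -- graph construction -----------------------------------------------------


def build_graph(skeleton: BinaryMask, smooth_window: int = 5) -> SpatialGraph:
    """Convert a unit-width skeleton into a :class:`SpatialGraph`.

    Voxels with exactly 2 skeleton 26-neighbors form edge chains; all other
    skeleton voxels are node voxels. 26-adjacent node voxels are merged
    into one node placed at their centroid. Chains of a closed loop with no
    node voxel are anchored at the lexicographically smallest loop voxel
    (deterministic synthetic node of degree 2). Disconnected skeletons
    yield a multi-component graph with a warning.
    """
    sk = skeleton.data
    if not sk.any():
        raise DataError("empty skeleton")
    ncount = ndi.convolve(sk.astype(np.uint8), STRUCT_26.astype(np.uint8), mode="constant")
    ncount = (ncount - 1) * sk  # neighbor count (kernel includes center)

    node_vox_mask = sk & (ncount != 2)
    chain_vox_mask = sk & (ncount == 2)
    chain_set = set(map(tuple, np.argwhere(chain_vox_mask)))

    # cluster node voxels (26-connected) into graph nodes
    labels, n_clusters = ndi.label(node_vox_mask, structure=STRUCT_26)
    cluster_of: dict[tuple, int] = {}
    cluster_voxels: dict[int, list[tuple]] = {}
    for vox in map(tuple, np.argwhere(node_vox_mask)):
        cid = int(labels[vox])
        cluster_of[vox] = cid
        cluster_voxels.setdefault(cid, []).append(vox)
    # deterministic node ids ordered by lexicographically smallest member voxel
    order = sorted(cluster_voxels, key=lambda c: min(cluster_voxels[c]))
    node_id_of_cluster = {cid: i for i, cid in enumerate(order)}

    spacing = np.asarray(skeleton.spacing)
    origin = np.asarray(skeleton.origin)

    def phys(vox_list):
        return origin + np.asarray(vox_list, float) * spacing

    def neighbors(vox):
        for off in _OFFSETS:
            q = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if 0 <= q[0] < sk.shape[0] and 0 <= q[1] < sk.shape[1] and 0 <= q[2] < sk.shape[2]:
                if sk[q]:
                    yield q

    visited: set[tuple] = set()
    raw_edges: list[tuple[int, int, list[tuple], bool]] = []  # (na, nb, voxel path, cyclic)

    # chains emanating from node clusters
    for cid in order:
        for member in sorted(cluster_voxels[cid]):
            for start in sorted(n for n in neighbors(member) if n in chain_set):
                if start in visited:
                    continue
                path = [member, start]
                visited.add(start)
                prev, cur = member, start
                end_cluster = None
                while True:
                    nxt = [q for q in neighbors(cur) if q != prev]
                    # a chain voxel has exactly 2 skeleton neighbors
                    if not nxt:
                        break  # degenerate: open end without an endpoint voxel
                    nxt = nxt[0]
                    path.append(nxt)
                    if nxt in cluster_of:
                        end_cluster = cluster_of[nxt]
                        break
                    visited.add(nxt)
                    prev, cur = cur, nxt
                nb = node_id_of_cluster[end_cluster] if end_cluster is not None else None
                if nb is None:  # treat the dangling end as part of this chain's own node
                    nb = node_id_of_cluster[cid]
                raw_edges.append((node_id_of_cluster[cid], nb, path, False))

    # direct cluster-to-cluster adjacency with no chain voxel in between
    seen_pairs = set()
    for cid in order:
        for member in sorted(cluster_voxels[cid]):
            for q in neighbors(member):
                if q in cluster_of and cluster_of[q] != cid:
                    key = tuple(sorted((member, q)))
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    raw_edges.append(
                        (node_id_of_cluster[cid], node_id_of_cluster[cluster_of[q]], [member, q], False)
                    )

    # pure cycles: chains never reached from any node
    next_node_id = len(order)
    remaining = sorted(chain_set - visited)
    while remaining:
        anchor = remaining[0]
        path = [anchor]
        visited.add(anchor)
        prev, cur = anchor, sorted(neighbors(anchor))[0]
        while cur != anchor:
            path.append(cur)
            visited.add(cur)
            nxt = [q for q in neighbors(cur) if q != prev][0]
            prev, cur = cur, nxt
        path.append(anchor)  # close the loop
        raw_edges.append((next_node_id, next_node_id, path, True))
        cluster_voxels[-next_node_id - 1] = [anchor]
        node_id_of_cluster[-next_node_id - 1] = next_node_id
        next_node_id += 1
        remaining = sorted(chain_set - visited)

    # assemble nodes
    nodes: dict[int, GraphNode] = {}
    for cid, nid in node_id_of_cluster.items():
        pos = phys(cluster_voxels[cid]).mean(axis=0)
        nodes[nid] = GraphNode(nid, pos, 0)

    edges: list[GraphEdge] = []
    for eid, (na, nb, path, cyclic) in enumerate(raw_edges):
        pts = phys(path)
        pts = _smooth_chain(pts, smooth_window, cyclic)
        edges.append(GraphEdge(eid, na, nb, pts))
        nodes[na].degree += 1
        nodes[nb].degree += 1

    graph = SpatialGraph(
        nodes,
        edges,
        tuple(skeleton.spacing),
        skeleton.unit,
        provenance={"source": "build_graph", "spacing": list(skeleton.spacing)},
    )
    n_components = ndi.label(sk, structure=STRUCT_26)[1]
    if n_components > 1:
        warnings.warn(
            f"skeleton has {n_components} connected components; graph is multi-component",
            stacklevel=2,
        )
    return graph


def _smooth_chain(points: np.ndarray, window: int, cyclic: bool) -> np.ndarray:
    """Moving-average smoothing of chain coordinates.

    Open chains keep their endpoints and shrink the window near them;
    cyclic chains (first point == last) are smoothed circularly.
    """
    if window <= 1 or len(points) < 3:
        return points
    half = window // 2
    if cyclic:
        core = points[:-1]
        sm = np.stack(
            [ndi.uniform_filter1d(core[:, i], window, mode="wrap") for i in range(3)], axis=1
        )
        return np.vstack([sm, sm[:1]])
    out = points.astype(float).copy()
    n = len(points)
    for i in range(1, n - 1):
        h = min(half, i, n - 1 - i)
        out[i] = points[i - h : i + h + 1].mean(axis=0)
    return out


# -- radii ------------------------------------------------------------------


def estimate_radii(
    graph: SpatialGraph, mask: BinaryMask, boundary_offset_voxels: float = 0.0
) -> SpatialGraph:
    """Attach inscribed-sphere radii to every chain point.

    The radius at a chain point is the anisotropy-aware Euclidean distance
    transform of `mask` (distance to the nearest background voxel center,
    in physical units) sampled at the nearest voxel. `boundary_offset_voxels`
    adds a constant offset in units of the mean voxel spacing for users who
    prefer a half-voxel boundary convention; the default of 0 is the
    convention under which occupancy-0.5 voxelized tubes are recovered with
    sub-half-voxel bias. Points falling outside the mask foreground get
    radius 0 with a warning.
    """
    edt = ndi.distance_transform_edt(mask.data, sampling=mask.spacing)
    offset = boundary_offset_voxels * float(np.mean(mask.spacing))
    out = copy.deepcopy(graph)
    n_outside = 0
    shape = mask.data.shape
    for e in out.edges:
        idx = np.rint(mask.physical_to_index(e.points)).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        inside = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        r = edt[idx[:, 0], idx[:, 1], idx[:, 2]]
        r = np.where(inside, r + offset, 0.0)
        n_outside += int((~inside).sum())
        e.radii = r
    if n_outside:
        warnings.warn(
            f"{n_outside} chain points fall outside the mask foreground; radius set to 0",
            stacklevel=2,
        )
    return out


# -- pruning ----------------------------------------------------------------


def prune_spurs(
    graph: SpatialGraph, min_length: float, radius_factor: float = 2.0
) -> SpatialGraph:
    """Remove short terminal spurs (thinning artifacts), iterated to fixpoint.

    A terminal edge (free end of degree 1, junction end of degree >= 3) is
    removed when its arc length is below `min_length` and — when radii are
    available — below ``radius_factor`` times the radius at its junction
    end, so genuine short branches thicker than the trunk's scale survive.
    Edges on cycles are never terminal and are never removed. Junction
    nodes left with degree 2 are dissolved by merging their two chains.
    """
    if min_length < 0:
        raise DataError("min_length must be >= 0")
    g = copy.deepcopy(graph)
    changed = True
    while changed:
        changed = False
        for e in list(g.edges):
            if e.is_cycle:
                continue
            deg_a, deg_b = g.nodes[e.node_a].degree, g.nodes[e.node_b].degree
            if {deg_a, deg_b} >= {1} and (deg_a == 1) != (deg_b == 1):
                junction = e.node_b if deg_a == 1 else e.node_a
                if g.nodes[junction].degree < 3:
                    continue
                if e.length >= min_length:
                    continue
                if e.radii is not None:
                    j_radius = e.radii[-1] if junction == e.node_b else e.radii[0]
                    if e.length >= radius_factor * j_radius:
                        continue
                _remove_edge(g, e)
                changed = True
        if _dissolve_degree2_nodes(g):
            changed = True
    return g


def _remove_edge(g: SpatialGraph, e: GraphEdge) -> None:
    g.edges.remove(e)
    g.nodes[e.node_a].degree -= 1
    g.nodes[e.node_b].degree -= 1
    for nid in {e.node_a, e.node_b}:
        if g.nodes[nid].degree == 0:
            del g.nodes[nid]


def _dissolve_degree2_nodes(g: SpatialGraph) -> bool:
    """Merge the two chains at any degree-2 node that is not a cycle anchor."""
    merged_any = False
    for nid in [n.id for n in g.nodes.values() if n.degree == 2]:
        incident = [e for e in g.edges if nid in (e.node_a, e.node_b)]
        if len(incident) != 2:  # self-loop anchor: keep
            continue
        e1, e2 = incident
        p1, r1 = _oriented(e1, end_at=nid)
        p2, r2 = _oriented(e2, start_at=nid)
        points = np.vstack([p1, p2])
        radii = None if (r1 is None or r2 is None) else np.concatenate([r1, r2])
        na = e1.node_a if e1.node_b == nid else e1.node_b
        nb = e2.node_b if e2.node_a == nid else e2.node_a
        new = GraphEdge(min(e1.id, e2.id), na, nb, points, radii)
        g.edges.remove(e1)
        g.edges.remove(e2)
        g.edges.append(new)
        del g.nodes[nid]
        merged_any = True
    g.edges.sort(key=lambda e: e.id)
    return merged_any


def _oriented(e: GraphEdge, end_at: int | None = None, start_at: int | None = None):
    flip = (end_at is not None and e.node_b != end_at) or (
        start_at is not None and e.node_a != start_at
    )
    if flip:
        return e.points[::-1], None if e.radii is None else e.radii[::-1]
    return e.points, e.radii


# -- resampling -------------------------------------------------------------


def resample_chain(points: np.ndarray, radii: np.ndarray | None, step: float):
    """Resample a chain at equal arc-length intervals along its polyline.

    Returns points at arc positions 0, step, 2*step, ... plus the original
    final point (so the full length is always covered; the last interval
    may be shorter than `step`). Radii are linearly interpolated in arc
    length. A chain shorter than one step reduces to its two end points.
    """
    if step <= 0:
        raise DataError("resampling step must be > 0")
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= step:
        targets = np.array([0.0, total])
    else:
        targets = np.arange(0.0, total, step)
        if total - targets[-1] > 1e-9 * max(total, 1.0):
            targets = np.append(targets, total)
        else:
            targets[-1] = total
    new_pts = np.stack([np.interp(targets, s, points[:, i]) for i in range(3)], axis=1)
    new_radii = None if radii is None else np.interp(targets, s, np.asarray(radii, float))
    return new_pts, new_radii
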