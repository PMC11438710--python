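"""Domain types for the river network and the land-cover mosaic.

A river network is a set of attributed polyline *segments* ("sequences" in
the river-management sense: the atomic stretch of channel that carries one
set of condition attributes and receives one restoration-priority score).
Segments are stitched into a graph by unifying their endpoints within a
snapping tolerance; along-network distances are then shortest paths over
that graph with segment lengths as edge weights.

All geometry is planar with coordinates in meters. Geographic (lon/lat)
input is rejected at the I/O layer rather than silently reprojected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from ._util import UnionFind

#: canonical attribute vocabularies
BARRIER_LEVELS = ("yes", "no", "unknown")
EC_LEVELS = ("natural", "semi_natural", "artificial", "unknown")
PRESENCE_LEVELS = ("present", "absent", "unknown")

#: the five land-cover classes of the mapping schema
LANDCOVER_CLASSES = ("EI", "Farmland", "Forest", "Settlement", "TI")

#: minimum mapping unit used during digitization, m^2
DEFAULT_MMU_M2 = 50.0


@dataclass
class RiverSegment:
    """One scored unit of the network.

    Attributes hold the four restoration criteria: ``barrier`` (does the
    sequence contain a fish-migration barrier), ``ec`` (ecomorphological
    condition of the riverbed, collapsed to natural / semi_natural /
    artificial), ``nps`` (national priority species present) and ``hdas``
    (high diversity of aquatic species). ``unknown`` is an explicit level,
    not a missing value. ``restored`` marks sequences already restored,
    which are excluded from scoring and reported as their own category.
    """

    id: str
    geometry: LineString
    state: str = ""
    barrier: str = "unknown"
    ec: str = "unknown"
    nps: str = "unknown"
    hdas: str = "unknown"
    restored: bool = False

    def __post_init__(self) -> None:
        if self.barrier not in BARRIER_LEVELS:
            raise ValueError(f"segment {self.id!r}: barrier={self.barrier!r} "
                             f"not in {BARRIER_LEVELS}")
        if self.ec not in EC_LEVELS:
            raise ValueError(f"segment {self.id!r}: ec={self.ec!r} not in {EC_LEVELS}")
        if self.nps not in PRESENCE_LEVELS:
            raise ValueError(f"segment {self.id!r}: nps={self.nps!r} "
                             f"not in {PRESENCE_LEVELS}")
        if self.hdas not in PRESENCE_LEVELS:
            raise ValueError(f"segment {self.id!r}: hdas={self.hdas!r} "
                             f"not in {PRESENCE_LEVELS}")

    @property
    def length_m(self) -> float:
        return self.geometry.length


@dataclass
class RiverNetwork:
    """Segments plus node topology for along-network distance queries.

    ``graph`` is an undirected multigraph whose nodes are unified endpoint
    clusters and whose edges carry ``length`` (m) and ``segment`` (id).
    ``seg_nodes`` maps each segment id to its (start, end) node ids.
    """

    segments: dict[str, RiverSegment]
    graph: nx.MultiGraph
    seg_nodes: dict[str, tuple[int, int]]
    node_coords: dict[int, tuple[float, float]] = field(default_factory=dict)
    snap_tol: float = 0.0

    @property
    def total_length_km(self) -> float:
        return sum(s.length_m for s in self.segments.values()) / 1000.0

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self.segments


def build_network(segments, snap_tol: float = 1.0) -> RiverNetwork:
    """Stitch segments into a :class:`RiverNetwork`.

    Endpoints are unified by single-linkage clustering at ``snap_tol``
    meters (``snap_tol=0`` means exact coordinate coincidence). The node
    partition is a connected-components computation and therefore does not
    depend on input order.

    Raises
    ------
    ValueError
        on a duplicate segment id or a zero-length geometry.
    """
    if snap_tol < 0:
        raise ValueError("snap_tol must be >= 0")
    seg_list = list(segments)
    by_id: dict[str, RiverSegment] = {}
    for seg in seg_list:
        if seg.id in by_id:
            raise ValueError(f"duplicate segment id {seg.id!r}")
        if seg.geometry.length <= 0:
            raise ValueError(f"segment {seg.id!r} has zero-length geometry")
        if not seg.geometry.is_simple:
            raise ValueError(f"segment {seg.id!r} geometry is self-intersecting")
        by_id[seg.id] = seg

    # endpoint array: 2 rows per segment (start, end)
    ends = np.empty((2 * len(seg_list), 2), dtype=float)
    for i, seg in enumerate(seg_list):
        coords = np.asarray(seg.geometry.coords)
        ends[2 * i] = coords[0]
        ends[2 * i + 1] = coords[-1]

    uf = UnionFind(len(ends))
    if len(ends):
        pts = shapely.points(ends)
        tree = STRtree(pts)
        left, right = tree.query(pts, predicate="dwithin", distance=snap_tol)
        for a, b in zip(left.tolist(), right.tolist()):
            if a < b:
                uf.union(a, b)

    # canonical node ids: rank of cluster's lexicographically smallest
    # mean coordinate, so ids are stable under input permutation
    groups = uf.groups()
    means = {root: tuple(ends[idx].mean(axis=0)) for root, idx in groups.items()}
    order = sorted(means, key=lambda r: means[r])
    node_of_root = {root: i for i, root in enumerate(order)}
    node_coords = {node_of_root[r]: means[r] for r in means}

    graph = nx.MultiGraph()
    graph.add_nodes_from(node_coords)
    seg_nodes: dict[str, tuple[int, int]] = {}
    for i, seg in enumerate(seg_list):
        u = node_of_root[uf.find(2 * i)]
        v = node_of_root[uf.find(2 * i + 1)]
        seg_nodes[seg.id] = (u, v)
        graph.add_edge(u, v, segment=seg.id, length=seg.length_m)

    return RiverNetwork(segments=by_id, graph=graph, seg_nodes=seg_nodes,
                        node_coords=node_coords, snap_tol=snap_tol)


@dataclass
class LandCoverPolygon:
    geometry: BaseGeometry
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in LANDCOVER_CLASSES:
            raise ValueError(f"unknown land-cover class {self.cls!r}; "
                             f"expected one of {LANDCOVER_CLASSES}")


@dataclass
class LandCoverMap:
    """A valid polygon mosaic; each polygon carries one of five classes."""

    polygons: list[LandCoverPolygon]
    epoch: str = ""
    _landscape_area_m2: float | None = None

    @property
    def landscape_area_m2(self) -> float:
        if self._landscape_area_m2 is None:
            self._landscape_area_m2 = shapely.union_all(
                [p.geometry for p in self.polygons]).area
        return self._landscape_area_m2

    def class_polygons(self, cls: str) -> list[BaseGeometry]:
        return [p.geometry for p in self.polygons if p.cls == cls]

    @property
    def classes(self) -> tuple[str, ...]:
        present = {p.cls for p in self.polygons}
        return tuple(c for c in LANDCOVER_CLASSES if c in present)


@dataclass(frozen=True)
class Violation:
    """One finding of the land-cover validator."""

    kind: str  # below_mmu | invalid_geometry | overlap
    indices: tuple[int, ...]
    detail: str


def validate_landcover(lc_map: LandCoverMap,
                       mmu_m2: float = DEFAULT_MMU_M2) -> list[Violation]:
    """Check a mosaic against the digitizing rules.

    Findings: polygons below the minimum mapping unit, invalid geometries,
    and pairs whose interiors overlap. Returns an empty list iff the map
    conforms; never raises.
    """
    if mmu_m2 <= 0:
        raise ValueError("mmu_m2 must be > 0")
    out: list[Violation] = []
    geoms = [p.geometry for p in lc_map.polygons]
    for i, p in enumerate(lc_map.polygons):
        if not p.geometry.is_valid:
            out.append(Violation("invalid_geometry", (i,),
                                 "polygon geometry is invalid"))
        elif p.geometry.area < mmu_m2:
            out.append(Violation(
                "below_mmu", (i,),
                f"area {p.geometry.area:.1f} m2 < MMU {mmu_m2:g} m2"))
    if geoms:
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        for a, b in zip(left.tolist(), right.tolist()):
            if a >= b:
                continue
            inter = geoms[a].intersection(geoms[b])
            if inter.area > 1e-9:
                out.append(Violation(
                    "overlap", (a, b),
                    f"interiors overlap by {inter.area:.1f} m2"))
    return out


@dataclass(frozen=True)
class Weights:
    """Nonnegative criterion weights; defaults give each criterion 25%."""

    w_barrier: float = 0.25
    w_ec: float = 0.25
    w_nps: float = 0.25
    w_hdas: float = 0.25

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValueError("weights must be nonnegative")
        if sum(vals) <= 0:
            raise ValueError("weights must not all be zero")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_barrier, self.w_ec, self.w_nps, self.w_hdas)


def midpoint(seg: RiverSegment) -> Point:
    return seg.geometry.interpolate(0.5, normalized=True)
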