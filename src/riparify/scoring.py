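"""The restoration-priority model.

Each river segment is scored on four criteria, each worth 0-2 points:

* barrier      — contains a fish-migration barrier: yes=2, no=0 (the barrier
                 criterion has no 1-point middle level)
* ec           — ecomorphological condition: natural=0, semi_natural=1,
                 artificial=2
* nps / hdas   — national priority species / high diversity of aquatic
                 species: present=0 (already valuable, protect rather than
                 restore), absent=1, absent-but-adjacent-to-a-flagged
                 sequence=2 (restoring next door extends habitat and
                 spawning grounds for the existing population)

"Adjacent" means within 500 m along the network by default, measured from
nearest point to nearest point over the node graph — the rationale is fish
migration, which follows the channel, not the crow's flight. A Euclidean
mode is available for sensitivity analysis.

The total score is the weighted mean of the points rescaled to 0-8 so that
equal weights reproduce the raw point sum; it is then binned into five
priority categories. Restored segments are never scored (category
``already_restored``); a segment with any unknown criterion gets category
``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from shapely.strtree import STRtree

from .network import RiverNetwork, RiverSegment, Weights

DEFAULT_MAX_DIST_M = 500.0

#: category labels in increasing priority order (the two non-score
#: categories first)
CATEGORIES = ("already_restored", "unknown", "very_low", "low",
              "moderate", "high", "very_high")
PRIORITY_CATEGORIES = ("very_low", "low", "moderate", "high", "very_high")

UNKNOWN = None  # sentinel for unknown points / scores


@dataclass(frozen=True)
class BinMap:
    """Ordered score intervals -> category labels.

    ``edges`` are the interior breakpoints between the five priority bins
    over [0, 8]; the first bin is closed on both sides, later bins are
    half-open (lo, hi]. Only the extremes of the scale are anchored by the
    model definition (8 -> very_high, 0-1 -> very_low); the middle
    breakpoints are configurable and default to 1, 3, 5, 7.
    """

    edges: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    labels: tuple[str, ...] = PRIORITY_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need one more label than interior edges")
        bounds = (0.0, *self.edges, 8.0)
        if any(a >= b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("bin edges must be strictly increasing in (0, 8)")
        if self.labels[0] != "very_low" or self.labels[-1] != "very_high":
            raise ValueError("bins must run from very_low to very_high")
        if self.edges[0] < 1.0:
            raise ValueError("very_low must cover at least [0, 1]")

    def category(self, score: float) -> str:
        if not 0.0 <= score <= 8.0:
            raise ValueError(f"score {score} outside [0, 8]")
        bounds = (0.0, *self.edges, 8.0)
        for lo, hi, label in zip(bounds, bounds[1:], self.labels):
            if score <= hi:  # first bin [0, e1], then (e_i, e_{i+1}]
                return label
        raise AssertionError("unreachable: bins partition [0, 8]")

    def intervals(self) -> list[tuple[float, float, str]]:
        bounds = (0.0, *self.edges, 8.0)
        return [(lo, hi, lab) for lo, hi, lab
                in zip(bounds, bounds[1:], self.labels)]


DEFAULT_BINS = BinMap()


@dataclass
class ScoredSegment:
    """A segment with per-criterion points, weighted score and category."""

    segment_id: str
    state: str
    length_m: float
    p_barrier: int | None
    p_ec: int | None
    p_nps: int | None
    p_hdas: int | None
    score: float | None
    category: str
    geometry: object = None  # original LineString, kept for buffers/output

    @property
    def points(self) -> tuple[int | None, ...]:
        return (self.p_barrier, self.p_ec, self.p_nps, self.p_hdas)


def score_barrier(seg: RiverSegment) -> int | None:
    """Barrier criterion: yes=2, no=0; no middle level."""
    return {"yes": 2, "no": 0, "unknown": UNKNOWN}[seg.barrier]


def score_ec(seg: RiverSegment) -> int | None:
    """Ecomorphological condition: natural=0, semi_natural=1, artificial=2."""
    return {"natural": 0, "semi_natural": 1,
            "artificial": 2, "unknown": UNKNOWN}[seg.ec]


def _network_distances_to_flagged(net: RiverNetwork, flag: str,
                                  cutoff: float) -> dict[int, float]:
    """Multi-source Dijkstra node distances to the nearest flagged segment.

    A flagged segment's own endpoints are sources at distance 0 (its
    nearest point to any segment sharing that node is the node itself).
    """
    sources = set()
    for seg in net.segments.values():
        if getattr(seg, flag) == "present":
            sources.update(net.seg_nodes[seg.id])
    if not sources:
        return {}
    return nx.multi_source_dijkstra_path_length(
        net.graph, sources, cutoff=cutoff, weight="length")


def flag_adjacency(net: RiverNetwork, flag: str,
                   max_dist: float = DEFAULT_MAX_DIST_M,
                   mode: str = "network") -> dict[str, bool]:
    """For every segment: is it within ``max_dist`` of a flagged segment?

    ``mode="network"`` measures along the channel network (shortest path
    over the node graph, segment lengths as weights, nearest point to
    nearest point); ``mode="euclidean"`` measures straight-line distance
    between geometries. Flagged segments themselves report True (distance
    0); presence dominates adjacency during scoring anyway.
    """
    if flag not in ("nps", "hdas"):
        raise ValueError("flag must be 'nps' or 'hdas'")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    segs = list(net.segments.values())
    flagged = [s for s in segs if getattr(s, flag) == "present"]
    if not flagged:
        return {s.id: False for s in segs}
    if mode == "network":
        dist = _network_distances_to_flagged(net, flag, cutoff=max_dist)
        out = {}
        for s in segs:
            u, v = net.seg_nodes[s.id]
            d = min(dist.get(u, float("inf")), dist.get(v, float("inf")))
            out[s.id] = d <= max_dist
        # a flagged segment is trivially adjacent to itself
        for s in flagged:
            out[s.id] = True
        return out
    if mode == "euclidean":
        tree = STRtree([s.geometry for s in flagged])
        return {s.id: len(tree.query(s.geometry, predicate="dwithin",
                                     distance=max_dist)) > 0
                for s in segs}
    raise ValueError(f"unknown adjacency mode {mode!r}")


def adjacent_to_flagged(seg: RiverSegment, net: RiverNetwork, flag: str,
                        max_dist: float = DEFAULT_MAX_DIST_M,
                        mode: str = "network") -> bool:
    """Single-segment adjacency query (see :func:`flag_adjacency`)."""
    if seg.id not in net:
        raise ValueError(f"segment {seg.id!r} is not part of the network")
    return flag_adjacency(net, flag, max_dist=max_dist, mode=mode)[seg.id]


def score_presence(seg: RiverSegment, net: RiverNetwork, flag: str,
                   max_dist: float = DEFAULT_MAX_DIST_M,
                   mode: str = "network",
                   _adjacent: bool | None = None) -> int | None:
    """Species criterion: present=0, absent+adjacent=2, absent alone=1."""
    value = getattr(seg, flag)
    if value == "unknown":
        return UNKNOWN
    if value == "present":
        return 0
    adj = (_adjacent if _adjacent is not None
           else adjacent_to_flagged(seg, net, flag, max_dist, mode))
    return 2 if adj else 1


def total_score(points, weights: Weights = Weights()) -> float | None:
    """Weighted score on the 0-8 scale.

    score = 4 * sum(w_i p_i) / sum(w_i): with equal weights this is exactly
    the raw point sum, and the 0-8 range is preserved for any weights.
    Returns unknown (None) if any criterion is unknown.
    """
    if any(p is UNKNOWN for p in points):
        return UNKNOWN
    w = weights.as_tuple()
    return 4.0 * sum(wi * pi for wi, pi in zip(w, points)) / sum(w)


def classify(seg: RiverSegment, score: float | None,
             bins: BinMap = DEFAULT_BINS) -> str:
    """Category with precedence: restored > unknown > score bin."""
    if seg.restored:
        return "already_restored"
    if score is UNKNOWN:
        return "unknown"
    return bins.category(score)


def score_segment(seg: RiverSegment, net: RiverNetwork,
                  weights: Weights = Weights(), bins: BinMap = DEFAULT_BINS,
                  max_dist: float = DEFAULT_MAX_DIST_M,
                  mode: str = "network",
                  _adj_nps: bool | None = None,
                  _adj_hdas: bool | None = None) -> ScoredSegment:
    """Score one segment. Restored segments get no points or score."""
    if seg.restored:
        return ScoredSegment(seg.id, seg.state, seg.length_m,
                             None, None, None, None, None,
                             "already_restored", geometry=seg.geometry)
    pts = (
        score_barrier(seg),
        score_ec(seg),
        score_presence(seg, net, "nps", max_dist, mode, _adjacent=_adj_nps),
        score_presence(seg, net, "hdas", max_dist, mode, _adjacent=_adj_hdas),
    )
    score = total_score(pts, weights)
    return ScoredSegment(seg.id, seg.state, seg.length_m, *pts, score,
                         classify(seg, score, bins), geometry=seg.geometry)


def score_network(net: RiverNetwork, weights: Weights = Weights(),
                  bins: BinMap = DEFAULT_BINS,
                  max_dist: float = DEFAULT_MAX_DIST_M,
                  mode: str = "network") -> list[ScoredSegment]:
    """Score every segment; adjacency is computed once per flag."""
    adj_nps = flag_adjacency(net, "nps", max_dist, mode)
    adj_hdas = flag_adjacency(net, "hdas", max_dist, mode)
    return [score_segment(s, net, weights, bins, max_dist, mode,
                          _adj_nps=adj_nps[s.id], _adj_hdas=adj_hdas[s.id])
            for s in net.segments.values()]
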