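"""Seeded generators for river networks and land-cover mosaics.

The generators emulate the structure the restoration model assumes: a
connected side-river network of attributed channel sequences inside a
drained agricultural plain, and an exhaustive five-class land-cover
mosaic. Defaults mirror the study conditions the model was built for: a
network of roughly 85 km split across ~200 sequences and three
administrative states; about 10% of sequences already restored; missing
connectivity (barrier) data on ~13% of sequences, which is what feeds the
"unknown" priority category; roughly half the channels in a non-natural
ecomorphological state; and a land-cover mixture dominated by farmland
with ~12% ecological infrastructure, as in a recent mapping epoch of a
channelized lowland plain.

One integer seed drives all randomness through a single numpy Generator;
identical specs and seeds give identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString

from .network import (LandCoverMap, LandCoverPolygon, RiverNetwork,
                      RiverSegment, build_network, LANDCOVER_CLASSES)
from .scoring import ScoredSegment


@dataclass
class NetworkSpec:
    """Parameters of the synthetic river network.

    ``p_unknown`` gives, per criterion attribute, the probability that the
    secondary data for a sequence are unavailable; the default puts all
    missingness on the barrier/connectivity data.
    """

    n_segments: int = 200
    segment_length_range_m: tuple[float, float] = (100.0, 800.0)
    branching_prob: float = 0.25
    p_barrier_yes: float = 0.35
    p_ec: tuple[float, float, float] = (0.2, 0.3, 0.5)  # natural/semi/artificial
    p_nps_present: float = 0.15
    p_hdas_present: float = 0.15
    p_restored: float = 0.10
    p_unknown: dict = field(default_factory=lambda: {
        "barrier": 0.13, "ec": 0.0, "nps": 0.0, "hdas": 0.0})
    n_states: int = 3
    mode: str = "tree"  # "tree" or "grid" (ditch-grid of a drained plain)
    seed: int = 0

    def validate(self) -> None:
        if self.n_segments <= 0:
            raise ValueError("n_segments must be >= 1")
        lo, hi = self.segment_length_range_m
        if not (0 < lo <= hi):
            raise ValueError("segment_length_range_m must be 0 < lo <= hi")
        probs = [self.branching_prob, self.p_barrier_yes, self.p_nps_present,
                 self.p_hdas_present, self.p_restored,
                 *self.p_unknown.values(), *self.p_ec]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.p_ec) - 1.0) > 1e-9:
            raise ValueError("p_ec must sum to 1")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.mode not in ("tree", "grid"):
            raise ValueError("mode must be 'tree' or 'grid'")


def _tree_geometry(spec: NetworkSpec, rng: np.random.Generator):
    """Random tree of polylines: each new segment grows from an existing
    node, branching sideways with probability ``branching_prob``."""
    lo, hi = spec.segment_length_range_m
    xs = [0.0]; ys = [0.0]; dirs = [0.0]
    lines = []
    tip = 0
    for _ in range(spec.n_segments):
        if len(lines) and rng.random() < spec.branching_prob:
            parent = int(rng.integers(len(xs)))
            ang = dirs[parent] + rng.uniform(-2.0, 2.0)
        else:
            parent = tip
            ang = dirs[parent] + rng.uniform(-0.5, 0.5)
        ln = rng.uniform(lo, hi)
        x = xs[parent] + ln * np.cos(ang)
        y = ys[parent] + ln * np.sin(ang)
        lines.append(LineString([(xs[parent], ys[parent]), (x, y)]))
        xs.append(x); ys.append(y); dirs.append(ang)
        tip = len(xs) - 1
    return lines


def _grid_geometry(spec: NetworkSpec):
    """Ditch grid: unit-spacing horizontal and vertical channel edges."""
    spacing = sum(spec.segment_length_range_m) / 2.0
    n = spec.n_segments
    side = int(np.ceil(np.sqrt(n / 2.0))) + 1
    lines = []
    for j in range(side):
        for i in range(side - 1):
            lines.append(LineString([(i * spacing, j * spacing),
                                     ((i + 1) * spacing, j * spacing)]))
    for j in range(side - 1):
        for i in range(side):
            lines.append(LineString([(i * spacing, j * spacing),
                                     (i * spacing, (j + 1) * spacing)]))
    # keep a connected prefix: sort by distance from origin
    lines.sort(key=lambda l: (l.centroid.x + l.centroid.y, l.centroid.x))
    return lines[:n]


def _draw_level(rng, p_unknown, levels, probs):
    if rng.random() < p_unknown:
        return "unknown"
    return levels[int(rng.choice(len(levels), p=probs))]


def make_network(spec: NetworkSpec = NetworkSpec()) -> RiverNetwork:
    """Generate a seeded synthetic river network."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "tree":
        lines = _tree_geometry(spec, rng)
    else:
        lines = _grid_geometry(spec)

    # states: contiguous bands by midpoint x-coordinate
    mids = np.array([l.interpolate(0.5, normalized=True).x for l in lines])
    qs = np.quantile(mids, np.linspace(0, 1, spec.n_states + 1)[1:-1]) \
        if spec.n_states > 1 else np.array([])
    state_idx = np.searchsorted(qs, mids, side="right")

    pn, pe = spec.p_nps_present, spec.p_ec
    segments = []
    for i, line in enumerate(lines):
        segments.append(RiverSegment(
            id=f"seg{i:05d}",
            geometry=line,
            state=f"state_{state_idx[i] + 1}",
            barrier=_draw_level(rng, spec.p_unknown.get("barrier", 0.0),
                                ("yes", "no"),
                                (spec.p_barrier_yes, 1 - spec.p_barrier_yes)),
            ec=_draw_level(rng, spec.p_unknown.get("ec", 0.0),
                           ("natural", "semi_natural", "artificial"), pe),
            nps=_draw_level(rng, spec.p_unknown.get("nps", 0.0),
                            ("present", "absent"), (pn, 1 - pn)),
            hdas=_draw_level(rng, spec.p_unknown.get("hdas", 0.0),
                             ("present", "absent"),
                             (spec.p_hdas_present, 1 - spec.p_hdas_present)),
            restored=bool(rng.random() < spec.p_restored),
        ))
    # endpoints coincide exactly by construction
    return build_network(segments, snap_tol=0.0)


@dataclass
class MosaicSpec:
    """Parameters of the synthetic land-cover mosaic.

    The mosaic is a full grid of square cells, one class per cell; the
    ``clustering`` parameter is the probability that a cell copies the
    class of an already-assigned neighbor instead of sampling from the
    mixture (copying preserves the marginal mixture while creating
    spatially coherent patches). The default mixture is a
    farmland-dominated riparian plain.
    """

    nx: int = 30
    ny: int = 20
    cell_size_m: float = 10.0
    mixture: dict = field(default_factory=lambda: {
        "Farmland": 0.690, "EI": 0.120, "TI": 0.087,
        "Settlement": 0.075, "Forest": 0.028})
    clustering: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dims must be >= 1")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        if set(self.mixture) - set(LANDCOVER_CLASSES):
            raise ValueError("mixture keys must be land-cover classes")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")
        if not 0 <= self.clustering <= 1:
            raise ValueError("clustering must lie in [0, 1]")


def make_mosaic(spec: MosaicSpec = MosaicSpec()) -> LandCoverMap:
    """Generate a seeded exhaustive grid mosaic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = [c for c in LANDCOVER_CLASSES if spec.mixture.get(c, 0) > 0]
    probs = np.array([spec.mixture[c] for c in classes])
    probs = probs / probs.sum()

    grid = np.empty((spec.ny, spec.nx), dtype=object)
    for j in range(spec.ny):
        for i in range(spec.nx):
            neighbors = []
            if i > 0:
                neighbors.append(grid[j, i - 1])
            if j > 0:
                neighbors.append(grid[j - 1, i])
            if neighbors and rng.random() < spec.clustering:
                grid[j, i] = neighbors[int(rng.integers(len(neighbors)))]
            else:
                grid[j, i] = classes[int(rng.choice(len(classes), p=probs))]

    s = spec.cell_size_m
    polys = [LandCoverPolygon(shapely.box(i * s, j * s, (i + 1) * s,
                                          (j + 1) * s), grid[j, i])
             for j in range(spec.ny) for i in range(spec.nx)]
    m = LandCoverMap(polygons=polys, epoch=f"synthetic-{spec.seed}")
    m._landscape_area_m2 = spec.nx * spec.ny * s * s
    return m


def make_worked_fixture() -> tuple[RiverNetwork, dict[str, ScoredSegment]]:
    """A hand-built 6-segment chain exercising every scoring branch.

    Layout along the x-axis (all segments share endpoints exactly):

    =====  ================  =========================================
    id     extent (m)        attributes
    =====  ================  =========================================
    hot    0-400             nps & hdas present, no barrier, natural
    worst  400-800           barrier, artificial, both species absent
                             (shares a node with ``hot`` -> adjacent)
    near   800-1000          barrier, semi-natural, absent; 400 m along
                             the network from ``hot`` -> adjacent
    far    1000-1800         no barrier, semi-natural, absent; 600 m
                             from ``hot`` -> not adjacent
    nodata 1800-2200         ec unknown -> category unknown
    done   2200-2600         restored -> already_restored
    =====  ================  =========================================

    Expected points, scores and categories are hand-computed from the
    criterion table and returned alongside the network.
    """
    def line(x0, x1):
        return LineString([(x0, 0.0), (x1, 0.0)])

    segs = [
        RiverSegment("hot", line(0, 400), state="Glarus", barrier="no",
                     ec="natural", nps="present", hdas="present"),
        RiverSegment("worst", line(400, 800), state="Glarus", barrier="yes",
                     ec="artificial", nps="absent", hdas="absent"),
        RiverSegment("near", line(800, 1000), state="Schwyz", barrier="yes",
                     ec="semi_natural", nps="absent", hdas="absent"),
        RiverSegment("far", line(1000, 1800), state="Schwyz", barrier="no",
                     ec="semi_natural", nps="absent", hdas="absent"),
        RiverSegment("nodata", line(1800, 2200), state="St. Gallen",
                     barrier="yes", ec="unknown", nps="absent",
                     hdas="absent"),
        RiverSegment("done", line(2200, 2600), state="St. Gallen",
                     barrier="yes", ec="artificial", nps="absent",
                     hdas="absent", restored=True),
    ]
    net = build_network(segs, snap_tol=0.0)
    expected = {
        "hot": ScoredSegment("hot", "Glarus", 400.0, 0, 0, 0, 0, 0.0,
                             "very_low"),
        "worst": ScoredSegment("worst", "Glarus", 400.0, 2, 2, 2, 2, 8.0,
                               "very_high"),
        "near": ScoredSegment("near", "Schwyz", 200.0, 2, 1, 2, 2, 7.0,
                              "high"),
        "far": ScoredSegment("far", "Schwyz", 800.0, 0, 1, 1, 1, 3.0,
                             "low"),
        "nodata": ScoredSegment("nodata", "St. Gallen", 400.0, 2, None, 1, 1,
                                None, "unknown"),
        "done": ScoredSegment("done", "St. Gallen", 400.0, None, None, None,
                              None, None, "already_restored"),
    }
    return net, expected
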