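"""GeoJSON / CSV input and output.

GeoJSON is the interchange format: it is plain text, round-trips the
attribute schema exactly, and needs no GIS runtime. Coordinates must be
planar meters; input whose bounding box fits inside lon/lat ranges is
rejected (rather than silently reprojected) unless the configuration sets
``assume_planar`` for legitimately small planar extents.
"""

from __future__ import annotations

import hashlib
import json
import logging

from shapely.geometry import LineString, mapping, shape

from .config import Config, DEFAULT_VALUE_MAP
from .network import LandCoverMap, LandCoverPolygon, RiverSegment
from .scoring import ScoredSegment

log = logging.getLogger("riparify")


def file_checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def _looks_geographic(features) -> bool:
    xs, ys = [], []
    for f in features:
        geom = shape(f["geometry"])
        x0, y0, x1, y1 = geom.bounds
        xs += [x0, x1]; ys += [y0, y1]
    if not xs:
        return False
    return (min(xs) >= -180 and max(xs) <= 180
            and min(ys) >= -90 and max(ys) <= 90)


def _normalize(attr: str, raw, value_map: dict) -> str:
    table = value_map["presence" if attr in ("nps", "hdas") else attr]
    key = str(raw).strip().lower() if raw is not None else ""
    if key in table:
        return table[key]
    log.warning("unmapped %s value %r -> unknown", attr, raw)
    return "unknown"


def _as_bool(raw) -> bool:
    return str(raw).strip().lower() in ("true", "yes", "1")


def read_network(path, config: Config | None = None) -> list[RiverSegment]:
    """Read river segments from a GeoJSON FeatureCollection.

    Attribute names follow ``config.attribute_map``; values are normalized
    to the canonical vocabulary, unmapped values becoming ``unknown`` with
    a logged warning.
    """
    config = config or Config()
    amap = config.attribute_map
    with open(path) as fh:
        data = json.load(fh)
    feats = data.get("features", [])
    if not config.assume_planar and _looks_geographic(feats):
        raise ValueError(
            f"{path}: coordinates look geographic (lon/lat); supply planar "
            "meters, or set assume_planar for a small planar extent")
    segments = []
    for i, f in enumerate(feats):
        geom = shape(f["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: feature {i} is not a LineString")
        props = f.get("properties") or {}
        segments.append(RiverSegment(
            id=str(props.get("id", f.get("id", i))),
            geometry=geom,
            state=str(props.get(amap["state"], "") or ""),
            barrier=_normalize("barrier", props.get(amap["barrier"]),
                               DEFAULT_VALUE_MAP),
            ec=_normalize("ec", props.get(amap["ec"]), DEFAULT_VALUE_MAP),
            nps=_normalize("nps", props.get(amap["nps"]), DEFAULT_VALUE_MAP),
            hdas=_normalize("hdas", props.get(amap["hdas"]),
                            DEFAULT_VALUE_MAP),
            restored=_as_bool(props.get(amap["restored"], False)),
        ))
    return segments


def write_network(path, segments: list[RiverSegment]) -> None:
    feats = []
    for s in segments:
        feats.append({"type": "Feature", "geometry": mapping(s.geometry),
                      "properties": {"id": s.id, "state": s.state,
                                     "barrier": s.barrier, "ec": s.ec,
                                     "nps": s.nps, "hdas": s.hdas,
                                     "restored": s.restored}})
    _dump(path, feats)


def read_landcover(path, epoch: str = "",
                   assume_planar: bool = False) -> LandCoverMap:
    """Read a land-cover mosaic from GeoJSON (``cls`` property per polygon)."""
    with open(path) as fh:
        data = json.load(fh)
    feats = data.get("features", [])
    if not assume_planar and _looks_geographic(feats):
        raise ValueError(f"{path}: coordinates look geographic (lon/lat)")
    polys = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        if "cls" not in props:
            raise ValueError(f"{path}: feature {i} lacks a 'cls' property")
        polys.append(LandCoverPolygon(shape(f["geometry"]), props["cls"]))
    return LandCoverMap(polygons=polys, epoch=epoch or str(path))


def write_landcover(path, lc_map: LandCoverMap) -> None:
    feats = [{"type": "Feature", "geometry": mapping(p.geometry),
              "properties": {"cls": p.cls}} for p in lc_map.polygons]
    _dump(path, feats)


def write_scored(path, scored: list[ScoredSegment]) -> None:
    """Write scored segments as GeoJSON; geometry passes through unchanged."""
    feats = []
    for s in scored:
        feats.append({
            "type": "Feature",
            "geometry": mapping(s.geometry) if s.geometry is not None else None,
            "properties": {
                "id": s.segment_id, "state": s.state,
                "length_m": s.length_m,
                "p_barrier": s.p_barrier, "p_ec": s.p_ec,
                "p_nps": s.p_nps, "p_hdas": s.p_hdas,
                "score": s.score, "category": s.category}})
    _dump(path, feats)


def read_scored(path) -> list[ScoredSegment]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for f in data.get("features", []):
        p = f["properties"]
        out.append(ScoredSegment(
            segment_id=p["id"], state=p["state"], length_m=p["length_m"],
            p_barrier=p["p_barrier"], p_ec=p["p_ec"], p_nps=p["p_nps"],
            p_hdas=p["p_hdas"], score=p["score"], category=p["category"],
            geometry=shape(f["geometry"]) if f.get("geometry") else None))
    return out


def _dump(path, features) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")


def rasterize_categories(scored: list[ScoredSegment], cell_size_m: float,
                         path, max_radius_m: float | None = None) -> None:
    """Export priority categories as an ESRI ASCII categorical grid.

    Each cell takes the category of the nearest scored segment within
    ``max_radius_m`` (default: the cell diagonal), coded 0-6 in category
    order; empty cells get NODATA (-1). Purely a visualization export —
    it adds no semantics beyond the vector result.
    """
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    from .scoring import CATEGORIES

    geoms = [s.geometry for s in scored if s.geometry is not None]
    cats = [s.category for s in scored if s.geometry is not None]
    if not geoms:
        raise ValueError("nothing to rasterize")
    if max_radius_m is None:
        max_radius_m = cell_size_m * 1.5
    x0 = min(g.bounds[0] for g in geoms) - cell_size_m
    y0 = min(g.bounds[1] for g in geoms) - cell_size_m
    x1 = max(g.bounds[2] for g in geoms) + cell_size_m
    y1 = max(g.bounds[3] for g in geoms) + cell_size_m
    ncols = max(1, int((x1 - x0) / cell_size_m) + 1)
    nrows = max(1, int((y1 - y0) / cell_size_m) + 1)
    tree = STRtree(geoms)
    code = {c: i for i, c in enumerate(CATEGORIES)}
    lines = [f"ncols {ncols}", f"nrows {nrows}",
             f"xllcorner {x0:.3f}", f"yllcorner {y0:.3f}",
             f"cellsize {cell_size_m:.3f}", "NODATA_value -1"]
    for r in range(nrows):
        cy = y1 - (r + 0.5) * cell_size_m
        row = []
        for c in range(ncols):
            pt = Point(x0 + (c + 0.5) * cell_size_m, cy)
            idx, dist = tree.query_nearest(pt, return_distance=True)
            if len(idx) and dist[0] <= max_radius_m:
                row.append(str(code[cats[int(idx[0])]]))
            else:
                row.append("-1")
        lines.append(" ".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
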