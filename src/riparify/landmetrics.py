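"""Class-level vector landscape metrics and epoch-to-epoch change tables.

Metrics are computed per land-cover class on *patches*: maximal groups of
contiguous same-class polygons after dissolution. All inputs are planar
meters; outputs use the conventional units:

* NP    — number of patches (count)
* MPS   — mean patch size, ha (sum of areas / NP / 10,000)
* ED    — edge density, m/ha (sum of patch perimeters / landscape area
          in m^2, x 10,000)
* MNND  — mean nearest-neighbor distance, m (edge-to-edge; undefined for
          a single patch)
* MSI   — mean shape index, dimensionless (perimeter over the perimeter of
          the equal-area circle, i.e. P / (2 sqrt(pi A)); 1 for a circle)

Contiguity for dissolution is "queen" by default: polygons sharing even a
single corner point merge into one patch (such a patch's geometry is a
MultiPolygon of point-touching parts). "rook" requires a shared edge of
positive length. Hole boundaries count toward perimeter — they are edges
of the patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.strtree import STRtree

from ._util import UnionFind, round_half_away
from .network import LandCoverMap, LANDCOVER_CLASSES


@dataclass
class Patch:
    """One maximal contiguous area of a single land-cover class."""

    cls: str
    geometry: Polygon | MultiPolygon
    area_m2: float
    perimeter_m: float

    @classmethod
    def from_geometry(cls_, cls: str, geom) -> "Patch":
        return cls_(cls=cls, geometry=geom, area_m2=geom.area,
                    perimeter_m=geom.length)


@dataclass
class MetricSet:
    """Per-class metric row for one map epoch."""

    cls: str
    epoch: str
    area_pct: float
    np: int
    mps_ha: float | None
    ed_m_per_ha: float
    mnnd_m: float | None
    msi: float | None


def dissolve_patches(lc_map: LandCoverMap, cls: str,
                     contiguity: str = "queen") -> list[Patch]:
    """Merge touching polygons of ``cls`` into maximal patches.

    ``contiguity="queen"`` merges on any boundary contact including a
    corner point; ``"rook"`` merges only on a shared edge of positive
    length. Returns an empty list when the class is absent. Holes are
    preserved.
    """
    geoms = lc_map.class_polygons(cls)
    if not geoms:
        return []
    if contiguity not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity {contiguity!r}")
    uf = UnionFind(len(geoms))
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    for a, b in zip(left.tolist(), right.tolist()):
        if a >= b:
            continue
        if contiguity == "rook":
            inter = geoms[a].intersection(geoms[b])
            if inter.length <= 0 and inter.area <= 0:
                continue
        uf.union(a, b)
    patches = []
    for idx in uf.groups().values():
        merged = shapely.union_all([geoms[i] for i in idx])
        patches.append(Patch.from_geometry(cls, merged))
    # deterministic order: by (min x, min y) of patch envelope
    patches.sort(key=lambda p: (p.geometry.bounds[0], p.geometry.bounds[1]))
    return patches


def metric_np(patches: list[Patch]) -> int:
    return len(patches)


def metric_mps(patches: list[Patch]) -> float | None:
    """Mean patch size in hectares; undefined (None) for no patches."""
    if not patches:
        return None
    return sum(p.area_m2 for p in patches) / len(patches) / 10_000.0


def metric_ed(patches: list[Patch], landscape_area_m2: float,
              landscape_boundary=None) -> float:
    """Edge density in m/ha.

    By default every patch perimeter counts in full, including stretches
    lying on the study-area boundary. Pass ``landscape_boundary`` (the
    boundary lines of the landscape polygon) to exclude those stretches
    instead — a sensitivity variant mirroring raster tools that do not
    count landscape-edge segments.
    """
    if landscape_area_m2 <= 0:
        raise ValueError("landscape_area_m2 must be > 0")
    total = 0.0
    for p in patches:
        perim = p.perimeter_m
        if landscape_boundary is not None:
            shared = p.geometry.boundary.intersection(landscape_boundary)
            perim -= shared.length
        total += perim
    return total / landscape_area_m2 * 10_000.0


def metric_mnnd(patches: list[Patch]) -> float | None:
    """Mean nearest-neighbor edge-to-edge distance in meters.

    Undefined (None) when fewer than two patches exist. Uses an STRtree
    nearest query; for point-touching queen patches the distance to the
    touching neighbor is 0.
    """
    if len(patches) < 2:
        return None
    geoms = [p.geometry for p in patches]
    tree = STRtree(geoms)
    total = 0.0
    for i, g in enumerate(geoms):
        idx, dist = tree.query_nearest(g, return_distance=True,
                                       exclusive=True)
        total += float(np.min(dist))
    return total / len(geoms)


def metric_msi(patches: list[Patch]) -> float | None:
    """Mean shape index against the circular standard; >= 1, 1 = circle."""
    if not patches:
        return None
    return float(np.mean([p.perimeter_m / (2.0 * np.sqrt(np.pi * p.area_m2))
                          for p in patches]))


def class_metrics(lc_map: LandCoverMap, cls: str,
                  contiguity: str = "queen",
                  exclude_boundary_edges: bool = False) -> MetricSet:
    """All class-level metrics for one class of one map epoch."""
    patches = dissolve_patches(lc_map, cls, contiguity=contiguity)
    area = sum(p.area_m2 for p in patches)
    boundary = None
    if exclude_boundary_edges:
        boundary = shapely.union_all(
            [p.geometry for p in lc_map.polygons]).boundary
    return MetricSet(
        cls=cls,
        epoch=lc_map.epoch,
        area_pct=100.0 * area / lc_map.landscape_area_m2,
        np=metric_np(patches),
        mps_ha=metric_mps(patches),
        ed_m_per_ha=metric_ed(patches, lc_map.landscape_area_m2, boundary),
        mnnd_m=metric_mnnd(patches),
        msi=metric_msi(patches),
    )


def metrics_table(maps: list[LandCoverMap], contiguity: str = "queen",
                  exclude_boundary_edges: bool = False) -> pd.DataFrame:
    """Metric rows for every class x epoch, in report column order."""
    rows = []
    for m in maps:
        for cls in LANDCOVER_CLASSES:
            if not m.class_polygons(cls):
                continue
            ms = class_metrics(m, cls, contiguity, exclude_boundary_edges)
            rows.append({"cls": ms.cls, "year": ms.epoch,
                         "area_pct": ms.area_pct, "MPS": ms.mps_ha,
                         "MSI": ms.msi, "NP": ms.np, "MNND": ms.mnnd_m,
                         "ED": ms.ed_m_per_ha})
    return pd.DataFrame(rows,
                        columns=["cls", "year", "area_pct", "MPS", "MSI",
                                 "NP", "MNND", "ED"])


def area_table(lc_map: LandCoverMap) -> pd.DataFrame:
    """Per-class area in km^2 and % of landscape, indexed by class."""
    rows = {}
    for cls in lc_map.classes:
        a = sum(g.area for g in lc_map.class_polygons(cls))
        rows[cls] = {"area_km2": a / 1e6,
                     "area_pct": 100.0 * a / lc_map.landscape_area_m2}
    return pd.DataFrame.from_dict(rows, orient="index")


def change_table(a, b) -> pd.DataFrame:
    """Per-class change between two epochs.

    ``a`` and ``b`` are :class:`LandCoverMap` objects or area tables as
    produced by :func:`area_table` (columns ``area_km2``, ``area_pct``).
    Returns ``d_area_km2`` (2 dp) and ``d_area_pct_points`` (1 dp),
    rounded half away from zero at the precision conventional for printed
    land-cover tables.
    """
    ta = area_table(a) if isinstance(a, LandCoverMap) else a
    tb = area_table(b) if isinstance(b, LandCoverMap) else b
    if set(ta.index) != set(tb.index):
        raise ValueError(
            f"class schemas differ: {sorted(ta.index)} vs {sorted(tb.index)}")
    tb = tb.loc[ta.index]
    out = pd.DataFrame(index=ta.index)
    out["d_area_km2"] = [
        round_half_away(d, 2) for d in tb["area_km2"] - ta["area_km2"]]
    out["d_area_pct_points"] = [
        round_half_away(d, 1) for d in tb["area_pct"] - ta["area_pct"]]
    return out
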