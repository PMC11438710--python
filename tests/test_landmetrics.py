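"""Vector landscape metrics and change tables."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box
from shapely import affinity

import riparify as rp


def lc(polys_with_cls, epoch="t"):
    return rp.LandCoverMap(
        polygons=[rp.LandCoverPolygon(g, c) for g, c in polys_with_cls],
        epoch=epoch)


def _floodfill_patch_count(cells, diagonal):
    """Oracle: connected components of grid cells (flood fill)."""
    cells = set(cells)
    steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if diagonal:
        steps += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    seen, count = set(), 0
    for c in cells:
        if c in seen:
            continue
        count += 1
        stack = [c]
        while stack:
            x, y = stack.pop()
            if (x, y) in seen:
                continue
            seen.add((x, y))
            stack += [(x + dx, y + dy) for dx, dy in steps
                      if (x + dx, y + dy) in cells]
    return count


class TestDissolve:
    def test_abutting_squares_merge(self):
        m = lc([(box(0, 0, 1, 1), "EI"), (box(1, 0, 2, 1), "EI")])
        patches = rp.dissolve_patches(m, "EI")
        assert len(patches) == 1
        assert patches[0].area_m2 == pytest.approx(2.0)

    def test_separated_squares_stay_apart(self):
        m = lc([(box(0, 0, 1, 1), "EI"), (box(2, 0, 3, 1), "EI")])
        assert len(rp.dissolve_patches(m, "EI")) == 2

    def test_absent_class_gives_empty_list(self, two_class_map):
        assert rp.dissolve_patches(two_class_map, "TI") == []

    @pytest.mark.parametrize("contiguity,diagonal", [("queen", True),
                                                     ("rook", False)])
    def test_checkerboard_matches_floodfill_oracle(self, contiguity,
                                                   diagonal):
        """Corner-touching cells merge under queen but not rook."""
        cells = [(i, j) for i in range(4) for j in range(4)
                 if (i + j) % 2 == 0]
        m = lc([(box(i, j, i + 1, j + 1), "Forest") for i, j in cells])
        got = len(rp.dissolve_patches(m, "Forest", contiguity=contiguity))
        assert got == _floodfill_patch_count(cells, diagonal)


class TestMetrics:
    def test_np_and_mps_unit_conversion(self):
        m = lc([(box(0, 0, 100, 100), "EI")])
        p = rp.dissolve_patches(m, "EI")
        assert rp.metric_np(p) == 1
        assert rp.metric_mps(p) == pytest.approx(1.0)  # 10,000 m2 = 1 ha

    def test_mps_mean_of_unequal_patches(self):
        m = lc([(box(0, 0, 50, 100), "EI"), (box(200, 0, 300, 150), "EI")])
        # (5,000 + 15,000) / 2 / 10,000 = 1.0 ha
        assert rp.metric_mps(rp.dissolve_patches(m, "EI")) == pytest.approx(1.0)

    def test_empty_class_np_zero_mps_undefined(self):
        assert rp.metric_np([]) == 0
        assert rp.metric_mps([]) is None

    def test_ed_closed_form(self):
        m = lc([(box(0, 0, 100, 100), "EI")])
        p = rp.dissolve_patches(m, "EI")
        assert rp.metric_ed(p, 10_000.0) == pytest.approx(400.0)
        # doubling the landscape halves ED
        assert rp.metric_ed(p, 20_000.0) == pytest.approx(200.0)
        assert rp.metric_ed([], 10_000.0) == 0.0

    def test_ed_zero_landscape_rejected(self):
        with pytest.raises(ValueError):
            rp.metric_ed([], 0.0)

    def test_ed_boundary_exclusion_variant(self):
        # patch sharing its west edge (100 m) with the landscape boundary
        m = lc([(box(0, 0, 100, 100), "EI"), (box(100, 0, 200, 100),
                                              "Farmland")])
        p = rp.dissolve_patches(m, "EI")
        landscape = box(0, 0, 200, 100)
        full = rp.metric_ed(p, landscape.area)
        trimmed = rp.metric_ed(p, landscape.area,
                               landscape_boundary=landscape.boundary)
        assert full == pytest.approx(400 / 20_000 * 10_000)
        assert trimmed == pytest.approx(100 / 20_000 * 10_000)

    def test_mnnd_symmetric_pair(self):
        m = lc([(box(0, 0, 10, 10), "EI"), (box(20, 0, 30, 10), "EI")])
        assert rp.metric_mnnd(rp.dissolve_patches(m, "EI")) == pytest.approx(10.0)

    def test_mnnd_collinear_triple_matches_exhaustive(self):
        m = lc([(box(0, 0, 10, 10), "EI"), (box(20, 0, 30, 10), "EI"),
                (box(60, 0, 70, 10), "EI")])
        patches = rp.dissolve_patches(m, "EI")
        # exhaustive oracle: nearest distances 10, 10, 30 -> mean 16.667
        geoms = [p.geometry for p in patches]
        oracle = np.mean([min(g.distance(h) for j, h in enumerate(geoms)
                              if j != i) for i, g in enumerate(geoms)])
        assert oracle == pytest.approx((10 + 10 + 30) / 3, abs=1e-9)
        assert rp.metric_mnnd(patches) == pytest.approx(oracle)

    def test_mnnd_single_patch_undefined(self):
        m = lc([(box(0, 0, 10, 10), "EI")])
        assert rp.metric_mnnd(rp.dissolve_patches(m, "EI")) is None

    def test_mnnd_equals_exhaustive_oracle_on_synthetic_mosaic(self):
        mosaic = rp.make_mosaic(rp.MosaicSpec(seed=5, nx=20, ny=20))
        for cls in mosaic.classes:
            patches = rp.dissolve_patches(mosaic, cls)
            if len(patches) < 2:
                continue
            geoms = [p.geometry for p in patches]
            oracle = np.mean([min(g.distance(h)
                                  for j, h in enumerate(geoms) if j != i)
                              for i, g in enumerate(geoms)])
            assert rp.metric_mnnd(patches) == pytest.approx(oracle), cls

    def test_msi_circle_is_one(self):
        m = lc([(Point(0, 0).buffer(50, quad_segs=256), "EI")])
        assert rp.metric_msi(rp.dissolve_patches(m, "EI")) == pytest.approx(
            1.0, abs=1e-3)

    def test_msi_square_closed_form(self):
        m = lc([(box(0, 0, 7, 7), "EI")])
        assert rp.metric_msi(rp.dissolve_patches(m, "EI")) == pytest.approx(
            2 / math.sqrt(math.pi), abs=1e-9)

    def test_msi_mean_of_identical_patches_unchanged(self):
        one = lc([(box(0, 0, 7, 7), "EI")])
        two = lc([(box(0, 0, 7, 7), "EI"), (box(20, 20, 27, 27), "EI")])
        assert rp.metric_msi(rp.dissolve_patches(two, "EI")) == pytest.approx(
            rp.metric_msi(rp.dissolve_patches(one, "EI")))

    def test_msi_at_least_one_with_holes_counted(self):
        outer = box(0, 0, 100, 100)
        holed = outer.difference(box(40, 40, 60, 60))
        patches = rp.dissolve_patches(lc([(holed, "EI")]), "EI")
        assert patches[0].perimeter_m == pytest.approx(400 + 80)
        assert rp.metric_msi(patches) > 1.0

    def test_scaling_behavior(self):
        """Uniform scaling by k: MPS x k^2, ED x 1/k, MNND x k, MSI fixed."""
        base = [(box(0, 0, 30, 20), "EI"), (box(50, 0, 70, 25), "EI")]
        k = 3.0
        scaled = [(affinity.scale(g, k, k, origin=(0, 0)), c)
                  for g, c in base]
        pa = rp.dissolve_patches(lc(base), "EI")
        pb = rp.dissolve_patches(lc(scaled), "EI")
        area = 10_000.0
        assert rp.metric_mps(pb) == pytest.approx(k * k * rp.metric_mps(pa))
        assert rp.metric_ed(pb, area * k * k) == pytest.approx(
            rp.metric_ed(pa, area) / k)
        assert rp.metric_mnnd(pb) == pytest.approx(k * rp.metric_mnnd(pa))
        assert rp.metric_msi(pb) == pytest.approx(rp.metric_msi(pa))

    def test_class_areas_conserve_landscape_area(self):
        mosaic = rp.make_mosaic(rp.MosaicSpec(seed=2))
        total = sum(sum(p.area_m2 for p in rp.dissolve_patches(mosaic, cls))
                    for cls in mosaic.classes)
        assert total == pytest.approx(mosaic.landscape_area_m2, rel=1e-6)


class TestChangeTable:
    def test_identical_maps_change_is_zero(self, two_class_map):
        ch = rp.change_table(two_class_map, two_class_map)
        assert (ch == 0).all().all()

    def test_change_from_area_tables(self):
        a = pd.DataFrame({"area_km2": [0.51, 4.85], "area_pct": [8.92, 84.98]},
                         index=["EI", "Farmland"])
        b = pd.DataFrame({"area_km2": [0.68, 3.94], "area_pct": [11.95, 69.03]},
                         index=["EI", "Farmland"])
        ch = rp.change_table(a, b)
        assert ch.loc["Farmland", "d_area_km2"] == pytest.approx(-0.91)
        assert ch.loc["EI", "d_area_km2"] == pytest.approx(0.17)
        assert ch.loc["Farmland", "d_area_pct_points"] == pytest.approx(-16.0)

    def test_mismatched_schema_rejected(self, two_class_map):
        other = lc([(box(0, 0, 100, 100), "Settlement")])
        with pytest.raises(ValueError, match="schemas"):
            rp.change_table(two_class_map, other)

    def test_geometry_route_matches_hand_areas(self):
        a = lc([(box(0, 0, 1000, 1000), "Farmland")], epoch="a")
        b = lc([(box(0, 0, 1000, 600), "Farmland"),
                (box(0, 600, 1000, 1000), "Settlement")], epoch="b")
        # schemas must match: Settlement absent in epoch a
        with pytest.raises(ValueError):
            rp.change_table(a, b)
        a2 = lc([(box(0, 0, 1000, 1000), "Farmland"),
                 (box(2000, 0, 2001, 1), "Settlement")], epoch="a")
        ch = rp.change_table(a2, b)
        assert ch.loc["Farmland", "d_area_km2"] == pytest.approx(-0.4)
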