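from collections import Counter

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon, box

import uavpheno as u
from uavpheno.grids import GridSpec, ClassifiedRaster, ZoneRaster, CLASS_IDS
from uavpheno.plots_extract import rasterize_polygons


def grid(rows, cols, gsd=1.0):
    return GridSpec(0.0, rows * gsd, gsd, rows, cols)


class TestPolylinesToPolygons:
    def test_unit_square(self):
        lines = [
            LineString([(0, 0), (1, 0)]), LineString([(1, 0), (1, 1)]),
            LineString([(1, 1), (0, 1)]), LineString([(0, 1), (0, 0)]),
        ]
        out = u.polylines_to_polygons(lines)
        assert len(out) == 1
        assert out[0][2] == pytest.approx(1.0)

    def test_plot_lattice(self):
        """A lattice of grid lines at 4 m x 1.5 m spacing closes into 6
        plot-sized faces of 6 m^2 each (shoelace check)."""
        xs = [0.0, 1.5, 3.0]
        ys = [0.0, 4.0, 8.0, 12.0]
        lines = [LineString([(x, ys[0]), (x, ys[-1])]) for x in xs]
        lines += [LineString([(xs[0], y), (xs[-1], y)]) for y in ys]
        out = u.polylines_to_polygons(lines)
        assert len(out) == 6
        for _, poly, area in out:
            coords = np.asarray(poly.exterior.coords)
            shoelace = 0.5 * abs(
                np.dot(coords[:, 0], np.roll(coords[:, 1], -1))
                - np.dot(coords[:, 1], np.roll(coords[:, 0], -1)))
            assert area == pytest.approx(shoelace)
            assert area == pytest.approx(6.0)
        # ids are auto-incrementing and unique
        assert [t[0] for t in out] == list(range(1, 7))

    def test_snapping_closes_small_gaps(self):
        eps = 0.004  # below the 1 cm default snap tolerance
        lines = [
            LineString([(0, 0), (1, 0)]), LineString([(1 + eps, 0), (1, 1)]),
            LineString([(1, 1 - eps), (0, 1)]), LineString([(0, 1), (0, eps)]),
        ]
        out = u.polylines_to_polygons(lines, snap_tol=0.01)
        assert len(out) == 1
        assert out[0][2] == pytest.approx(1.0, abs=0.05)

    def test_open_triangle_yields_nothing(self):
        lines = [
            LineString([(0, 0), (1, 0)]), LineString([(1, 0), (0.5, 1)]),
            LineString([(0.45, 1), (0.1, 0.2)]),  # gap 0.2 >> snap_tol
        ]
        assert u.polylines_to_polygons(lines, snap_tol=0.01) == []


class TestRasterizeZones:
    def test_single_polygon_covers_grid(self):
        g = grid(5, 7)
        zr = u.rasterize_zones([(3, box(-1, -1, 8, 6))], g)
        assert (zr.zones == 3).all()
        assert zr.ids == [3]

    def test_plot_pixel_area(self):
        """A 4 m x 1.5 m plot at 1.5 cm GSD rasterizes to its true 6 m^2
        within one pixel row + column of perimeter quantization error
        (centre-point count oracle)."""
        g = GridSpec(0.0, 10.0, 0.015, 667, 400)
        poly = box(1.0, 2.0, 2.5, 6.0)
        zr = u.rasterize_zones([(1, poly)], g)
        count = int((zr.zones == 1).sum())
        max_err = (1.5 / 0.015 + 4.0 / 0.015 + 2) * g.pixel_area
        assert abs(count * g.pixel_area - 6.0) <= max_err
        # oracle: explicit centre-in-rectangle count
        rows, cols = np.mgrid[0:667, 0:400]
        x = 0.0 + (cols + 0.5) * 0.015
        y = 10.0 - (rows + 0.5) * 0.015
        oracle = ((x >= 1.0) & (x <= 2.5) & (y >= 2.0) & (y <= 6.0)).sum()
        assert count == oracle

    def test_subpixel_polygon_between_centers(self):
        g = grid(4, 4)
        sliver = box(0.6, 0.0, 0.9, 4.0)  # lies between column centres
        zr = u.rasterize_zones([(1, sliver)], g)
        assert (zr.zones == 0).all()
        assert zr.ids == [1]  # still listed, with zero cells

    def test_shared_edge_goes_to_lower_id(self):
        g = grid(4, 4)
        # shared edge at x=2 passes nowhere near centres; make it x=2.5
        left, right = box(0, 0, 2.5, 4), box(2.5, 0, 4, 4)
        z = rasterize_polygons([left, right], [1, 2], g)
        # column 2 centres (x=2.5) lie exactly on the shared edge
        assert (z[:, 2] == 1).all()

    def test_overlap_rejected(self):
        g = grid(4, 4)
        with pytest.raises(ValueError, match="overlap"):
            u.rasterize_zones([(1, box(0, 0, 3, 3)), (2, box(2, 2, 4, 4))], g)

    def test_duplicate_ids_rejected(self):
        g = grid(4, 4)
        with pytest.raises(ValueError, match="duplicate"):
            u.rasterize_zones([(1, box(0, 0, 1, 1)), (1, box(2, 2, 3, 3))], g)


def random_scene(rng, rows, cols, n_zones, gsd=1.0):
    g = grid(rows, cols, gsd)
    zones = rng.integers(0, n_zones + 1, size=(rows, cols)).astype(np.int32)
    labels = rng.integers(0, 5, size=(rows, cols)).astype(np.uint8)
    return (ZoneRaster(zones, g, ids=list(range(1, n_zones + 1))),
            ClassifiedRaster(labels, g))


class TestTabulateArea:
    def test_single_class_zone(self):
        g = grid(10, 10, gsd=0.015)
        zones = ZoneRaster(np.zeros((10, 10), np.int32), g, ids=[1])
        zones.zones[:10, :10] = 1
        labels = np.full((10, 10), CLASS_IDS["green"], np.uint8)
        out = u.tabulate_area(zones, ClassifiedRaster(labels, g))
        row = out.iloc[0]
        assert row["area_green_m2"] == pytest.approx(100 * 0.000225)
        for other in ("soil", "yellow", "dry"):
            assert row[f"area_{other}_m2"] == 0.0

    def test_matches_exhaustive_count(self, rng):
        """tabulate_area equals a brute-force per-pixel Counter."""
        zones, classes = random_scene(rng, 80, 120, n_zones=9, gsd=0.5)
        out = u.tabulate_area(zones, classes).set_index("plot_id")
        counter = Counter(
            zip(zones.zones.ravel().tolist(), classes.labels.ravel().tolist()))
        px = zones.grid.pixel_area
        for zid in zones.ids:
            for cls, code in CLASS_IDS.items():
                assert out.loc[zid, f"area_{cls}_m2"] == counter[(zid, code)] * px

    def test_zone_conservation(self, rng):
        zones, classes = random_scene(rng, 60, 60, n_zones=5)
        out = u.tabulate_area(zones, classes)
        px = zones.grid.pixel_area
        for _, row in out.iterrows():
            class_sum = sum(row[f"area_{c}_m2"] for c in
                            ("soil", "green", "yellow", "dry"))
            nodata = Counter(
                zip(zones.zones.ravel().tolist(),
                    classes.labels.ravel().tolist()))[(row["plot_id"], 0)]
            assert class_sum + nodata * px == pytest.approx(row["plot_area_m2"])

    def test_empty_zone_retained(self):
        g = grid(5, 5)
        zones = ZoneRaster(np.zeros((5, 5), np.int32), g, ids=[1, 2])
        zones.zones[0, 0] = 1  # zone 2 has no cells
        labels = ClassifiedRaster(np.ones((5, 5), np.uint8), g)
        out = u.tabulate_area(zones, labels)
        assert list(out["plot_id"]) == [1, 2]
        assert out.set_index("plot_id").loc[2].sum() == 0.0

    def test_relabelling_invariance(self, rng):
        zones, classes = random_scene(rng, 40, 40, n_zones=4)
        out1 = u.tabulate_area(zones, classes).set_index("plot_id")
        perm = {1: 3, 2: 4, 3: 1, 4: 2, 0: 0}
        relabeled = np.vectorize(perm.get)(zones.zones).astype(np.int32)
        zr2 = ZoneRaster(relabeled, zones.grid, ids=[1, 2, 3, 4])
        out2 = u.tabulate_area(zr2, classes).set_index("plot_id")
        for old, new in perm.items():
            if old == 0:
                continue
            pd.testing.assert_series_equal(
                out1.loc[old], out2.loc[new], check_names=False)

    def test_grid_mismatch(self, rng):
        zones, _ = random_scene(rng, 10, 10, 2)
        _, classes = random_scene(rng, 10, 11, 2)
        with pytest.raises(ValueError, match="grid"):
            u.tabulate_area(zones, classes)


class TestJoinAttributes:
    def test_full_trial_join(self, small_classified, small_trial):
        table = small_classified["table"]
        assert len(table) == small_trial["layout"].n_plots
        assert list(table.columns) == [
            "plot_id", "trial", "variety", "rep", "block", "plot_area_m2",
            "area_soil_m2", "area_green_m2", "area_yellow_m2", "area_dry_m2"]
        assert table["variety"].notna().all()

    def test_empty_area_table(self, small_trial):
        out = u.join_attributes(pd.DataFrame(), small_trial["layout"])
        assert out.empty

    def test_duplicate_plot_id_rejected(self, small_trial):
        areas = pd.DataFrame({
            "plot_id": [1, 1], "plot_area_m2": [6.0, 6.0],
            "area_soil_m2": 0.0, "area_green_m2": 0.0,
            "area_yellow_m2": 0.0, "area_dry_m2": 0.0})
        with pytest.raises(ValueError, match="duplicate"):
            u.join_attributes(areas, small_trial["layout"])

    def test_unmatched_id_rejected(self, small_trial):
        areas = pd.DataFrame({
            "plot_id": [9999], "plot_area_m2": [6.0],
            "area_soil_m2": 0.0, "area_green_m2": 0.0,
            "area_yellow_m2": 0.0, "area_dry_m2": 0.0})
        with pytest.raises(ValueError, match="9999"):
            u.join_attributes(areas, small_trial["layout"])
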