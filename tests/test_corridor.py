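import numpy as np
import pytest

from ecocorridor import kernel_density, quantile_classes
from ecocorridor.corridor import CorridorSet, delineate_corridors, restoration_points
from ecocorridor.mcr import Path

from conftest import grid


def template(shape=(40, 40), cell=30.0):
    return grid(np.zeros(shape), cell_size=cell)


class TestKernelDensity:
    def test_single_point_mass_conserved(self):
        g = template()
        pt = np.array([[g.cell_center(20, 20)[0], g.cell_center(20, 20)[1]]])
        dens = kernel_density(pt, np.array([7.0]), g, bandwidth_m=300.0)
        assert dens.values.sum() == pytest.approx(7.0, rel=1e-9)

    def test_coincident_points_double_density(self):
        g = template()
        pt = np.array([g.cell_center(20, 20)])
        one = kernel_density(pt, np.array([3.0]), g, 300.0)
        two = kernel_density(np.vstack([pt, pt]), np.array([3.0, 3.0]), g, 300.0)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_maximum_at_cluster_centroid(self):
        g = template()
        pts = np.array([g.cell_center(20, 18), g.cell_center(20, 22),
                        g.cell_center(18, 20), g.cell_center(22, 20)])
        dens = kernel_density(pts, np.ones(4), g, 300.0)
        assert np.unravel_index(dens.values.argmax(), dens.shape) == (20, 20)

    def test_gaussian_kernel_option(self):
        g = template()
        pt = np.array([g.cell_center(20, 20)])
        dens = kernel_density(pt, np.array([1.0]), g, 120.0, kernel="gaussian")
        assert dens.values.sum() == pytest.approx(1.0, rel=1e-6)

    def test_edge_loss_warned(self):
        g = template()
        pt = np.array([g.cell_center(0, 0)])  # corner point loses mass
        with pytest.warns(UserWarning, match="edge loss"):
            kernel_density(pt, np.array([1.0]), g, 600.0)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kernel_density(np.empty((0, 2)), np.empty(0), template(), 300.0)


class TestQuantileClasses:
    def test_nine_distinct_values_one_per_class(self):
        vals = np.zeros((3, 9))
        vals[1] = np.arange(1.0, 10.0)
        classes = quantile_classes(grid(vals), 9)
        assert sorted(classes.values[1]) == list(range(1, 10))
        assert (classes.values[[0, 2]] == 0).all()  # zero density unclassed

    def test_eighteen_values_two_per_class(self):
        vals = np.arange(1.0, 19.0).reshape(2, 9)
        classes = quantile_classes(grid(vals), 9)
        counts = np.bincount(classes.values.ravel(), minlength=10)[1:]
        assert (counts == 2).all()

    def test_constant_positive_density_collapses_to_top(self):
        with pytest.warns(UserWarning, match="collapse"):
            classes = quantile_classes(grid(np.full((4, 4), 2.0)), 9)
        assert (classes.values == 9).all()

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 10)) + 0.1
        c1 = quantile_classes(grid(vals), 9).values
        c2 = quantile_classes(grid(vals**3), 9).values
        np.testing.assert_array_equal(c1, c2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            quantile_classes(grid(np.zeros((3, 3))), 9)


class TestDelineateCorridors:
    def make_classes(self):
        rng = np.random.default_rng(1)
        dens = np.zeros((20, 30))
        dens[5:15, :] = rng.random((10, 30)) + 0.01
        g = grid(dens, cell_size=1000.0)
        return quantile_classes(g, 9), np.ones((20, 30), dtype=bool)

    def test_partition_of_pheromone_bearing_region(self):
        classes, region = self.make_classes()
        rec = delineate_corridors(classes, region, Path([(10, 0), (10, 1)], 0.0))
        bearing = classes.values >= 1
        assert not (rec.main_mask & rec.potential_mask).any()
        np.testing.assert_array_equal(rec.main_mask | rec.potential_mask, bearing)

    def test_main_fraction_about_three_ninths(self):
        classes, region = self.make_classes()
        rec = delineate_corridors(classes, region, Path([(10, 0)], 0.0))
        bearing = (classes.values >= 1).sum()
        assert rec.main_mask.sum() / bearing == pytest.approx(3 / 9, abs=0.02)

    def test_no_pheromone_means_all_potential(self):
        g = grid(np.zeros((10, 10)), cell_size=1000.0)
        classes = g.like(np.zeros((10, 10), dtype=np.int16))
        with pytest.warns(UserWarning, match="unsupported"):
            rec = delineate_corridors(classes, np.ones((10, 10), dtype=bool),
                                      Path([(5, 5)], 0.0))
        assert rec.unsupported
        assert rec.main_polygon is None

    def test_areas_in_km2(self):
        classes, region = self.make_classes()
        rec = delineate_corridors(classes, region, Path([(10, 0)], 0.0))
        # 1 km cells: area equals cell count
        assert rec.main_area_km2 == pytest.approx(rec.main_mask.sum())


class TestRestorationPoints:
    def make_record(self, main_mask, cells, region=None):
        from ecocorridor.corridor import CorridorRecord

        region = region if region is not None else np.ones_like(main_mask)
        return CorridorRecord(
            id=1, centreline=Path(cells, 0.0), main_polygon=None,
            potential_polygon=None, main_area_km2=0.0, potential_area_km2=0.0,
            main_mask=main_mask, potential_mask=np.zeros_like(main_mask),
            region_mask=region.astype(bool),
        )

    def test_gap_in_cover_yields_midpoint_discontinuity(self):
        shape = (20, 40)
        cells = [(10, c) for c in range(40)]
        main = np.zeros(shape, dtype=bool)
        main[10, :18] = True
        main[10, 24:] = True  # 6-cell gap at cols 18..23
        rec = self.make_record(main, cells)
        res = grid(np.ones(shape))
        pts = restoration_points(CorridorSet([rec], res), res)
        disc = [p for p in pts if p.kind == "discontinuity"]
        assert len(disc) == 1
        assert disc[0].cell == (10, 21)

    def test_short_gap_ignored(self):
        shape = (20, 40)
        cells = [(10, c) for c in range(40)]
        main = np.ones(shape, dtype=bool)
        main[10, 20:22] = False  # 2-cell gap < gap_min_cells
        rec = self.make_record(main, cells)
        res = grid(np.ones(shape))
        pts = restoration_points(CorridorSet([rec], res), res, gap_min_cells=3)
        assert [p for p in pts if p.kind == "discontinuity"] == []

    def test_crossing_corridors_yield_intersection_point(self):
        shape = (30, 30)
        a = self.make_record(np.ones(shape, dtype=bool),
                             [(15, c) for c in range(30)])
        b = self.make_record(np.ones(shape, dtype=bool),
                             [(r, 15) for r in range(30)])
        b.id = 2
        res = grid(np.ones(shape))
        pts = restoration_points(CorridorSet([a, b], res), res)
        inter = [p for p in pts if p.kind == "intersection"]
        assert len(inter) == 1
        assert inter[0].cell == (15, 15)
        assert set(inter[0].corridor_ids) == {1, 2}

    def test_clean_corridor_yields_no_points(self):
        shape = (20, 40)
        cells = [(10, c) for c in range(40)]
        rec = self.make_record(np.ones(shape, dtype=bool), cells)
        res = grid(np.ones(shape))  # constant resistance: no mutation maxima
        pts = restoration_points(CorridorSet([rec], res), res)
        assert pts == []
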