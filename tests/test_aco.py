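import numpy as np
import pytest

from ecocorridor import AntParams, filter_pheromone_points, run_colony, search_region
from ecocorridor.aco import deposit_mass, direction_layer, transition_probabilities
from ecocorridor.mcr import Path

from conftest import grid


def straight_path(row, cols):
    return Path(cells=[(row, c) for c in cols], total_cost=0.0)


class TestSearchRegion:
    def test_band_width_matches_buffer(self):
        g = grid(np.ones((151, 40)), cell_size=30.0)
        path = straight_path(75, range(40))
        region = search_region(path, g, 1500.0)
        # 1500 m at 30 m cells: 50 cells each side plus the path row
        col = region.values[:, 20]
        assert col.sum() == 101
        assert col[75 - 50 : 75 + 51].all()

    def test_region_contains_path(self):
        g = grid(np.ones((20, 20)), cell_size=30.0)
        path = straight_path(10, range(3, 17))
        region = search_region(path, g, 60.0)
        assert all(region.values[r, c] for r, c in path.cells)

    def test_buffer_below_cell_size_rejected(self):
        g = grid(np.ones((20, 20)), cell_size=30.0)
        with pytest.raises(ValueError, match="narrower"):
            search_region(straight_path(10, range(20)), g, 10.0)


class TestTransitionProbabilities:
    def setup_method(self):
        self.region = np.ones((7, 7), dtype=bool)
        self.tau = np.full((7, 7), 0.5)
        self.res = np.ones((7, 7))
        self.visited = np.zeros((7, 7), dtype=bool)
        self.params = AntParams(seed=0)

    def test_first_step_uniform_over_neighbors(self):
        cand, probs, jumped = transition_probabilities(
            (3, 3), 8, self.visited, self.tau, self.res, self.region,
            self.params, threshold=np.inf,
        )
        assert not jumped
        assert len(cand) == 8
        np.testing.assert_allclose(probs, 1 / 8)

    def test_large_beta_concentrates_on_cheapest(self):
        res = self.res.copy()
        res[3, 4] = 0.5  # strictly cheapest neighbor
        params = AntParams(beta=30.0, seed=0)
        cand, probs, _ = transition_probabilities(
            (3, 3), 8, self.visited, self.tau, res, self.region, params,
            threshold=np.inf,
        )
        assert probs[cand.index((3, 4))] > 0.999

    def test_all_high_neighbors_trigger_jump(self):
        res = self.res.copy()
        res[2:5, 2:5] = 100.0  # everything around (3,3) is high resistance
        cand, probs, jumped = transition_probabilities(
            (3, 3), 8, self.visited, self.tau, res, self.region, self.params,
            threshold=50.0,
        )
        assert jumped
        # jump set: all region cells within Chebyshev radius 3, minus self
        assert len(cand) == 7 * 7 - 1
        np.testing.assert_allclose(probs, 1 / len(cand))

    def test_direction_memory_restricts_moves(self):
        # previous step east (dir index 4): no westward component allowed
        cand, _, _ = transition_probabilities(
            (3, 3), 4, self.visited, self.tau, self.res, self.region,
            self.params, threshold=np.inf,
        )
        assert all(dc >= 0 for _, dc in ((r - 3, c - 3) for r, c in cand))
        assert len(cand) == 5

    def test_visited_cells_excluded(self):
        self.visited[3, 4] = True
        cand, _, _ = transition_probabilities(
            (3, 3), 8, self.visited, self.tau, self.res, self.region,
            self.params, threshold=np.inf,
        )
        assert (3, 4) not in cand


class TestRunColony:
    def small_setup(self, seed=5):
        rng = np.random.default_rng(1)
        res = grid(5.0 * (1 + 0.05 * rng.standard_normal((20, 40))), cell_size=30.0)
        region = np.ones((20, 40), dtype=bool)
        params = AntParams(n_ants=30, n_iterations=8, seed=seed)
        return res, region, params

    def test_seed_determinism(self):
        res, region, params = self.small_setup()
        f1 = run_colony(res, region, (10, 2), (10, 37), params)
        f2 = run_colony(res, region, (10, 2), (10, 37), params)
        np.testing.assert_array_equal(f1.tau.values, f2.tau.values)

    def test_different_seeds_differ(self):
        res, region, _ = self.small_setup()
        f1 = run_colony(res, region, (10, 2), (10, 37), AntParams(n_ants=30, n_iterations=8, seed=1))
        f2 = run_colony(res, region, (10, 2), (10, 37), AntParams(n_ants=30, n_iterations=8, seed=2))
        assert not np.array_equal(f1.tau.values, f2.tau.values)

    def test_tau_zero_outside_region(self):
        res, region, params = self.small_setup()
        region[:4, :] = False
        f = run_colony(res, region, (10, 2), (10, 37), params)
        assert (f.tau.values[~f.region] == 0).all()
        assert (f.tau.values[f.region] > 0).all()

    def test_pheromone_floor_after_evaporation(self):
        res, region, params = self.small_setup()
        f = run_colony(res, region, (10, 2), (10, 37), params)
        floor = params.tau0 * (1 - params.rho) ** params.n_iterations
        assert (f.tau.values[f.region] >= floor - 1e-15).all()

    def test_transverse_symmetry_on_uniform_corridor(self, colony_runs):
        sc, field, params = colony_runs("b")
        dep = deposit_mass(field, params)
        rows = np.arange(dep.shape[0], dtype=float)
        mean_row = (dep.sum(axis=1) * rows).sum() / dep.sum()
        assert mean_row == pytest.approx(sc.start[0], abs=2.0)
        # binned mass decreases away from the corridor axis
        offset = np.abs(rows - sc.start[0]).astype(int)
        mass = np.zeros(offset.max() + 1)
        np.add.at(mass, offset, dep.sum(axis=1))
        near, mid, far = mass[:5].sum(), mass[5:15].sum(), mass[15:].sum()
        assert near > mid > far

    def test_identical_terminals_rejected(self):
        res, region, params = self.small_setup()
        with pytest.raises(ValueError, match="coincide"):
            run_colony(res, region, (5, 5), (5, 5), params)

    def test_terminal_outside_region_rejected(self):
        res, region, params = self.small_setup()
        region[10, 2] = False
        with pytest.raises(ValueError, match="outside"):
            run_colony(res, region, (10, 2), (10, 37), params)


class TestDirectionLayer:
    def test_flow_points_toward_target_on_uniform_field(self):
        g = grid(np.ones((9, 9)), cell_size=30.0)
        region = np.ones((9, 9), dtype=bool)
        layer = direction_layer(g, region, (4, 8))
        # due west of the target the flow must have an eastward component
        assert layer[4, 0] in (2, 4, 7)  # NE, E, SE


class TestFilterPheromonePoints:
    def make_field(self, tau_vals, visits_vals):
        from ecocorridor.aco import PheromoneField

        g = grid(tau_vals, cell_size=30.0)
        return PheromoneField(
            tau=g, visits=g.like(np.asarray(visits_vals)),
            region=np.ones_like(np.asarray(tau_vals), dtype=bool),
            start=(0, 0), end=(0, 2),
        )

    def test_strictly_above_mean_retained(self):
        f = self.make_field([[1.0, 2.0, 3.0]], [[1, 1, 1]])
        pts, w = filter_pheromone_points(f)
        assert len(w) == 1
        assert w[0] == 3.0

    def test_flat_field_yields_empty_set(self):
        f = self.make_field([[2.0, 2.0, 2.0]], [[1, 1, 1]])
        with pytest.warns(UserWarning, match="equal"):
            pts, w = filter_pheromone_points(f)
        assert len(w) == 0

    def test_weights_are_subset_of_tau_values(self):
        rng = np.random.default_rng(0)
        tau = rng.random((5, 5))
        f = self.make_field(tau, np.ones((5, 5), dtype=int))
        _, w = filter_pheromone_points(f)
        tau_set = set(np.round(tau.ravel(), 12))
        assert set(np.round(w, 12)) <= tau_set
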