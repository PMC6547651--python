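import itertools
import math

import numpy as np
import pytest

from dendriflow import (
    ScenarioConfig,
    build_cost_raster,
    build_network,
    least_cost_distance,
    select_patches,
)
from dendriflow.habitat_network import HabitatNetwork, HabitatPatch
from dendriflow.landscape import CostRaster


def uniform_raster(rows, cols, cost, config, aquatic_cells=()):
    grid = np.zeros((rows, cols), dtype=np.int8)
    return build_cost_raster(grid, set(aquatic_cells), config)


def brute_force_distance(raster, a, b):
    """Minimum path cost by pruned exhaustive search over simple 8-connected paths."""
    rows, cols = raster.cost.shape
    best = [math.inf]

    def walk(cell, acc, seen):
        if acc >= best[0]:
            return
        if cell == b:
            best[0] = acc
            return
        r, c = cell
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            nb = (r + dr, c + dc)
            if not (0 <= nb[0] < rows and 0 <= nb[1] < cols) or nb in seen:
                continue
            mult = math.sqrt(2) if dr and dc else 1.0
            step = (raster.cost[cell] + raster.cost[nb]) / 2 * mult
            walk(nb, acc + step, seen | {nb})

    walk(a, 0.0, {a})
    return best[0]


class TestSelectPatches:
    def make_raster(self, config, n_aquatic=100):
        cells = {(0, i) for i in range(n_aquatic)}
        grid = np.zeros((2, n_aquatic), dtype=np.int8)
        return build_cost_raster(grid, cells, config)

    def test_ten_percent_of_aquatic_cells(self, config):
        raster = self.make_raster(config, 100)
        patches = select_patches(raster, config)
        assert len(patches) == 10
        assert all(raster.aquatic_mask[p.cell] for p in patches)
        assert all(0.5 <= p.quality <= 1.0 and p.K == p.quality * 100.0 for p in patches)

    def test_fraction_one_selects_all(self, config):
        config.habitat_fraction = 1.0
        raster = self.make_raster(config, 23)
        assert len(select_patches(raster, config)) == 23

    def test_deterministic(self, config):
        raster = self.make_raster(config)
        a = select_patches(raster, config)
        b = select_patches(raster, config)
        assert a == b

    def test_no_aquatic_cells_rejected(self, config):
        raster = uniform_raster(3, 3, 50.0, config)
        with pytest.raises(ValueError):
            select_patches(raster, config)


class TestLeastCostDistance:
    def test_identity(self, config):
        raster = uniform_raster(4, 4, 50.0, config)
        assert least_cost_distance(raster, (1, 2), (1, 2)) == 0.0

    def test_straight_run_uniform_cost(self, config):
        # n 4-neighbour steps through uniform cost c accumulate n*c
        raster = uniform_raster(1, 11, 50.0, config)
        assert least_cost_distance(raster, (0, 0), (0, 10)) == pytest.approx(10 * 50.0)

    def test_diagonal_shortcut(self, config):
        raster = uniform_raster(3, 3, 50.0, config)
        d = least_cost_distance(raster, (0, 0), (2, 2))
        assert d == pytest.approx(2 * 50.0 * math.sqrt(2))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_small_grids(self, config, seed):
        rng = np.random.default_rng(seed)
        cost = rng.choice([25.0, 50.0, 75.0, 100.0], size=(4, 4))
        raster = CostRaster(
            landcover=np.zeros((4, 4), np.int8),
            cost=cost,
            aquatic_mask=np.zeros((4, 4), bool),
        )
        a, b = (0, 0), (3, 3)
        assert least_cost_distance(raster, a, b) == pytest.approx(brute_force_distance(raster, a, b))

    def test_triangle_inequality(self, config):
        rng = np.random.default_rng(7)
        cost = rng.choice([25.0, 50.0, 75.0, 100.0], size=(6, 6))
        raster = CostRaster(
            landcover=np.zeros((6, 6), np.int8), cost=cost, aquatic_mask=np.zeros((6, 6), bool)
        )
        cells = [(0, 0), (5, 5), (2, 3), (4, 1), (0, 5)]
        for a, b, c in itertools.permutations(cells, 3):
            assert least_cost_distance(raster, a, c) <= (
                least_cost_distance(raster, a, b) + least_cost_distance(raster, b, c) + 1e-9
            )

    def test_returns_path(self, config):
        raster = uniform_raster(1, 5, 50.0, config)
        d, path = least_cost_distance(raster, (0, 0), (0, 4), return_path=True)
        assert path[0] == (0, 0) and path[-1] == (0, 4)
        assert d == pytest.approx(4 * 50.0)


class TestBuildNetwork:
    def patches_at(self, cells):
        return [HabitatPatch(i, cell, 1.0, 100.0) for i, cell in enumerate(cells)]

    def test_over_budget_pair_not_connected(self, config):
        # 30 uniform-agriculture steps cost 1500 >= 1250
        raster = uniform_raster(1, 40, 50.0, config)
        net = build_network(self.patches_at([(0, 0), (0, 30)]), raster, config)
        assert net.n_edges == 0

    def test_sub_budget_pair_connected_at_path_cost(self, config):
        raster = uniform_raster(1, 40, 50.0, config)
        net = build_network(self.patches_at([(0, 0), (0, 10)]), raster, config)
        assert net.n_edges == 1
        assert net.edge_cost(0, 1) == pytest.approx(500.0)

    def test_single_patch_empty_edge_set(self, config):
        raster = uniform_raster(3, 3, 50.0, config)
        net = build_network(self.patches_at([(1, 1)]), raster, config)
        assert net.n_edges == 0

    def test_all_edges_strictly_below_budget(self, config):
        config_small = ScenarioConfig(rows=60, cols=60, seed=8)
        from dendriflow import build_scenario

        _, net = build_scenario(config_small)
        assert net.n_patches >= 10
        assert all(c < config_small.C_max for _, _, c in net.edges())
        assert all(c > 0 for _, _, c in net.edges())

    def test_edge_at_or_above_cmax_rejected(self):
        patches = self.patches_at([(0, 0), (0, 1)])
        with pytest.raises(ValueError):
            HabitatNetwork(patches, [(0, 1, 1250.0)], C_max=1250.0)


def test_graphml_roundtrip(tmp_path, config):
    patches = [HabitatPatch(i, (0, i), 0.75, 75.0) for i in range(3)]
    net = HabitatNetwork(patches, [(0, 1, 400.0), (1, 2, 600.0)], C_max=1250.0)
    path = tmp_path / "net.graphml"
    net.to_graphml(str(path))
    back = HabitatNetwork.from_graphml(str(path))
    assert back.patches == net.patches
    assert sorted(back.edges()) == sorted(net.edges())
    assert back.C_max == 1250.0
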