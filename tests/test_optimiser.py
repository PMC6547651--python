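import numpy as np
import pytest

from dendriflow import (
    ScenarioConfig,
    build_mip,
    build_ten,
    choose_time_horizon,
    extract_route,
    horizon_bounds,
    minimum_colonisation_time,
    path_fill_time,
    run_simulation,
    solve_mip,
)
from dendriflow.habitat_network import HabitatNetwork, HabitatPatch
from dendriflow.optimiser import (
    UnreachableDestinationError,
    audit_solution,
    to_lp_string,
    to_mps_string,
)

from conftest import make_chain, random_network, serial_fill_oracle


def triangle():
    patches = [HabitatPatch(i, (0, i), 1.0, 100.0) for i in range(3)]
    edges = [(0, 1, 100.0), (1, 2, 100.0), (0, 2, 100.0)]
    return HabitatNetwork(patches, edges, C_max=1250.0)


class TestTimeExpandedNetwork:
    def test_copy_and_arc_counts(self, config):
        ten = build_ten(triangle(), [0], 3, config)
        assert ten.n_copies == 3 * 4 + 1  # T+1 copies per patch plus Q
        assert ten.n_arcs == 3 * (2 * 3 + 3) + 1

    def test_single_patch_minimal(self, config):
        net = HabitatNetwork([HabitatPatch(0, (0, 0), 1.0, 100.0)], [], C_max=1250.0)
        ten = build_ten(net, [0], 1, config)
        assert ten.n_copies == 3
        assert ten.n_arcs == 2  # (Q, v_0) and (v_0, v_1)

    def test_arc_costs_and_capacities(self, config):
        ten = build_ten(triangle(), [0], 2, config)
        move = ten.arc_kind == ten.MOVE
        assert (ten.arc_cost[move] == 100.0).all()
        assert (ten.arc_cost[~move] == 0.0).all()
        assert (ten.u == 10.0).all()  # S_DIS * K

    def test_horizon_below_one_rejected(self, config):
        with pytest.raises(ValueError):
            build_ten(triangle(), [0], 0, config)


class TestMIP:
    def test_variable_counts(self, config):
        ten = build_ten(triangle(), [0], 3, config)
        instance = build_mip(ten, [2], config)
        assert instance.n_f == 3 * (2 * 3 + 3) + 1
        assert instance.n_xc == 3 * 4
        assert instance.n_xl == 4

    def test_chain_optimum(self, config):
        net = make_chain([625.0, 625.0])
        t_star, route = minimum_colonisation_time(net, [0], [2], config)
        assert t_star == 4
        assert route.paths, "expected at least one decomposed path"

    def test_two_sources_jointly_colonise(self, config):
        patches = [HabitatPatch(i, (0, i), 1.0, 100.0) for i in range(3)]
        net = HabitatNetwork(patches, [(0, 2, 625.0), (1, 2, 625.0)], C_max=1250.0)
        t_star, _ = minimum_colonisation_time(net, [0, 1], [2], config)
        assert t_star == 1
        # a single source needs two steps: 5 units per step against T_SH = 10
        t_single, _ = minimum_colonisation_time(net, [0], [2], config)
        assert t_single == 2

    def test_destination_in_sources(self, config):
        net = make_chain([625.0])
        t_star, route = minimum_colonisation_time(net, [0], [0], config)
        assert t_star == 0
        assert route.paths[0].steps == [("Q", -1), (0, 0)]

    def test_solution_audit_is_clean(self, config):
        net = make_chain([625.0, 625.0])
        ten = build_ten(net, [0], 4, config)
        instance = build_mip(ten, [2], config)
        solution = solve_mip(instance)
        assert solution.status == "optimal"
        assert audit_solution(instance, solution.f, solution.x_copy, solution.x_layer) == []

    def test_infeasible_at_short_horizon(self, config):
        net = make_chain([625.0, 625.0])
        ten = build_ten(net, [0], 2, config)
        solution = solve_mip(build_mip(ten, [2], config))
        assert solution.status == "infeasible"

    def test_scale_equivariance(self, config):
        net = make_chain([500.0, 800.0, 300.0])
        t_a, _ = minimum_colonisation_time(net, [0], [3], config)
        lam = 3.7
        scaled = ScenarioConfig(T_SH=config.T_SH * lam, K_max=config.K_max * lam)
        net_scaled = make_chain([500.0, 800.0, 300.0], K=100.0 * lam)
        t_b, _ = minimum_colonisation_time(net_scaled, [0], [3], scaled)
        assert t_a == t_b

    def test_adding_a_source_never_slows(self, config):
        rng = np.random.default_rng(11)
        net = random_network(rng, 12)
        ids = net.ids()
        dest = ids[-1]
        sources = [ids[0]]
        t_one, _ = minimum_colonisation_time(net, sources, [dest], config)
        t_two, _ = minimum_colonisation_time(net, sources + [ids[1]], [dest], config)
        assert t_two <= t_one

    def test_multiple_destinations(self, config):
        net = make_chain([625.0, 625.0, 625.0])
        t_star, _ = minimum_colonisation_time(net, [0], [2, 3], config)
        assert t_star == 6  # the farther destination dictates the layer


class TestRoute:
    def test_chain_route_reaches_destination_with_threshold(self, config):
        net = make_chain([625.0, 625.0])
        t_star, route = minimum_colonisation_time(net, [0], [2], config)
        into_dest = sum(p.amount for p in route.paths if p.steps[-1] == (2, t_star))
        assert into_dest >= config.T_SH - 1e-6
        for path in route.paths:
            times = [t for _, t in path.steps]
            assert times == sorted(times)
            assert all(b - a >= 1 for a, b in zip(times[:-1], times[1:]) if a >= 0)


class TestPathFillTime:
    def test_chain_formula(self, config):
        net = make_chain([625.0, 625.0])
        assert path_fill_time([0, 1, 2], net, config) == 4

    def test_single_patch_path(self, config):
        net = make_chain([625.0])
        assert path_fill_time([0], net, config) == 0

    def test_ceiling_behaviour(self):
        config = ScenarioConfig(T_SH=10.1)
        net = make_chain([625.0])
        assert path_fill_time([0, 1], net, config) == 3  # ceil(10.1 / 5)

    def test_non_adjacent_rejected(self, config):
        net = make_chain([625.0, 625.0])
        with pytest.raises(ValueError):
            path_fill_time([0, 2], net, config)


class TestTimeHorizon:
    def test_single_source_chain(self, config):
        net = make_chain([625.0, 625.0])
        assert choose_time_horizon(net, [0], 2, config) == 4

    def test_block_caps_large_bounds(self, config):
        # 23 hops of 2 steps each: TH1 = 46, capped at the 30-layer block
        net = make_chain([625.0] * 23)
        th1, th2 = horizon_bounds(net, [0], 23, config)
        assert th1 == 46 and th2 is None
        assert choose_time_horizon(net, [0], 23, config) == 30

    def test_destination_is_a_source(self, config):
        net = make_chain([625.0])
        assert choose_time_horizon(net, [1], 1, config) == 0

    def test_unreachable_destination(self, config):
        patches = [HabitatPatch(0, (0, 0), 1.0, 100.0), HabitatPatch(1, (0, 30), 1.0, 100.0)]
        net = HabitatNetwork(patches, [], C_max=1250.0)
        with pytest.raises(UnreachableDestinationError):
            choose_time_horizon(net, [0], 1, config)

    def test_second_nearest_bound_used(self, config):
        # source 1 is nearer in cost but fills slowly (low K); TH2 can win
        patches = [
            HabitatPatch(0, (0, 0), 1.0, 100.0),
            HabitatPatch(1, (0, 1), 0.5, 50.0),
            HabitatPatch(2, (0, 2), 1.0, 100.0),
        ]
        net = HabitatNetwork(patches, [(1, 2, 300.0), (0, 2, 400.0)], C_max=1250.0)
        th1, th2 = horizon_bounds(net, [0, 1], 2, config)
        assert th1 == path_fill_time([1, 2], net, config)
        assert th2 == path_fill_time([0, 2], net, config)


class TestChainExactness:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_mip_equals_serial_fill_on_chains(self, config, seed):
        rng = np.random.default_rng(seed)
        n_edges = int(rng.integers(1, 5))  # up to 5 patches
        costs = rng.uniform(100.0, 1200.0, size=n_edges)
        net = make_chain(costs, K=float(rng.uniform(50.0, 100.0)))
        dest = n_edges
        t_star, _ = minimum_colonisation_time(net, [0], [dest], config)
        oracle = serial_fill_oracle(net, config, list(range(n_edges + 1)))
        assert t_star == oracle
        assert t_star == path_fill_time(list(range(n_edges + 1)), net, config)


class TestDominance:
    @pytest.mark.parametrize("seed", list(range(10)))
    def test_lower_bound_and_th1_sandwich(self, config, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, int(rng.integers(8, 20)))
        ids = net.ids()
        sources = sorted(int(i) for i in rng.choice(ids, size=2, replace=False))
        sim = run_simulation(net, sources, config)
        for dest in ids:
            if dest in sources:
                continue
            try:
                th1, th2 = horizon_bounds(net, sources, dest, config)
            except UnreachableDestinationError:
                assert sim.first_colonised[dest] is None
                continue
            t_star, _ = minimum_colonisation_time(net, sources, [dest], config)
            assert t_star <= th1
            t_sim = sim.first_colonised[dest]
            if t_sim is not None:
                assert t_star <= t_sim


class TestExport:
    def test_lp_and_mps_mention_named_variables(self, config):
        net = make_chain([625.0])
        ten = build_ten(net, [0], 2, config)
        instance = build_mip(ten, [1], config)
        lp = to_lp_string(instance)
        assert "x_1_2" in lp and "xl_2" in lp and "f_Q_0_0" in lp
        mps = to_mps_string(instance)
        assert "ENDATA" in mps and "x_1_2" in mps
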