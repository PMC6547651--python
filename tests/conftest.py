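import math

import numpy as np
import pytest

from dendriflow import ScenarioConfig
from dendriflow.habitat_network import HabitatNetwork, HabitatPatch


@pytest.fixture
def config():
    return ScenarioConfig()


def make_chain(costs, K=100.0):
    """Path network P0 - P1 - ... with the given edge costs, all K equal."""
    n = len(costs) + 1
    patches = [HabitatPatch(i, (0, i), K / 100.0, K) for i in range(n)]
    edges = [(i, i + 1, float(c)) for i, c in enumerate(costs)]
    return HabitatNetwork(patches, edges, C_max=1250.0)


def random_network(rng, n_patches, c_max=1250.0, radius_cost=900.0):
    """Random geometric habitat network with sub-budget edge costs.

    Patches are scattered on a coarse grid; pairs closer than a cost radius
    are connected with cost proportional to their distance.  Guaranteed to
    contain at least one edge.
    """
    while True:
        cells = set()
        while len(cells) < n_patches:
            cells.add((int(rng.integers(0, 40)), int(rng.integers(0, 40))))
        cells = sorted(cells)
        patches = [
            HabitatPatch(i, cell, q, 100.0 * q)
            for i, (cell, q) in enumerate(zip(cells, 0.5 + 0.5 * rng.random(n_patches)))
        ]
        edges = []
        for i in range(n_patches):
            for j in range(i + 1, n_patches):
                d = math.hypot(cells[i][0] - cells[j][0], cells[i][1] - cells[j][1])
                cost = d * 60.0
                if 0 < cost < min(radius_cost, c_max):
                    edges.append((i, j, cost))
        if edges:
            return HabitatNetwork(patches, edges, C_max=c_max)


def serial_fill_oracle(network, config, path):
    """Independent colonisation clock along a single-predecessor path.

    Accumulates arrivals step by step (no closed-form rounding): the next
    patch on the path receives the full survival-scaled emission of its
    predecessor each step once the predecessor is colonised.
    """
    t = 0
    c_max = network.C_max
    for a, b in zip(path[:-1], path[1:]):
        surv = 1.0 - network.edge_cost(a, b) / c_max
        rate = network.K(a) * config.S_DIS * surv
        acc = 0.0
        while acc < config.T_SH - 1e-12:
            acc += rate
            t += 1
    return t
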