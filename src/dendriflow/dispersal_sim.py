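"""Deterministic discrete-time dispersal simulation on a habitat network.

Each step, every source habitat v emits a pool of ``S_DIS * K(v)`` biomass,
split among all its neighbours with shares proportional to the survival
factor ``1 - C(e)/C_max`` (cheap connections receive a bigger share; an
inverse-cost weighting is available).  The amount actually arriving at a
neighbour is its share reduced by cost-proportional mortality, i.e.
``share * (1 - C/C_max)``.  Arrivals at patches that are already sources
are discarded; vacant patches accumulate arrivals and become sources in
the step after their accumulated biomass reaches the threshold ``T_SH``,
at which point their population jumps to the carrying capacity (or ramps
up logistically with the optional growth model).  Source biomass is
restored to K within the same step, so emission never depletes a source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .habitat_network import HabitatNetwork
from .scenario import ScenarioConfig


@dataclass
class SimulationState:
    t: int
    ids: list[int]  # patch ids, index-aligned with the arrays below
    biomass: np.ndarray
    is_source: np.ndarray  # bool

    def copy(self) -> "SimulationState":
        return SimulationState(self.t, self.ids, self.biomass.copy(), self.is_source.copy())


@dataclass
class SimulationResult:
    first_colonised: dict[int, int | None]
    steps_run: int
    trajectory: pd.DataFrame | None = None


def _sim_arrays(network: HabitatNetwork, config: ScenarioConfig):
    """Per-patch neighbour index/share/survival arrays, cached on the network."""
    key = (config.allocation, config.C_max, id(network.graph))
    cache = getattr(network, "_sim_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    ids = network.ids()
    pos = {pid: i for i, pid in enumerate(ids)}
    nbr, share, surv = [], [], []
    for pid in ids:
        ns = network.neighbours(pid)
        costs = np.array([network.edge_cost(pid, u) for u in ns])
        s = 1.0 - costs / config.C_max if network.C_max is None else 1.0 - costs / network.C_max
        if config.allocation == "survival":
            w = s.copy()
        else:  # inverse_cost
            w = 1.0 / costs
        total = w.sum()
        nbr.append(np.array([pos[u] for u in ns], dtype=np.intp))
        share.append(w / total if total > 0 else w)
        surv.append(s)
    K = np.array([network.K(pid) for pid in ids])
    data = (ids, pos, nbr, share, surv, K)
    network._sim_cache = (key, data)
    return data


def init_state(network: HabitatNetwork, sources) -> SimulationState:
    """State at t = 0: sources hold K and are flagged; all others are empty."""
    ids = network.ids()
    pos = {pid: i for i, pid in enumerate(ids)}
    biomass = np.zeros(len(ids))
    is_source = np.zeros(len(ids), dtype=bool)
    for q in sources:
        if q not in pos:
            raise ValueError(f"unknown patch id {q} in sources")
        is_source[pos[q]] = True
        biomass[pos[q]] = network.K(q)
    return SimulationState(t=0, ids=ids, biomass=biomass, is_source=is_source)


def step(
    state: SimulationState,
    network: HabitatNetwork,
    config: ScenarioConfig,
) -> SimulationState:
    """Advance the simulation one time step (synchronous update)."""
    ids, pos, nbr, share, surv, K = _sim_arrays(network, config)
    n = len(ids)
    arrivals = np.zeros(n)
    for v in np.flatnonzero(state.is_source):
        if nbr[v].size == 0:
            continue
        pool = config.S_DIS * (K[v] if config.growth == "instant" else state.biomass[v])
        np.add.at(arrivals, nbr[v], pool * share[v] * surv[v])
    arrivals[state.is_source] = 0.0  # immigration into occupied patches is lost

    biomass = state.biomass.copy()
    vacant = ~state.is_source
    biomass[vacant] += arrivals[vacant]
    newly = vacant & (biomass >= config.T_SH - 1e-12)
    is_source = state.is_source | newly
    if config.growth == "instant":
        biomass[is_source] = K[is_source]
    else:
        grow = is_source & (biomass < K)
        biomass[grow] += config.growth_rate * biomass[grow] * (1.0 - biomass[grow] / K[grow])
        np.minimum(biomass, K, out=biomass)
    return SimulationState(t=state.t + 1, ids=ids, biomass=biomass, is_source=is_source)


def run_simulation(
    network: HabitatNetwork,
    sources,
    config: ScenarioConfig,
    record_trajectory: bool = False,
) -> SimulationResult:
    """Iterate the step rule up to ``sim_max_steps`` and record first
    colonisation times (the step at which a patch's source flag first
    becomes true; initial sources are colonised at step 0)."""
    state = init_state(network, sources)
    ids = state.ids
    first = {pid: (0 if state.is_source[i] else None) for i, pid in enumerate(ids)}
    rows = []
    if record_trajectory:
        rows.extend({"t": 0, "patch_id": pid, "biomass": float(state.biomass[i])} for i, pid in enumerate(ids))
    steps_run = 0
    for _ in range(config.sim_max_steps):
        prev_sources = state.is_source
        state = step(state, network, config)
        steps_run = state.t
        for i in np.flatnonzero(state.is_source & ~prev_sources):
            first[ids[i]] = state.t
        if record_trajectory:
            rows.extend(
                {"t": state.t, "patch_id": pid, "biomass": float(state.biomass[i])}
                for i, pid in enumerate(ids)
            )
        if state.is_source.all():
            break
    trajectory = pd.DataFrame(rows) if record_trajectory else None
    return SimulationResult(first_colonised=first, steps_run=steps_run, trajectory=trajectory)


def write_result_csv(result: SimulationResult, path: str) -> None:
    pd.DataFrame(
        [
            {"patch_id": pid, "first_colonised_step": ("" if t is None else t)}
            for pid, t in sorted(result.first_colonised.items())
        ]
    ).to_csv(path, index=False)
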