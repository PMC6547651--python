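"""Paired simulation / optimisation experiment and comparison statistics.

One habitat network is built per scenario; several random source sets and
destination patches are drawn; the simulation runs once per source set
(dispersal is undirected, so one run covers every destination) and the
optimisation once per (source set, destination) pair.  The comparison
statistics are the Pearson correlation between the optimal colonisation
time and the least-cost distance from the nearest (and the mean over all)
connected source(s), and the per-run speed factor t_sim / t_opt.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dispersal_sim import run_simulation
from .habitat_network import HabitatNetwork, build_network, select_patches
from .landscape import CostRaster, generate_landscape
from .optimiser import SolverTimeout, UnreachableDestinationError, minimum_colonisation_time
from .scenario import ScenarioConfig

log = logging.getLogger("dendriflow")


def build_scenario(config: ScenarioConfig) -> tuple[CostRaster, HabitatNetwork]:
    """Generate the landscape and the habitat network of a scenario."""
    raster = generate_landscape(config)
    patches = select_patches(raster, config)
    network = build_network(patches, raster, config)
    log.info(
        "scenario: %dx%d cells, %d aquatic, %d patches, %d edges",
        config.rows,
        config.cols,
        int(raster.aquatic_mask.sum()),
        network.n_patches,
        network.n_edges,
    )
    return raster, network


def draw_source_sets(network: HabitatNetwork, config: ScenarioConfig, n_sets: int) -> list[list[int]]:
    rng = config.rng("sources")
    ids = np.array(network.ids())
    n_src = int(math.floor(config.source_fraction * len(ids)))
    if n_src < 1:
        raise ValueError("source_fraction selects zero patches")
    return [sorted(int(i) for i in rng.choice(ids, size=n_src, replace=False)) for _ in range(n_sets)]


def draw_destinations(network: HabitatNetwork, config: ScenarioConfig, n_destinations: int) -> list[int]:
    rng = config.rng("destinations")
    ids = np.array(network.ids())
    if n_destinations > len(ids):
        raise ValueError(f"cannot draw {n_destinations} destinations from {len(ids)} patches")
    return sorted(int(i) for i in rng.choice(ids, size=n_destinations, replace=False))


def run_experiment(
    config: ScenarioConfig,
    n_source_sets: int,
    n_destinations: int,
    network: HabitatNetwork | None = None,
    solver: str = "highs",
    time_limit: float | None = None,
) -> pd.DataFrame:
    """One row per (source set, destination) pair.

    Columns: source_set_id, destination_id, t_opt, t_sim (NaN when the
    simulation never colonises the destination within ``sim_max_steps``),
    nearest_cost / mean_cost (least-cost network distances from the
    connected sources), status in {ok, censored, unreachable,
    dest_in_sources, timeout}.
    """
    if network is None:
        _, network = build_scenario(config)
    source_sets = draw_source_sets(network, config, n_source_sets)
    destinations = draw_destinations(network, config, n_destinations)

    # least-cost distance maps, one Dijkstra per destination
    dist_from = {
        d: nx.single_source_dijkstra_path_length(network.graph, d, weight="cost")
        for d in destinations
    }

    records = []
    for set_id, sources in enumerate(source_sets):
        sim = run_simulation(network, sources, config)
        for dest in destinations:
            dists = [dist_from[dest][q] for q in sources if q in dist_from[dest]]
            nearest = min(dists) if dists else np.nan
            mean = float(np.mean(dists)) if dists else np.nan
            rec = {
                "source_set_id": set_id,
                "destination_id": dest,
                "t_opt": np.nan,
                "t_sim": np.nan,
                "nearest_cost": nearest,
                "mean_cost": mean,
                "status": "ok",
            }
            if dest in sources:
                rec.update(t_opt=0.0, t_sim=0.0, status="dest_in_sources")
            elif not dists:
                rec["status"] = "unreachable"
            else:
                try:
                    t_opt, _ = minimum_colonisation_time(
                        network, sources, [dest], config, solver=solver, time_limit=time_limit
                    )
                    rec["t_opt"] = float(t_opt)
                except UnreachableDestinationError:  # pragma: no cover - guarded above
                    rec["status"] = "unreachable"
                except SolverTimeout:
                    rec["status"] = "timeout"
                    log.warning("solver timeout for source set %d, destination %d", set_id, dest)
                t_sim = sim.first_colonised[dest]
                if t_sim is None:
                    if rec["status"] == "ok":
                        rec["status"] = "censored"
                else:
                    rec["t_sim"] = float(t_sim)
            records.append(rec)
        log.info("source set %d/%d done", set_id + 1, len(source_sets))
    return pd.DataFrame(records)


def compare_models(records: pd.DataFrame) -> dict:
    """Summary statistics of a paired-run table.

    Pearson correlations are computed over every run with a defined
    optimisation outcome; the speed factor is the mean per-run ratio
    t_sim / t_opt over runs with both times defined and t_opt >= 1
    (the ratio is undefined for destinations that start colonised).
    """
    records = records.copy()
    for col in ("t_opt", "t_sim", "nearest_cost", "mean_cost"):
        records[col] = pd.to_numeric(records[col], errors="coerce")
    usable = records[np.isfinite(records["t_opt"]) & np.isfinite(records["nearest_cost"])]
    summary: dict = {
        "n_records": int(len(records)),
        "n_usable": int(len(usable)),
        "n_censored": int((records["status"] == "censored").sum()),
        "n_unreachable": int((records["status"] == "unreachable").sum()),
        "n_timeout": int((records["status"] == "timeout").sum()),
    }
    if len(usable) < 3:
        summary.update(r_nearest=None, r_mean=None, speed_factor_mean=None)
        return summary
    summary["r_nearest"] = float(stats.pearsonr(usable["t_opt"], usable["nearest_cost"])[0])
    summary["r_mean"] = float(stats.pearsonr(usable["t_opt"], usable["mean_cost"])[0])

    both = records[
        np.isfinite(records["t_opt"]) & np.isfinite(records["t_sim"]) & (records["t_opt"] >= 1)
    ]
    summary["n_zero_opt_excluded"] = int(
        (np.isfinite(records["t_opt"]) & np.isfinite(records["t_sim"]) & (records["t_opt"] < 1)).sum()
    )
    summary["n_ratio"] = int(len(both))
    if len(both):
        ratios = both["t_sim"] / both["t_opt"]
        summary["speed_factor_mean"] = float(ratios.mean())
        summary["speed_factor_median"] = float(ratios.median())
        summary["speed_factor_min"] = float(ratios.min())
        summary["speed_factor_max"] = float(ratios.max())
    else:
        summary["speed_factor_mean"] = None
    return summary


def scatter_figure(records: pd.DataFrame, xcol: str, ycol: str, path: str) -> None:
    """Scatter of paired runs with a least-squares line, written as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = records[np.isfinite(records[xcol]) & np.isfinite(records[ycol])]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data[xcol], data[ycol], s=8, c="k")
    if len(data) >= 2 and data[xcol].nunique() > 1:
        slope, intercept = np.polyfit(data[xcol], data[ycol], 1)
        xs = np.array([data[xcol].min(), data[xcol].max()])
        ax.plot(xs, slope * xs + intercept, color="grey")
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
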