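"""Synthetic landscape generation.

Produces the three ingredients of a scenario's cost surface:

* a spatially autocorrelated land-cover grid (agriculture / forest / urban)
  from a modified random-cluster neutral landscape model,
* a dendritic stream network — a 4-connected spanning tree of aquatic cells
  grown headward from a boundary outlet,
* the combined cost raster, where stream cells override the land-cover
  class and every cell costs what its class costs.

Rasters can be round-tripped through Esri ASCII grids with a JSON sidecar
recording class codes and costs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scenario import ScenarioConfig

AGRICULTURE, FOREST, URBAN, AQUATIC = 0, 1, 2, 3
CLASS_NAMES = ("agriculture", "forest", "urban", "aquatic")
#: land-cover classes produced by the neutral landscape model (aquatic is overlaid)
UPLAND_CLASSES = ("agriculture", "forest", "urban")


@dataclass
class CostRaster:
    """Land-cover grid with per-cell dispersal costs and an aquatic mask."""

    landcover: np.ndarray  # int8 class codes
    cost: np.ndarray  # float cost-units per cell
    aquatic_mask: np.ndarray  # bool

    @property
    def rows(self) -> int:
        return self.landcover.shape[0]

    @property
    def cols(self) -> int:
        return self.landcover.shape[1]

    def class_fractions(self) -> dict[str, float]:
        n = self.landcover.size
        return {
            name: float(np.count_nonzero(self.landcover == code)) / n
            for code, name in enumerate(CLASS_NAMES)
        }


def _as_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _normalise_proportions(proportions: dict[str, float]) -> np.ndarray:
    unknown = set(proportions) - set(UPLAND_CLASSES)
    if unknown:
        raise ValueError(f"unknown land-cover classes in proportions: {sorted(unknown)}")
    p = np.array([float(proportions.get(c, 0.0)) for c in UPLAND_CLASSES])
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    # Tolerate printed fractions such as 66.6/11.1/22.2% that sum to 0.999.
    if abs(total - 1.0) > 2e-3:
        raise ValueError(f"proportions must sum to 1, got {total:.6f}")
    return p / total


def generate_landcover(
    rows: int,
    cols: int,
    proportions: dict[str, float],
    seed,
    cluster_fill: float = 0.55,
) -> np.ndarray:
    """Generate a clustered land-cover grid with the requested class shares.

    Modified random-cluster neutral landscape model: cells are occupied
    independently with probability ``cluster_fill`` (kept below the
    4-neighbour percolation threshold so clusters stay finite), occupied
    cells are grouped into 4-connected clusters, clusters are assigned
    whole to classes so that class cell-counts track the requested
    proportions, and unoccupied cells copy the class of their nearest
    occupied cell.  Empirical class fractions converge to *proportions* as
    the grid grows.
    """
    p = _normalise_proportions(proportions)
    rng = _as_rng(seed)
    occupied = rng.random((rows, cols)) < cluster_fill
    if not occupied.any():
        occupied[rng.integers(rows), rng.integers(cols)] = True
    labels, n_clusters = ndimage.label(occupied)
    sizes = np.bincount(labels.ravel())[1:]  # cluster label l has size sizes[l-1]

    # Deficit-greedy assignment: each cluster goes to the class currently
    # furthest below its target share of occupied cells.
    targets = p * sizes.sum()
    assigned = np.zeros(3)
    cluster_class = np.zeros(n_clusters, dtype=np.int8)
    for lab in rng.permutation(n_clusters):
        c = int(np.argmax(targets - assigned))
        cluster_class[lab] = c
        assigned[c] += sizes[lab]

    grid = np.zeros((rows, cols), dtype=np.int8)
    grid[occupied] = cluster_class[labels[occupied] - 1]
    if not occupied.all():
        nearest = ndimage.distance_transform_edt(
            ~occupied, return_distances=False, return_indices=True
        )
        grid = grid[nearest[0], nearest[1]]
    return grid


def _neighbours4(r: int, c: int, rows: int, cols: int):
    if r > 0:
        yield r - 1, c
    if r < rows - 1:
        yield r + 1, c
    if c > 0:
        yield r, c - 1
    if c < cols - 1:
        yield r, c + 1


def random_boundary_cell(rows: int, cols: int, rng) -> tuple[int, int]:
    """Pick a uniformly random cell on the grid boundary."""
    rng = _as_rng(rng)
    side = int(rng.integers(4))
    if side == 0:
        return 0, int(rng.integers(cols))
    if side == 1:
        return rows - 1, int(rng.integers(cols))
    if side == 2:
        return int(rng.integers(rows)), 0
    return int(rng.integers(rows)), cols - 1


_DIRS = ((-1, 0), (0, 1), (1, 0), (0, -1))


def generate_stream_network(
    rows: int,
    cols: int,
    outlet: tuple[int, int],
    seed,
    target_cells: int | None = None,
    target_fraction: float | None = None,
    persistence: float = 0.95,
    branch_prob: float = 0.01,
) -> set[tuple[int, int]]:
    """Grow a dendritic stream network as a random 4-connected tree.

    Headward growth: channel tips advance one cell per event as persistent
    random walks (probability *persistence* of continuing straight,
    otherwise turning 90 degrees), occasionally spawning a new tip on an
    existing channel cell (*branch_prob*), starting from *outlet* on the
    grid boundary.  A cell is only added while it touches exactly one
    aquatic cell, so the aquatic set remains a spanning tree of itself
    (no 4-connected cycles).  Growth stops at the target cell count.
    """
    r0, c0 = outlet
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"outlet {outlet} is off the grid")
    if r0 not in (0, rows - 1) and c0 not in (0, cols - 1):
        raise ValueError(f"outlet {outlet} must lie on the grid boundary")
    if target_cells is None:
        if target_fraction is None:
            raise ValueError("one of target_cells / target_fraction is required")
        target_cells = int(round(target_fraction * rows * cols))
    if not 1 <= target_cells <= rows * cols:
        raise ValueError(f"stream target of {target_cells} cells is infeasible on a {rows}x{cols} grid")

    rng = _as_rng(seed)
    aquatic = np.zeros((rows, cols), dtype=bool)
    nbr_count = np.zeros((rows, cols), dtype=np.int32)
    cells: list[tuple[int, int]] = []

    def add(cell: tuple[int, int]) -> None:
        aquatic[cell] = True
        cells.append(cell)
        for nb in _neighbours4(*cell, rows, cols):
            nbr_count[nb] += 1

    def valid(cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < rows and 0 <= c < cols and not aquatic[cell] and nbr_count[cell] == 1

    add((r0, c0))
    # initial heading: into the grid
    if r0 == 0:
        head = 2
    elif r0 == rows - 1:
        head = 0
    elif c0 == 0:
        head = 1
    else:
        head = 3
    tips: list[tuple[tuple[int, int], int]] = [((r0, c0), head)]
    stalls = 0
    while len(cells) < target_cells:
        if tips:
            i = int(rng.integers(len(tips)))
            (r, c), d = tips[i]
            u = rng.random()
            if u < persistence:
                order = (d, (d + 1) % 4, (d + 3) % 4)
            elif u < persistence + (1 - persistence) / 2:
                order = ((d + 1) % 4, d, (d + 3) % 4)
            else:
                order = ((d + 3) % 4, d, (d + 1) % 4)
            for nd in order:
                cell = (r + _DIRS[nd][0], c + _DIRS[nd][1])
                if valid(cell):
                    add(cell)
                    tips[i] = (cell, nd)
                    if rng.random() < branch_prob:
                        br, bc = cells[int(rng.integers(len(cells)))]
                        tips.append(((br, bc), int(rng.integers(4))))
                    break
            else:
                tips[i] = tips[-1]
                tips.pop()
        else:
            # all tips dead: restart from a random channel cell
            br, bc = cells[int(rng.integers(len(cells)))]
            nd = int(rng.integers(4))
            cell = (br + _DIRS[nd][0], bc + _DIRS[nd][1])
            if valid(cell):
                add(cell)
                tips.append((cell, nd))
                stalls = 0
            else:
                stalls += 1
                if stalls > 200 * rows * cols:
                    raise ValueError(
                        f"stream growth stalled at {len(cells)} of {target_cells} cells; "
                        "target infeasible"
                    )
    return set(cells)


def stream_adjacency_pairs(cells: set[tuple[int, int]]) -> int:
    """Count 4-adjacent pairs within *cells* (== len-1 for a tree)."""
    pairs = 0
    for r, c in cells:
        if (r + 1, c) in cells:
            pairs += 1
        if (r, c + 1) in cells:
            pairs += 1
    return pairs


def build_cost_raster(
    landcover: np.ndarray,
    streams: set[tuple[int, int]],
    config: ScenarioConfig,
) -> CostRaster:
    """Overlay the stream network on a land-cover grid and assign costs."""
    rows, cols = landcover.shape
    lc = landcover.astype(np.int8, copy=True)
    mask = np.zeros((rows, cols), dtype=bool)
    for r, c in streams:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"stream cell {(r, c)} is off the grid")
        mask[r, c] = True
    lc[mask] = AQUATIC
    lut = np.array(
        [config.agriculture_cost, config.forest_cost, config.urban_cost, config.aquatic_cost]
    )
    return CostRaster(landcover=lc, cost=lut[lc], aquatic_mask=mask)


def generate_landscape(config: ScenarioConfig) -> CostRaster:
    """Generate the full cost raster of a scenario from its named substreams."""
    lc = generate_landcover(
        config.rows,
        config.cols,
        config.proportions,
        seed=config.rng("landcover"),
        cluster_fill=config.cluster_fill,
    )
    stream_rng = config.rng("streams")
    outlet = random_boundary_cell(config.rows, config.cols, stream_rng)
    streams = generate_stream_network(
        config.rows,
        config.cols,
        outlet,
        seed=stream_rng,
        target_fraction=config.aquatic_fraction,
    )
    return build_cost_raster(lc, streams, config)


# -- Esri ASCII grid I/O ---------------------------------------------------


def write_asc(path: str, array: np.ndarray, cellsize: float = 100.0, nodata: float = -9999) -> None:
    rows, cols = array.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt="%g")


def read_asc(path: str) -> tuple[np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, value = lines[i].split()[:2]
        header[key.lower()] = float(value)
        i += 1
    array = np.loadtxt(lines[i:])
    array = np.atleast_2d(array)
    if array.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {array.shape} disagrees with header")
    return array, header.get("cellsize", 1.0)


def write_raster(prefix: str, raster: CostRaster, config: ScenarioConfig) -> None:
    """Write landcover as .asc plus a JSON sidecar with class codes/costs."""
    write_asc(f"{prefix}.asc", raster.landcover, cellsize=config.cell_size_m)
    sidecar = {
        "classes": {name: code for code, name in enumerate(CLASS_NAMES)},
        "costs": {
            "agriculture": config.agriculture_cost,
            "forest": config.forest_cost,
            "urban": config.urban_cost,
            "aquatic": config.aquatic_cost,
        },
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_raster(prefix: str, config: ScenarioConfig) -> CostRaster:
    lc, _ = read_asc(f"{prefix}.asc")
    lc = lc.astype(np.int8)
    streams = {(int(r), int(c)) for r, c in np.argwhere(lc == AQUATIC)}
    return build_cost_raster(np.where(lc == AQUATIC, AGRICULTURE, lc).astype(np.int8), streams, config)
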