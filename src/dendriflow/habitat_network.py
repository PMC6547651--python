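"""Habitat patch selection and least-cost-path network construction.

Habitat patches are a random subset of aquatic cells with random habitat
qualities; their carrying capacity is ``K = quality * K_max``.  Two patches
are connected iff the least accumulated traversal cost between their cells
(8-connected moves, cost of a move = arithmetic mean of the two cell costs,
x sqrt(2) for diagonals) is strictly below the budget ``C_max``.  The
result is an undirected weighted graph G = (V, E) with edge costs
0 < C(e) < C_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .landscape import CostRaster
from .scenario import ScenarioConfig

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class HabitatPatch:
    id: int
    cell: tuple[int, int]
    quality: float  # dimensionless in (0, 1]
    K: float  # carrying capacity, biomass units


class HabitatNetwork:
    """Undirected weighted graph of habitat patches.

    Nodes are patch ids; each edge carries the least-cost-path cost
    ``cost`` between the two patches, strictly below ``C_max`` when a
    budget is given.
    """

    def __init__(
        self,
        patches,
        edges=(),
        C_max: float | None = None,
    ):
        self.patches: dict[int, HabitatPatch] = {}
        self.C_max = C_max
        self.graph = nx.Graph()
        for p in patches:
            if p.K <= 0:
                raise ValueError(f"patch {p.id} has non-positive carrying capacity")
            if p.id in self.patches:
                raise ValueError(f"duplicate patch id {p.id}")
            self.patches[p.id] = p
            self.graph.add_node(p.id, row=p.cell[0], col=p.cell[1], quality=p.quality, K=p.K)
        for u, v, cost in edges:
            self.add_edge(u, v, cost)

    def add_edge(self, u: int, v: int, cost: float) -> None:
        if u == v:
            raise ValueError(f"self-loop on patch {u}")
        if u not in self.patches or v not in self.patches:
            raise ValueError(f"edge ({u}, {v}) references an unknown patch")
        if cost <= 0:
            raise ValueError(f"edge ({u}, {v}) has non-positive cost {cost}")
        if self.C_max is not None and cost >= self.C_max:
            raise ValueError(f"edge ({u}, {v}) cost {cost} is not below C_max {self.C_max}")
        self.graph.add_edge(u, v, cost=float(cost))

    # -- queries -----------------------------------------------------------

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def ids(self) -> list[int]:
        return sorted(self.patches)

    def K(self, patch_id: int) -> float:
        return self.patches[patch_id].K

    def neighbours(self, patch_id: int) -> list[int]:
        return sorted(self.graph.neighbors(patch_id))

    def edge_cost(self, u: int, v: int) -> float:
        return self.graph.edges[u, v]["cost"]

    def edges(self):
        for u, v, d in self.graph.edges(data=True):
            yield (u, v, d["cost"])

    def subnetwork(self, keep) -> "HabitatNetwork":
        """Induced subnetwork on the given patch ids."""
        keep = set(keep)
        patches = [p for pid, p in self.patches.items() if pid in keep]
        edges = [(u, v, c) for u, v, c in self.edges() if u in keep and v in keep]
        return HabitatNetwork(patches, edges, C_max=self.C_max)

    # -- persistence -------------------------------------------------------

    def to_graphml(self, path: str) -> None:
        g = self.graph.copy()
        g.graph["C_max"] = float(self.C_max) if self.C_max is not None else -1.0
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path: str) -> "HabitatNetwork":
        g = nx.read_graphml(path)
        c_max = float(g.graph.get("C_max", -1.0))
        patches = [
            HabitatPatch(
                id=int(n),
                cell=(int(d["row"]), int(d["col"])),
                quality=float(d["quality"]),
                K=float(d["K"]),
            )
            for n, d in g.nodes(data=True)
        ]
        edges = [(int(u), int(v), float(d["cost"])) for u, v, d in g.edges(data=True)]
        return cls(patches, edges, C_max=None if c_max < 0 else c_max)

    def to_csvs(self, nodes_path: str, edges_path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {"id": p.id, "row": p.cell[0], "col": p.cell[1], "quality": p.quality, "K": p.K}
                for p in self.patches.values()
            ]
        ).to_csv(nodes_path, index=False)
        pd.DataFrame(
            [{"u": u, "v": v, "cost": c} for u, v, c in self.edges()]
        ).to_csv(edges_path, index=False)


# -- patch selection -------------------------------------------------------


def select_patches(
    raster: CostRaster,
    config: ScenarioConfig,
    rng=None,
    quality_rng=None,
) -> list[HabitatPatch]:
    """Sample ``floor(habitat_fraction * n_aquatic)`` aquatic cells as patches.

    Qualities are drawn Uniform(0.5, 1.0] so that no patch has a degenerate
    near-zero carrying capacity; ``K = quality * K_max``.
    """
    cells = np.argwhere(raster.aquatic_mask)
    n_aquatic = len(cells)
    if n_aquatic == 0:
        raise ValueError("raster has no aquatic cells; cannot place habitat patches")
    n = int(math.floor(config.habitat_fraction * n_aquatic))
    if n < 1:
        raise ValueError(
            f"habitat_fraction {config.habitat_fraction} selects zero of {n_aquatic} aquatic cells"
        )
    rng = config.rng("patches") if rng is None else np.random.default_rng(rng)
    quality_rng = config.rng("qualities") if quality_rng is None else np.random.default_rng(quality_rng)
    chosen = rng.choice(n_aquatic, size=n, replace=False)
    chosen_cells = cells[np.sort(chosen)]  # stable row-major id order
    qualities = 0.5 + 0.5 * quality_rng.random(n)
    return [
        HabitatPatch(id=i, cell=(int(r), int(c)), quality=float(q), K=float(q * config.K_max))
        for i, ((r, c), q) in enumerate(zip(chosen_cells, qualities))
    ]


# -- least-cost paths on the raster ---------------------------------------


def grid_cost_graph(cost: np.ndarray) -> coo_matrix:
    """Sparse 8-connected traversal graph of a cost raster.

    Moving between two cells costs the mean of their per-cell costs,
    multiplied by sqrt(2) for diagonal moves; the matrix holds each
    undirected link once (use ``directed=False`` in csgraph routines).
    """
    rows, cols = cost.shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    heads, tails, weights = [], [], []
    for a, b, mult in (
        (idx[:, :-1], idx[:, 1:], 1.0),
        (idx[:-1, :], idx[1:, :], 1.0),
        (idx[:-1, :-1], idx[1:, 1:], _SQRT2),
        (idx[:-1, 1:], idx[1:, :-1], _SQRT2),
    ):
        a = a.ravel()
        b = b.ravel()
        tails.append(a)
        heads.append(b)
        weights.append((cost.ravel()[a] + cost.ravel()[b]) * 0.5 * mult)
    n = rows * cols
    return coo_matrix(
        (np.concatenate(weights), (np.concatenate(tails), np.concatenate(heads))), shape=(n, n)
    )


def least_cost_distance(
    raster: CostRaster,
    a: tuple[int, int],
    b: tuple[int, int],
    return_path: bool = False,
):
    """Minimum accumulated traversal cost between two cells (symmetric).

    With ``return_path=True`` also returns one optimal cell sequence.
    """
    cols = raster.cols
    ia = a[0] * cols + a[1]
    ib = b[0] * cols + b[1]
    if a == b:
        return (0.0, [a]) if return_path else 0.0
    graph = grid_cost_graph(raster.cost)
    if return_path:
        dist, pred = dijkstra(graph, directed=False, indices=ia, return_predecessors=True)
        path_nodes = []
        node = ib
        while node != -9999 and node != ia:
            path_nodes.append(node)
            node = pred[node]
        path_nodes.append(ia)
        path = [(int(n) // cols, int(n) % cols) for n in reversed(path_nodes)]
        return float(dist[ib]), path
    dist = dijkstra(graph, directed=False, indices=ia)
    return float(dist[ib])


def build_network(
    patches,
    raster: CostRaster,
    config: ScenarioConfig,
) -> HabitatNetwork:
    """Connect patches whose least-cost distance is strictly below ``C_max``.

    One truncated Dijkstra sweep per patch (accumulated cost capped at the
    budget) rather than an all-pairs computation over cells.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("at least one patch is required")
    cols = raster.cols
    nodes = np.array([p.cell[0] * cols + p.cell[1] for p in patches])
    graph = grid_cost_graph(raster.cost)
    dist = dijkstra(graph, directed=False, indices=nodes, limit=config.C_max)
    net = HabitatNetwork(patches, C_max=config.C_max)
    for i in range(len(patches)):
        di = dist[i]
        for j in range(i + 1, len(patches)):
            d = di[nodes[j]]
            if np.isfinite(d) and d < config.C_max:
                net.add_edge(patches[i].id, patches[j].id, float(d))
    return net
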