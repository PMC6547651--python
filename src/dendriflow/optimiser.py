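"""Quickest-flow MIP lower bounds on colonisation time.

The habitat network is unrolled into a time-expanded network: one copy of
every patch per time layer t = 0..T, two directed movement arcs per habitat
edge and layer, a zero-cost holdover arc between consecutive copies of the
same patch, and a super source Q feeding the layer-0 copies of the initial
source habitats.  A mixed integer program on this network minimises
``sum_t t * x(t)`` subject to

1. a copy may be flagged colonised only if its incoming biomass (new
   arrivals plus the holdover from the previous layer) reaches ``T_SH``;
2. all biomass held in a patch is forwarded to its next copy;
3. survival-scaled emission of a copy is capped by its dispersal capacity
   ``u(v) = S_DIS * K(v)`` when colonised (and by zero otherwise) on top
   of forwarding its inflow — the emission-cap constraint that makes the
   optimum a provable lower bound on any dispersal behaviour;
4. every initial source receives exactly ``T_SH`` from Q at layer 0;
5. a layer may be flagged only if every destination is colonised in it;
6. some layer must be flagged.

The minimum flagged layer is the minimum colonisation time.  The time
horizon is chosen from serial fill-time bounds along cost-shortest paths
(TH1 for the nearest source, TH2 for the second nearest), capped at a
block of 30 layers and escalated by further blocks on infeasibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .habitat_network import HabitatNetwork
from .scenario import ScenarioConfig

log = logging.getLogger("dendriflow")

#: pseudo patch id of the super source in extracted routes
SUPER_SOURCE = "Q"


class UnreachableDestinationError(ValueError):
    """The destination is not graph-reachable from any initial source."""


class ConsistencyError(RuntimeError):
    """The MIP was infeasible at a horizon that admits a known feasible schedule."""


class SolverTimeout(RuntimeError):
    """The MILP solver hit its time limit without proving optimality."""


class AuditError(RuntimeError):
    """A solver answer violated the model constraints on re-check."""


# -- time-expanded network -------------------------------------------------


class TimeExpandedNetwork:
    """Layered digraph with per-copy capacities and per-arc survival factors.

    Copies are indexed ``v_local * (T+1) + t``; the super source Q is the
    last index.  Arc kinds: 0 movement, 1 holdover, 2 super-source.
    """

    MOVE, HOLD, SOURCE = 0, 1, 2

    def __init__(self, network: HabitatNetwork, sources, T: int, config: ScenarioConfig):
        if T < 1:
            raise ValueError(f"time horizon must be >= 1, got {T}")
        sources = sorted(set(sources))
        if not sources:
            raise ValueError("at least one initial source habitat is required")
        for q in sources:
            if q not in network.patches:
                raise ValueError(f"unknown source patch id {q}")
        c_max = network.C_max if network.C_max is not None else config.C_max
        self.network = network
        self.sources = sources
        self.T = T
        self.C_max = c_max
        self.patch_ids = network.ids()
        self.local = {pid: i for i, pid in enumerate(self.patch_ids)}
        n = len(self.patch_ids)
        self.n_patches = n
        self.Q = n * (T + 1)
        self.n_copies = n * (T + 1) + 1
        self.u = np.array([config.S_DIS * network.K(pid) for pid in self.patch_ids])

        tails, heads, costs, kinds = [], [], [], []
        edge_list = sorted((min(u, v), max(u, v), c) for u, v, c in network.edges())
        for t in range(T):
            for u, v, c in edge_list:
                if c >= c_max:
                    raise ValueError(f"edge ({u}, {v}) cost {c} is not below C_max {c_max}")
                iu, iv = self.local[u], self.local[v]
                tails += [iu * (T + 1) + t, iv * (T + 1) + t]
                heads += [iv * (T + 1) + t + 1, iu * (T + 1) + t + 1]
                costs += [c, c]
                kinds += [self.MOVE, self.MOVE]
            for pid in self.patch_ids:
                i = self.local[pid]
                tails.append(i * (T + 1) + t)
                heads.append(i * (T + 1) + t + 1)
                costs.append(0.0)
                kinds.append(self.HOLD)
        for q in sources:
            tails.append(self.Q)
            heads.append(self.local[q] * (T + 1))
            costs.append(0.0)
            kinds.append(self.SOURCE)

        self.arc_tail = np.array(tails, dtype=np.intp)
        self.arc_head = np.array(heads, dtype=np.intp)
        self.arc_cost = np.array(costs)
        self.arc_kind = np.array(kinds, dtype=np.int8)
        self.arc_surv = 1.0 - self.arc_cost / c_max  # 1.0 for artificial arcs
        self.n_arcs = len(tails)
        assert self.n_arcs == T * (2 * network.n_edges + n) + len(sources)

        self.in_arcs: list[list[int]] = [[] for _ in range(self.n_copies)]
        self.out_arcs: list[list[int]] = [[] for _ in range(self.n_copies)]
        for e in range(self.n_arcs):
            self.out_arcs[self.arc_tail[e]].append(e)
            self.in_arcs[self.arc_head[e]].append(e)

    def copy_index(self, patch_id: int, t: int) -> int:
        return self.local[patch_id] * (self.T + 1) + t

    def copy_label(self, copy: int):
        if copy == self.Q:
            return (SUPER_SOURCE, -1)
        return (self.patch_ids[copy // (self.T + 1)], copy % (self.T + 1))


def build_ten(network: HabitatNetwork, sources, T: int, config: ScenarioConfig) -> TimeExpandedNetwork:
    return TimeExpandedNetwork(network, sources, T, config)


# -- MIP formulation -------------------------------------------------------


@dataclass
class MIPInstance:
    ten: TimeExpandedNetwork
    H_dest: list[int]
    c: np.ndarray
    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray

    @property
    def n_f(self) -> int:
        return self.ten.n_arcs

    @property
    def n_xc(self) -> int:
        return self.ten.n_patches * (self.ten.T + 1)

    @property
    def n_xl(self) -> int:
        return self.ten.T + 1

    def split(self, z: np.ndarray):
        f = z[: self.n_f]
        xc = z[self.n_f : self.n_f + self.n_xc]
        xl = z[self.n_f + self.n_xc :]
        return f, xc, xl


def earliest_layer_bounds(
    network: HabitatNetwork, sources, config: ScenarioConfig
) -> dict[int, int]:
    """Lower bound on the layer at which each patch can first be colonised.

    Relaxed earliest-arrival dynamics: every neighbour u is assumed to emit
    its full capacity ``S_DIS K(u)`` towards v from the moment u itself
    could first be colonised, scaled by the survival factor of the
    connection.  The earliest integer layer at which these idealised
    arrivals can accumulate to ``T_SH`` dominates any feasible dispersal
    behaviour, so it is a valid bound; it is exact on chains.  Computed
    with a Dijkstra-style sweep (labels are final when popped because a
    patch's bound only depends on strictly smaller neighbour bounds).
    """
    import heapq

    c_max = network.C_max if network.C_max is not None else config.C_max
    sources = set(sources)
    rate = {
        (u, v): config.S_DIS * network.K(u) * (1.0 - network.edge_cost(u, v) / c_max)
        for u, v, _ in network.edges()
    }
    for (u, v), r in list(rate.items()):
        rate[v, u] = config.S_DIS * network.K(v) * (1.0 - network.edge_cost(u, v) / c_max)

    def arrival(settled_nbrs: list[tuple[int, float]]) -> float:
        # settled_nbrs: (label, rate) sorted by label; earliest integer t
        # with sum_u rate_u * (t - label_u)_+ >= T_SH
        best = math.inf
        total_rate = 0.0
        offset = 0.0  # sum rate_u * label_u over active neighbours
        for k, (lab, r) in enumerate(settled_nbrs):
            total_rate += r
            offset += r * lab
            t = math.ceil((config.T_SH + offset) / total_rate - 1e-9)
            t = max(t, lab + 1)
            nxt = settled_nbrs[k + 1][0] if k + 1 < len(settled_nbrs) else math.inf
            if t <= nxt:  # consistent with the set of active neighbours
                best = min(best, t)
        return best

    bound = {v: (0 if v in sources else math.inf) for v in network.ids()}
    settled: set[int] = set()
    heap = [(0, v) for v in sources]
    heapq.heapify(heap)
    while heap:
        t, u = heapq.heappop(heap)
        if u in settled or t > bound[u]:
            continue
        settled.add(u)
        for v in network.neighbours(u):
            if v in settled:
                continue
            nbrs = sorted(
                (bound[w], rate[w, v]) for w in network.neighbours(v) if w in settled
            )
            cand = arrival(nbrs)
            if cand < bound[v]:
                bound[v] = cand
                heapq.heappush(heap, (cand, v))
    return bound


def serial_fill_upper_bounds(
    network: HabitatNetwork, sources, config: ScenarioConfig
) -> dict[int, float]:
    """Upper bound on the optimal colonisation layer of every patch.

    Shortest path from the initial sources in the serial fill-time metric,
    where hop u -> v takes ``ceil(T_SH / (S_DIS K(u) (1 - C/C_max)))``
    steps: colonising patches one at a time along that path is a feasible
    schedule, so the optimum can never exceed it.  Unreachable patches map
    to infinity.
    """
    import heapq

    c_max = network.C_max if network.C_max is not None else config.C_max
    bound = {v: math.inf for v in network.ids()}
    heap = []
    for q in set(sources):
        bound[q] = 0
        heap.append((0, q))
    heapq.heapify(heap)
    while heap:
        t, u = heapq.heappop(heap)
        if t > bound[u]:
            continue
        rate_base = network.K(u) * config.S_DIS
        for v in network.neighbours(u):
            surv = 1.0 - network.edge_cost(u, v) / c_max
            cand = t + math.ceil(config.T_SH / (rate_base * surv) - 1e-9)
            if cand < bound[v]:
                bound[v] = cand
                heapq.heappush(heap, (cand, v))
    return bound


def build_mip(
    ten: TimeExpandedNetwork,
    H_dest,
    config: ScenarioConfig,
    strengthen: bool = True,
) -> MIPInstance:
    """Assemble objective, constraint matrix, bounds and integrality.

    With ``strengthen`` (default), optimum-preserving reductions are
    applied on top of the core model: copies of initial sources are pinned
    colonised (they hold ``T_SH`` from layer 0 on), copies below the
    earliest-arrival bound of their patch are pinned vacant, and monotone
    colonisation cuts ``x(v_t) <= x(v_{t+1})`` are added (inflow never
    decreases along the holdover chain, so colonisation persists).
    """
    H_dest = sorted(set(H_dest))
    if not H_dest:
        raise ValueError("at least one destination habitat is required")
    for d in H_dest:
        if d not in ten.local:
            raise ValueError(f"unknown destination patch id {d}")
    T, n = ten.T, ten.n_patches
    n_f = ten.n_arcs
    n_xc = n * (T + 1)
    n_xl = T + 1
    off_xc = n_f
    off_xl = n_f + n_xc

    rows, cols, vals = [], [], []
    row_lb, row_ub = [], []
    r = 0

    def emit(entries, lb, ub):
        nonlocal r
        for j, a in entries:
            rows.append(r)
            cols.append(j)
            vals.append(a)
        row_lb.append(lb)
        row_ub.append(ub)
        r += 1

    # (1) colonisation requires inflow >= T_SH:  T_SH*x(v_t) - inflow <= 0
    for copy in range(n_xc):
        entries = [(off_xc + copy, config.T_SH)]
        entries += [(e, -1.0) for e in ten.in_arcs[copy]]
        emit(entries, -np.inf, 0.0)

    # (2) the holdover arc forwards all inflow of the previous copy (t = 1..T)
    for i in range(n):
        for t in range(1, T + 1):
            prev = i * (T + 1) + t - 1
            hold = next(e for e in ten.out_arcs[prev] if ten.arc_kind[e] == ten.HOLD)
            entries = [(hold, 1.0)]
            entries += [(e, -1.0) for e in ten.in_arcs[prev]]
            emit(entries, 0.0, 0.0)

    # (3) survival-scaled outflow <= u(v)*x(v_t) + inflow  (all copies but Q)
    for copy in range(n_xc):
        i = copy // (T + 1)
        entries = [(e, 1.0 / ten.arc_surv[e]) for e in ten.out_arcs[copy]]
        entries.append((off_xc + copy, -ten.u[i]))
        entries += [(e, -1.0) for e in ten.in_arcs[copy]]
        emit(entries, -np.inf, 0.0)

    # (5) a layer is flagged only when every destination is colonised in it
    for t in range(T + 1):
        entries = [(off_xl + t, float(len(H_dest)))]
        entries += [(off_xc + ten.copy_index(d, t), -1.0) for d in H_dest]
        emit(entries, -np.inf, 0.0)

    # (6) some layer must be flagged
    emit([(off_xl + t, 1.0) for t in range(T + 1)], 1.0, np.inf)

    if strengthen:
        # monotone colonisation cuts: once colonised, a patch stays colonised
        for i in range(n):
            for t in range(T):
                emit(
                    [(off_xc + i * (T + 1) + t, 1.0), (off_xc + i * (T + 1) + t + 1, -1.0)],
                    -np.inf,
                    0.0,
                )

    n_var = n_f + n_xc + n_xl
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(r, n_var)).tocsr()

    var_lb = np.zeros(n_var)
    var_ub = np.full(n_var, np.inf)
    # (4) exactly T_SH is injected into each initial source at layer 0
    source_arcs = np.flatnonzero(ten.arc_kind == ten.SOURCE)
    var_lb[source_arcs] = config.T_SH
    var_ub[source_arcs] = config.T_SH
    var_ub[off_xc:] = 1.0
    integrality = np.zeros(n_var)
    integrality[off_xc:] = 1.0

    if strengthen:
        for q in ten.sources:
            i = ten.local[q]
            var_lb[off_xc + i * (T + 1) : off_xc + (i + 1) * (T + 1)] = 1.0
        bounds_by_patch = earliest_layer_bounds(ten.network, ten.sources, config)
        cuts = np.zeros(n, dtype=int)
        for pid, t_min in bounds_by_patch.items():
            i = ten.local[pid]
            cut = min(int(t_min), T + 1) if np.isfinite(t_min) else T + 1
            if cut > 0 and pid not in ten.sources:
                cuts[i] = cut
                var_ub[off_xc + i * (T + 1) : off_xc + i * (T + 1) + cut] = 0.0
        # a vacant copy cannot emit, so movement arcs out of pinned-vacant
        # copies carry no flow
        move = ten.arc_kind == ten.MOVE
        tail_i = ten.arc_tail[move] // (T + 1)
        tail_t = ten.arc_tail[move] % (T + 1)
        dead = np.flatnonzero(move)[tail_t < cuts[tail_i]]
        var_ub[dead] = 0.0

    c = np.zeros(n_var)
    c[off_xl : off_xl + T + 1] = np.arange(T + 1, dtype=float)

    return MIPInstance(
        ten=ten,
        H_dest=H_dest,
        c=c,
        A=A,
        row_lb=np.array(row_lb),
        row_ub=np.array(row_ub),
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
    )


@dataclass
class MIPSolution:
    status: str  # "optimal" | "infeasible" | "timeout"
    t_star: int | None = None
    f: np.ndarray | None = None
    x_copy: np.ndarray | None = None
    x_layer: np.ndarray | None = None
    layer_hits: set[int] = field(default_factory=set)
    objective: float | None = None
    H_dest: list[int] = field(default_factory=list)


def solve_mip(
    instance: MIPInstance,
    solver: str = "highs",
    time_limit: float | None = None,
    feasibility_only: bool = False,
) -> MIPSolution:
    """Solve the instance and audit the answer before reporting it.

    The objective is integer-valued, so a relative optimality gap below
    ``1/T`` certifies the exact optimum.  A time-limit hit is reported as
    an explicit timeout, never as a silent wrong answer.
    """
    if solver != "highs":
        raise ValueError(f"unknown solver {solver!r}; available: 'highs'")
    # The objective is integer-valued and bounded by T, so a relative gap
    # below 1/T certifies an absolute gap below 1, i.e. exact optimality.
    options = {"mip_rel_gap": 0.9 / max(1, instance.n_xl - 1)}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=np.zeros_like(instance.c) if feasibility_only else instance.c,
        constraints=LinearConstraint(instance.A, instance.row_lb, instance.row_ub),
        bounds=Bounds(instance.var_lb, instance.var_ub),
        integrality=instance.integrality,
        options=options,
    )
    if res.status == 2:
        return MIPSolution(status="infeasible")
    if res.status == 1:
        raise SolverTimeout(f"MILP solver hit its time limit ({time_limit} s)")
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    f, xc, xl = instance.split(res.x)
    xc = np.round(xc)
    xl = np.round(xl)
    violations = audit_solution(instance, f, xc, xl)
    if violations:
        raise AuditError("solver answer violates constraints: " + "; ".join(violations[:5]))
    hits = {int(t) for t in np.flatnonzero(xl > 0.5)}
    return MIPSolution(
        status="optimal",
        t_star=min(hits),
        f=f,
        x_copy=xc,
        x_layer=xl,
        layer_hits=hits,
        objective=float(res.fun),
        H_dest=list(instance.H_dest),
    )


def audit_solution(
    instance: MIPInstance,
    f: np.ndarray,
    xc: np.ndarray,
    xl: np.ndarray,
    tol: float = 1e-6,
) -> list[str]:
    """Re-check constraints (1)-(6) by direct arithmetic on the flows.

    Returns a list of human-readable violations (empty when clean).  The
    check recomputes every sum from the time-expanded network itself, not
    from the solver's constraint matrix.
    """
    ten = instance.ten
    config_TSH = instance.var_lb[np.flatnonzero(ten.arc_kind == ten.SOURCE)]
    T_SH = float(config_TSH[0]) if len(config_TSH) else 0.0
    T, n = ten.T, ten.n_patches
    bad: list[str] = []
    scale = max(1.0, float(np.abs(f).max(initial=0.0)))
    tol = tol * scale

    inflow = np.zeros(ten.n_copies)
    np.add.at(inflow, ten.arc_head, f)
    out_scaled = np.zeros(ten.n_copies)
    np.add.at(out_scaled, ten.arc_tail, f / ten.arc_surv)

    if np.any(f < -tol):
        bad.append("negative flow")
    for copy in range(n * (T + 1)):
        i = copy // (T + 1)
        if T_SH * xc[copy] > inflow[copy] + tol:
            bad.append(f"(1) violated at copy {ten.copy_label(copy)}")
        if out_scaled[copy] > ten.u[i] * xc[copy] + inflow[copy] + tol:
            bad.append(f"(3) violated at copy {ten.copy_label(copy)}")
    for e in np.flatnonzero(ten.arc_kind == ten.HOLD):
        prev = ten.arc_tail[e]
        if abs(f[e] - inflow[prev]) > tol:
            bad.append(f"(2) violated at copy {ten.copy_label(prev)}")
    for e in np.flatnonzero(ten.arc_kind == ten.SOURCE):
        if abs(f[e] - T_SH) > tol:
            bad.append(f"(4) violated on arc from Q to {ten.copy_label(ten.arc_head[e])}")
    for t in range(T + 1):
        if xl[t] > 0.5:
            for d in instance.H_dest:
                if xc[ten.copy_index(d, t)] < 0.5:
                    bad.append(f"(5) violated at layer {t}: destination {d} not colonised")
    if xl.sum() < 1 - tol:
        bad.append("(6) violated: no layer flagged")
    for z in np.concatenate([xc, xl]):
        if min(abs(z), abs(z - 1.0)) > 1e-6:
            bad.append("binary variable not integral")
            break
    return bad


# -- route extraction ------------------------------------------------------


@dataclass
class RoutePath:
    steps: list[tuple]  # [(patch_id | "Q", t), ...] with strictly increasing t
    amount: float


@dataclass
class ColonisationRoute:
    paths: list[RoutePath]
    residual: float = 0.0  # positive flow not decomposable into origin->destination paths


def extract_route(solution: MIPSolution, ten: TimeExpandedNetwork) -> ColonisationRoute:
    """Decompose the positive flows into time-stamped paths into the
    destination copies at the optimal layer.

    Paths are extracted greedily, earliest-arriving first, starting from Q
    or from any colonised copy (where new biomass is generated); each path
    carries the bottleneck residual flow along it.  Residual flow that
    cannot be decomposed (degenerate optima with cycles through holdover
    chains) is reported, never raised.
    """
    if solution.status != "optimal":
        raise ValueError("route extraction requires an optimal solution")
    residual = solution.f.copy()
    t_star = solution.t_star
    dest_copies = []
    tol = 1e-9 * max(1.0, float(residual.max(initial=1.0)))

    origins = {ten.Q} | {
        int(c) for c in np.flatnonzero(solution.x_copy > 0.5)
    }
    if solution.H_dest:
        xl_dests = {ten.copy_index(d, t_star) for d in solution.H_dest}
    else:
        # fall back to every copy flagged colonised at the optimal layer
        xl_dests = {
            copy
            for copy in range(ten.n_patches * (ten.T + 1))
            if ten.copy_label(copy)[1] == t_star and solution.x_copy[copy] > 0.5
        }
    origins -= xl_dests

    paths: list[RoutePath] = []
    for _ in range(ten.n_arcs):
        targets = [c for c in xl_dests if any(residual[e] > tol for e in ten.in_arcs[c])]
        if not targets:
            break
        # BFS over residual arcs from all origins; layered, so earliest first
        pred = {o: None for o in origins}
        frontier = list(origins)
        found = None
        while frontier and found is None:
            nxt = []
            for node in frontier:
                for e in ten.out_arcs[node]:
                    if residual[e] <= tol:
                        continue
                    head = int(ten.arc_head[e])
                    if head in pred:
                        continue
                    pred[head] = e
                    if head in targets:
                        found = head
                        break
                    nxt.append(head)
                if found is not None:
                    break
            frontier = nxt
        if found is None:
            break
        arcs = []
        node = found
        while pred[node] is not None:
            e = pred[node]
            arcs.append(e)
            node = int(ten.arc_tail[e])
        arcs.reverse()
        amount = float(min(residual[e] for e in arcs))
        for e in arcs:
            residual[e] -= amount
        steps = [ten.copy_label(node)] + [ten.copy_label(int(ten.arc_head[e])) for e in arcs]
        paths.append(RoutePath(steps=steps, amount=amount))

    leftover = float(
        sum(residual[e] for c in xl_dests for e in ten.in_arcs[c] if residual[e] > tol)
    )
    return ColonisationRoute(paths=paths, residual=leftover)


# -- time horizon ----------------------------------------------------------


def path_fill_time(path, network: HabitatNetwork, config: ScenarioConfig) -> int:
    """Serial fill time along a patch path: each hop takes
    ``ceil(T_SH / (K(tail) * S_DIS * (1 - C/C_max)))`` steps."""
    c_max = network.C_max if network.C_max is not None else config.C_max
    total = 0
    for a, b in zip(path[:-1], path[1:]):
        if not network.graph.has_edge(a, b):
            raise ValueError(f"patches {a} and {b} are not network neighbours")
        surv = 1.0 - network.edge_cost(a, b) / c_max
        rate = network.K(a) * config.S_DIS * surv
        total += math.ceil(config.T_SH / rate - 1e-9)
    return total


def horizon_bounds(
    network: HabitatNetwork,
    sources,
    dest: int,
    config: ScenarioConfig,
) -> tuple[int, int | None]:
    """Serial fill-time bounds TH1 (nearest source) and TH2 (second nearest).

    Raises :class:`UnreachableDestinationError` when no source reaches the
    destination in the habitat graph.
    """
    sources = sorted(set(sources))
    if dest in sources:
        return 0, None
    dist, paths = nx.single_source_dijkstra(network.graph, dest, weight="cost")
    reachable = [(dist[q], q) for q in sources if q in dist]
    if not reachable:
        raise UnreachableDestinationError(
            f"destination {dest} is unreachable from every initial source"
        )
    reachable.sort()
    th = []
    for _, q in reachable[:2]:
        th.append(path_fill_time(list(reversed(paths[q])), network, config))
    return th[0], (th[1] if len(th) > 1 else None)


def choose_time_horizon(
    network: HabitatNetwork,
    sources,
    dest: int,
    config: ScenarioConfig,
) -> int:
    """T = min{TH1, TH2, horizon_block} for a single destination."""
    th1, th2 = horizon_bounds(network, sources, dest, config)
    candidates = [th1, config.horizon_block]
    if th2 is not None:
        candidates.append(th2)
    return min(candidates)


def minimum_colonisation_time(
    network: HabitatNetwork,
    sources,
    H_dest,
    config: ScenarioConfig,
    solver: str = "highs",
    time_limit: float | None = None,
) -> tuple[int, ColonisationRoute]:
    """Minimum number of steps to colonise every destination, with a route.

    Builds the time-expanded MIP at the chosen horizon (for several
    destinations: the maximum of their per-destination horizons) and
    escalates the cap by blocks of ``horizon_block`` while infeasible.
    """
    sources = sorted(set(sources))
    H_dest = sorted(set(H_dest))
    if not H_dest:
        raise ValueError("at least one destination habitat is required")
    if set(H_dest) <= set(sources):
        paths = [RoutePath(steps=[(SUPER_SOURCE, -1), (d, 0)], amount=config.T_SH) for d in H_dest]
        return 0, ColonisationRoute(paths=paths)

    min_th = {}
    for d in H_dest:
        th1, th2 = horizon_bounds(network, sources, d, config)
        min_th[d] = th1 if th2 is None else min(th1, th2)
    t_lb = earliest_layer_bounds(network, sources, config)
    t_ub = serial_fill_upper_bounds(network, sources, config)
    need_lb = max(t_lb[d] for d in H_dest)
    # A provably feasible horizon: the best serial schedule per destination,
    # their sum when concurrent schedules must share emission capacity.
    feasible_cap = (
        int(max(t_ub[d] for d in H_dest))
        if len(H_dest) == 1
        else int(sum(t_ub[d] for d in H_dest))
    )

    # hop distance to the closest destination: biomass acting through patch v
    # must colonise at least one patch per hop, so v is irrelevant to any
    # horizon below t_lb(v) + hops(v)
    hops: dict[int, float] = {}
    for d in H_dest:
        for v, h in nx.single_source_shortest_path_length(network.graph, d).items():
            if h < hops.get(v, math.inf):
                hops[v] = h

    def attempt(T: int):
        keep = [v for v in network.ids() if t_lb[v] + hops.get(v, math.inf) <= T]
        kept_sources = [q for q in sources if q in set(keep)]
        if not kept_sources or not set(H_dest) <= set(keep):
            return None, MIPSolution(status="infeasible")
        subnet = network.subnetwork(keep) if len(keep) < network.n_patches else network
        ten = build_ten(subnet, kept_sources, T, config)
        instance = build_mip(ten, H_dest, config)
        log.debug(
            "probing horizon T=%d: %d of %d patches, %d arcs",
            T,
            subnet.n_patches,
            network.n_patches,
            ten.n_arcs,
        )
        return ten, solve_mip(instance, solver=solver, time_limit=time_limit, feasibility_only=True)

    # The optimum is the smallest horizon admitting a feasible schedule
    # (truncating a solution at its flagged layer stays feasible), so it is
    # found by scanning horizons upward from the earliest-arrival bound
    # with cheap feasibility versions of the model: no instance larger than
    # the optimum itself is ever solved, and branch-and-bound never has to
    # prove optimality.  The horizon-block escalation caps each round.
    lo = max(need_lb, 1)
    k = 1
    while True:
        T_round = max(min(b, k * config.horizon_block) for b in min_th.values())
        # clipping at a provably feasible horizon preserves the optimum
        T_round = max(min(T_round, feasible_cap), 1)
        for T in range(lo, T_round + 1):
            ten, solution = attempt(T)
            if solution.status == "optimal":
                # all horizons below T are infeasible, so the flagged layer is T
                return solution.t_star, extract_route(solution, ten)
            lo = T + 1
        if T_round >= feasible_cap:
            raise ConsistencyError(
                f"MIP infeasible at horizon {T_round} >= serial-schedule bound {feasible_cap}; "
                "this indicates an implementation inconsistency"
            )
        k += 1


# -- LP / MPS export -------------------------------------------------------


def _var_names(instance: MIPInstance) -> list[str]:
    ten = instance.ten
    names = []
    for e in range(ten.n_arcs):
        tail, t_tail = ten.copy_label(int(ten.arc_tail[e]))
        head, _ = ten.copy_label(int(ten.arc_head[e]))
        t = 0 if tail == SUPER_SOURCE else t_tail
        names.append(f"f_{tail}_{head}_{t}")
    for copy in range(instance.n_xc):
        pid, t = ten.copy_label(copy)
        names.append(f"x_{pid}_{t}")
    for t in range(instance.n_xl):
        names.append(f"xl_{t}")
    return names


def to_lp_string(instance: MIPInstance) -> str:
    """CPLEX LP-format text of the instance (f_tail_head_t / x_patch_t / xl_t)."""
    names = _var_names(instance)
    A = instance.A.tocoo()
    by_row: dict[int, list[tuple[int, float]]] = {}
    for r, c, v in zip(A.row, A.col, A.data):
        by_row.setdefault(int(r), []).append((int(c), float(v)))
    obj = " + ".join(
        f"{instance.c[j]:g} {names[j]}" for j in np.flatnonzero(instance.c != 0)
    ) or "0 " + names[0]
    lines = ["Minimize", f" obj: {obj}", "Subject To"]
    for r in range(instance.A.shape[0]):
        terms = " ".join(
            f"{'+' if v >= 0 else '-'} {abs(v):.12g} {names[j]}" for j, v in by_row.get(r, [])
        )
        lb, ub = instance.row_lb[r], instance.row_ub[r]
        if lb == ub:
            lines.append(f" c{r}: {terms} = {lb:.12g}")
        elif np.isfinite(ub) and not np.isfinite(lb):
            lines.append(f" c{r}: {terms} <= {ub:.12g}")
        elif np.isfinite(lb) and not np.isfinite(ub):
            lines.append(f" c{r}: {terms} >= {lb:.12g}")
        else:
            lines.append(f" c{r}a: {terms} >= {lb:.12g}")
            lines.append(f" c{r}b: {terms} <= {ub:.12g}")
    lines.append("Bounds")
    for j, name in enumerate(names):
        lb, ub = instance.var_lb[j], instance.var_ub[j]
        if np.isfinite(ub):
            lines.append(f" {lb:.12g} <= {name} <= {ub:.12g}")
        else:
            lines.append(f" {name} >= {lb:.12g}")
    lines.append("Binaries")
    lines.append(" " + " ".join(names[instance.n_f :]))
    lines.append("End")
    return "\n".join(lines) + "\n"


def to_mps_string(instance: MIPInstance) -> str:
    """Free-format MPS text of the instance."""
    names = _var_names(instance)
    n_rows = instance.A.shape[0]
    lines = ["NAME dendriflow_mip", "ROWS", " N obj"]
    rowtype = []
    for r in range(n_rows):
        lb, ub = instance.row_lb[r], instance.row_ub[r]
        if lb == ub:
            rowtype.append(("E", lb))
            lines.append(f" E c{r}")
        elif np.isfinite(ub) and not np.isfinite(lb):
            rowtype.append(("L", ub))
            lines.append(f" L c{r}")
        else:
            rowtype.append(("G", lb))
            lines.append(f" G c{r}")
    lines.append("COLUMNS")
    Acsc = instance.A.tocsc()
    in_int = False
    marker = 0
    for j, name in enumerate(names):
        is_int = instance.integrality[j] > 0
        if is_int and not in_int:
            lines.append(f" MARKER{marker} 'MARKER' 'INTORG'")
            marker += 1
            in_int = True
        if not is_int and in_int:
            lines.append(f" MARKER{marker} 'MARKER' 'INTEND'")
            marker += 1
            in_int = False
        if instance.c[j] != 0:
            lines.append(f" {name} obj {instance.c[j]:.12g}")
        start, end = Acsc.indptr[j], Acsc.indptr[j + 1]
        for r, v in zip(Acsc.indices[start:end], Acsc.data[start:end]):
            lines.append(f" {name} c{r} {v:.12g}")
    if in_int:
        lines.append(f" MARKER{marker} 'MARKER' 'INTEND'")
    lines.append("RHS")
    for r, (kind, rhs) in enumerate(rowtype):
        if rhs != 0:
            lines.append(f" rhs c{r} {rhs:.12g}")
    lines.append("BOUNDS")
    for j, name in enumerate(names):
        lb, ub = instance.var_lb[j], instance.var_ub[j]
        if lb == ub:
            lines.append(f" FX bnd {name} {lb:.12g}")
            continue
        if lb != 0:
            lines.append(f" LO bnd {name} {lb:.12g}")
        if np.isfinite(ub):
            lines.append(f" UP bnd {name} {ub:.12g}")
    lines.append("ENDATA")
    return "\n".join(lines) + "\n"
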