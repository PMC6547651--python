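# Methods

`dendriflow` couples a deterministic, discrete-time dispersal simulation on
a habitat network with a mixed-integer quickest-flow model on the
time-expanded version of the same network.  This note records the models,
the synthetic-data generators that stand in for real landscape inputs, the
numerical choices, and the limits of what the package's tests demonstrate.

## Scenario parameters

All parameters live in `ScenarioConfig`; a single integer seed fans out
into named substreams (land cover, streams, patches, qualities, sources,
destinations) so every stage is independently reproducible.

| parameter | default | meaning |
| --- | --- | --- |
| `cell_size_m` | 100 | raster cell edge, metres |
| `max_dispersal_m` | 2500 | maximum dispersal through open agricultural land |
| `agriculture/forest/urban/aquatic_cost` | 50 / 75 / 100 / 25 | dispersal cost per cell by land-cover class |
| `C_max` | derived: 1250 | cost budget = agriculture cost × (max dispersal / cell size); edges exist only strictly below it |
| `T_SH` | 10 | minimum viable population (biomass units); colonisation threshold |
| `S_DIS` | 0.1 | fraction of carrying capacity a source habitat can emit per step |
| `K_max` | 100 | carrying capacity at quality 1; `K(v) = quality · K_max`, quality ~ U(0.5, 1] |
| `habitat_fraction` | 0.10 | share of aquatic cells that become habitat patches |
| `source_fraction` | 0.10 | share of patches initially colonised per source set |
| `aquatic_fraction` | 0.078 | share of grid cells occupied by the stream network (19,490 per 500×500 reference extent) |
| `sim_max_steps` | 250 | simulation cap; uncolonised destinations are censored |
| `horizon_block` | 30 | time-horizon cap block for the optimisation |

`T_SH`, `S_DIS` and `K_max` are not dictated by published material; the
defaults make one hop over a mid-cost edge (survival 0.5) take two steps —
`ceil(10 / (100 · 0.1 · 0.5)) = 2` — which puts landscape-scale
colonisation times in the tens of steps, the regime the models are meant
to compare in.  All three are configurable.

## Synthetic landscape

Two generators emulate landscape inputs that are normally GIS products:

* **Land cover** — a modified random-cluster neutral landscape model.
  Cells are occupied independently with probability `cluster_fill = 0.55`
  (below the 4-neighbour site-percolation threshold ≈ 0.593, so clusters
  stay finite); 4-connected clusters are assigned whole to the classes
  agriculture/forest/urban by a deficit-greedy rule that tracks the target
  shares 66.6 / 11.1 / 22.2 %, and unoccupied cells copy their nearest
  occupied cell.  Class fractions converge to the targets (±0.03 at
  500×500) while remaining spatially clustered.  The printed class shares
  sum to 0.999; proportions within 2 × 10⁻³ of 1 are renormalised,
  anything further off is rejected.
* **Stream network** — headward growth of channel tips as persistent
  random walks (probability 0.95 of continuing straight, otherwise a 90°
  turn; a 1 % chance per growth event of sprouting a new tip on an
  existing channel cell) from a random boundary outlet.  A cell is only
  added while it touches exactly one aquatic cell, so the aquatic set is
  by construction a 4-connected spanning tree of itself — dendritic, no
  braided channels.  Persistence and branching were chosen so that the
  channels span the extent with near-uniform drainage density, as real
  stream rasters do; a compact, blob-like tree would make every patch
  reachable from every other and destroy the distance structure both
  models depend on.

What the generators do **not** reproduce: real hydrographic geometry
(meander wavelengths, Horton ratios), elevation-conditioned flow, land
cover correlated with the river corridor.  Tests passing on these
landscapes show the models behave correctly and reproduce the qualitative
comparison pattern, not that numbers for any particular real catchment
would be identical.

## Habitat network

Patches are a uniform sample of `floor(habitat_fraction · #aquatic)`
aquatic cells.  Least-cost distances between cells use the standard GIS
convention: 8-connected moves, a move costs the arithmetic mean of the two
cell costs, ×√2 for diagonals.  This reduces to `cells × cost` on straight
uniform runs, so 25 agriculture cells cost exactly the 1250 budget.  Each
patch runs one Dijkstra sweep truncated at `C_max`; an edge `(u, v)` with
`C(e) < C_max` (strict — the survival factor must stay positive) enters
the network with the least-cost value.  Ties between equal-cost paths are
irrelevant: only costs enter either model.

## Dispersal simulation

Synchronous update per step:

1. every source `v` emits a pool `S_DIS · K(v)`, split over all its
   neighbours with weights `1 − C(e)/C_max` normalised within `v`
   (option `allocation="inverse_cost"` uses `1/C(e)` weights instead);
2. the share travelling an edge is additionally multiplied by its survival
   factor; arrivals at patches that are already sources are discarded;
3. vacant patches accumulate arrivals; any patch at or above `T_SH` after
   the step becomes a source from the next step, its population jumping to
   `K(v)` (`growth="instant"`, mirroring the optimisation model's
   simplification) or ramping logistically at rate `growth_rate`
   (`growth="logistic"`); source biomass is restored to `K(v)` within the
   step, so emission never depletes a source.

The emission cap — no source ever emits more than `S_DIS · K(v)` per step
— is the property that makes the optimisation model's answer a valid lower
bound on the simulation, whatever allocation or growth option is active.

## Optimisation model

The time-expanded network has `T+1` copies per patch, two movement arcs
per habitat edge and layer, zero-cost holdover arcs, and a super source
`Q` injecting exactly `T_SH` into each initial source at layer 0.  Flow
variables carry *arriving* (post-mortality) biomass; the capacity
constraint divides outflow by the survival factor so that emission is
capped at `u(v) = S_DIS · K(v)` for colonised copies and zero otherwise,
on top of forwarding all held biomass to the next layer.  The capacity
constraint is not applied at `Q` (its outflow is fixed by the injection
constraint), and the carry-over constraint runs for `t = 1..T` (there is
no layer −1).  The minimum flagged layer — not the objective value, which
is degenerate at layer 0 — is reported as `t*`.

**Time horizon.**  `TH1` is the serial fill time along the cost-shortest
path from the nearest source — the sum over hops of
`ceil(T_SH / (K(tail) · S_DIS · (1 − C/C_max)))`, summed over the path's
edges — and `TH2` the same for the second-nearest source when one exists
(integer rounding can make it smaller).  The horizon is
`min{TH1, TH2, 30}`, escalated to `min{TH1, TH2, 60}` and further
multiples of 30 on infeasibility.  With several destinations the horizon
is the maximum of the per-destination choices; the infeasibility-at-bound
consistency check uses the per-destination serial bound for one
destination and their sum for several (concurrent serial schedules can
contend for shared emission capacity, sequential ones cannot).

**Solving.**  Instances are solved with HiGHS through
`scipy.optimize.milp`.  Three optimum-preserving reductions keep
branch-and-bound tractable on dense networks:

* copies of initial sources are pinned colonised (they hold `T_SH` from
  layer 0 on) and monotone cuts `x(v_t) ≤ x(v_{t+1})` are added — inflow
  never decreases along the holdover chain, so colonisation persists;
* a relaxed earliest-arrival bound (every neighbour assumed to emit at
  full capacity from its own earliest colonisation layer; exact on
  chains) pins copies of earlier layers vacant — and their outgoing
  movement arcs to zero — and certifies horizons below it infeasible
  without a solve;
* a serial-fill shortest path from the sources gives a feasible schedule,
  hence an upper bound that clips the solve horizon;
* per probed horizon `T`, patches with `earliest_bound(v) + hops(v, dest)
  > T` cannot influence the destination within the horizon (emission
  requires colonisation, so biomass advances at most one hop per layer)
  and are removed from the instance.

`minimum_colonisation_time` then exploits that feasibility at horizon `T`
is equivalent to `t* ≤ T` (truncating any solution at its flagged layer
stays feasible): it scans horizons upward from the earliest-arrival bound
with feasibility-only solves, which HiGHS terminates at the first
incumbent.  No instance larger than the optimum itself is ever solved and
branch-and-bound never has to prove optimality.  Every
returned solution is re-audited against the six constraint families by
direct arithmetic on the flows at tolerance 10⁻⁶ before being reported;
a time-limit hit raises an explicit timeout, never a silent answer.

**Routes.**  The positive flows are decomposed greedily into
time-stamped paths from `Q` or from colonised copies (where new biomass is
generated) to the destination copies at layer `t*`, earliest-arriving
first, each carrying its bottleneck flow; residual flow that cannot be
decomposed (degenerate optima) is reported, not raised.

## Comparison experiment

One network per scenario; `n` source sets (10 % of patches each) and `m`
destination patches; one simulation per source set (dispersal is
undirected, so a single run covers every destination) and one optimisation
per (source set, destination) pair.  Reported statistics: raw-scale
Pearson correlations of `t_opt` with the nearest-source and mean-source
least-cost distances, and the mean per-run ratio `t_sim / t_opt` over
pairs with both defined and `t_opt ≥ 1` (ratios are undefined when the
destination starts colonised; such pairs are counted and excluded — they
cannot arise in a design whose destinations are drawn disjointly from
sources, but can here).  Censored simulations (no colonisation within 250
steps) are counted separately.

The default experiment scale is a 150 × 150 grid (≈ 1 755 aquatic cells,
≈ 175 patches) with 10 source sets × 10 destinations — 10 simulations and
100 optimisations, a few minutes on one CPU.  At this extent the landscape
is only about six dispersal radii across, so optimal times compress into a
handful of steps and the nearest-source and mean-source distances are more
strongly coupled than they would be on a much larger landscape; the
qualitative pattern (strong nearest-source correlation exceeding the
mean-source correlation, simulation several-fold slower than the bound)
is the reproducible content at this scale.

## Known limitations

* The simulation's allocation rule and growth model bracket plausible
  behaviours behind config switches; field-calibrated demography would
  change simulated times (and hence speed factors), though never below the
  optimisation bound.
* The MIP treats population growth as an instant jump to `K(v)`; species
  with slow dynamics would make the bound loose.
* Habitat networks are undirected with symmetric costs; downstream drift
  is not modelled.
* Route decomposition on degenerate optima may leave residual flow; the
  amount is reported on the route object.
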