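# Methods

This note documents the modelling choices behind `cityaccess`: the procedure,
its assumptions, the parameters that matter, what the synthetic data does and
does not emulate, and the numerical conventions.

## Pipeline

1. **Graph construction.** Streets become an undirected graph; each edge
   carries `travel_time = length_m / (speed_kph · 1000/60)` minutes. Speeds
   come from a road-class table with a configurable default (30 km/h) for
   unknown classes — street data in the wild is messy and erroring on every
   unmapped class would make the tool unusable. Directed graphs are supported
   but the undirected configuration is the one the methodology was designed
   and validated for. Coordinates must be projected meters; the library does
   no geodetic math, because buffering (500 m) and the 1 km sampling lattice
   are metric operations.
2. **Origins and population.** Population polygons are assigned the nodes
   they cover (boundary nodes go to the first covering cell in input order —
   a deterministic, documented convention). One of five sampling strategies
   picks origin nodes; each cell's population is split equally among its
   selected origins, so per-cell population is conserved exactly. The 10%/5%
   strategies round up with a minimum of one origin per non-empty cell, so no
   populated cell silently loses representation.
3. **Hazard application.** Edges intersecting a hazard footprint (stored
   shape, else the straight chord; boundary contact counts) are affected.
   Flood depth > 5 cm penalizes (speed / ρ, default ρ = 3, chosen to mirror
   observed congestion friction of roughly 0.4–0.5 speed loss and then some);
   depth ≥ 15 cm disrupts; fault-buffered edges always disrupt. Disruption is
   modelled as infinite travel time rather than edge deletion so disrupted
   segments remain addressable in criticality reports.
4. **Routing.** Per-origin Dijkstra on travel time. Equal-cost paths are
   tie-broken lexicographically on the node-id sequence (the priority queue
   orders by `(cost, sequence)`), which makes criticality imputation
   reproducible across runs and platforms.
5. **Measures.** Huff probabilities, expected accessibility, edge
   criticality, isolation, compound aggregation and scenario comparison, as
   summarized in the README.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| ρ (speed penalization) | 3 | – | divisor on flooded-edge speed |
| flood penalize threshold | 5 | cm | strict: depth > 5 penalizes |
| flood disrupt threshold | 15 | cm | inclusive: depth ≥ 15 disrupts |
| fault buffer | 500 | m | all edges inside are disrupted |
| α (service importance) | 1 | – | per-service-type weight on criticality |
| time floor | 0.1 | min | clamp for co-located origin/facility pairs |
| λ (influence radius) | 2 | km | facility subgraph radius (partitioning) |
| δ (merge threshold) | 0.5 | fraction | subgraph-overlap merge criterion |
| JS histogram bins | 256 | – | shared equal-width bins, natural-log base |

## Design choices where the design was open

- **Huff normalization.** The choice probability for origin `i` is
  normalized over destinations `j` in `i`'s reachable set. This is the
  standard Huff formulation and the only reading under which the
  probabilities from one origin to all facilities sum to one. When a hazard
  removes facilities from reach, the choice set shrinks and the remaining
  probabilities renormalize — this is what produces preference shifts.
- **Zero travel time.** An origin co-located with a facility would divide by
  zero in `A_j / t`; travel times entering the Huff model are floored at
  0.1 min, preserving near-certain choice of the co-located facility without
  infinities.
- **Isolation rule.** An origin is isolated iff *no* facility is reachable;
  the isolated population is the sum of those origins' weights. (A
  per-destination sum would count one origin several times and contradicts
  the measure's meaning as "people who cannot reach the system".)
- **Compounding penalties.** An edge hit by several penalizing hazards is
  slowed once, by the largest applicable ρ, not by ρ². Multiplicative
  stacking has no physical basis (two 8 cm floods are still an 8 cm flood)
  and single application is the conservative choice. Severity order for
  status is disrupted > penalized > intact.
- **Partitioning details.** λ-balls use network (edge-length) distance, not
  Euclidean — an influence radius on a road network is naturally graph
  distance. The δ-overlap denominator is the smaller subgraph, so a small
  region engulfed by a larger one merges. The gateway for out-of-subgraph
  destinations is the time-nearest facility in the origin's subgraph (ties by
  facility id). These choices make partitioned times a provable upper bound
  on exact ones; the gap is zero whenever origin, gateway and destination lie
  on one shortest path.
- **Snap ties** go to the smallest node id (within 1e-9 m);
  **criticality rank ties** go to the smaller edge id; both purely for
  reproducibility.
- **λ = 2 km, δ = 0.5 defaults** are set for dense urban fabrics where
  facility spacing is hundreds of meters; for sparse regions λ should grow to
  the typical facility catchment radius. Partitioning is an opt-in
  scalability device; exact routing is the default path.

## Synthetic data

The generator produces rows × cols street lattices with 4-neighbour edges,
optional arterial rows/columns (60 km/h vs 30 km/h), square population cells
with uniform populations, and facilities on random intersections with
lognormal footprint areas (median 2 000 m², σ_log = 0.8) — a long-tailed size
mix of many small clinics and few large hospitals. Hazard bands are
rectangles (floods) or straight lines (faults) crossing the lattice, so the
affected edge set is enumerable from geometry in tests.

What the synthetic cities do **not** emulate: irregular street geometry and
dead-end density of real road networks, heterogeneous travel-speed mixes,
spatially correlated population density, realistic hazard footprint shapes,
and congestion (explicitly out of scope — travel times represent off-peak,
free-flow conditions). Passing tests therefore demonstrate the correctness
of the *method* — conservation, normalization, monotonicity under
disruption, oracle equality for routing and criticality — not the empirical
accuracy of any city-specific number.

A separate hand-coded eleven-node city (`fig2_fixture`) encodes the worked
example used throughout the documentation: two facilities (H, J), four
population cells, a flood and a fault overlapping on edge E–F, and a node (A)
whose single link makes it isolatable. Its coordinates are illustrative;
fixture-based tests assert topological and relational facts only (which edges
are affected, who becomes isolated), not metric distances.

## Numerical conventions

- Unreachability is `+inf` in travel-time matrices, never a sentinel.
- Scenario construction never mutates the baseline network; removing all
  hazard layers reproduces baseline travel times exactly (tested).
- The Jensen–Shannon divergence is computed between histograms of finite
  accessibility values on 256 shared equal-width bins over the pooled range,
  natural-log base (scipy returns the JS *distance*; the reported value is
  its square). Identical inputs give exactly 0. Tests assert only the
  identity and non-negativity properties, since the divergence value itself
  depends on binning.
- CSV outputs use fixed 6-decimal formatting so reruns diff cleanly;
  pipeline reruns with the same config and seed are byte-identical (tested).
- Test problem sizes (lattices up to 7×7, random graphs up to 50 nodes, 30
  oracle replicates) were chosen as the smallest sizes that still exercise
  tie-breaking, disconnection and multi-facility choice; all-pairs oracles
  use small integer edge weights so float comparisons can be exact.

## Known limitations

- No congestion, turn penalties, time-of-day effects or multi-modal routing.
- No fragility curves or probabilistic hazard sampling: hazard maps act as
  deterministic exposure proxies for utility loss.
- Partitioned travel times are upper bounds, not exact values; accessibility
  computed from them is conservative (never optimistic).
- The optional real-city (OSM) adapter is not part of the tested core.
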