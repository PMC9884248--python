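"""Shortest-path travel times, path extraction, and influence-radius partitioning.

Travel times are computed with Dijkstra's algorithm weighted by edge travel
time (minutes).  Equal-cost paths are tie-broken lexicographically on the node
id sequence: the priority queue orders entries by (cost, node-sequence), so
the first settled label at a node is both cheapest and lexicographically
smallest.  This makes criticality imputation — which walks the winning path's
edges — reproducible across runs and platforms.

For large urban areas the full origin x destination matrix is expensive
(O(n * m) single-source searches).  The partitioning scheme cuts the graph
into subgraphs G_i of all nodes within a network distance lambda (km) of each
facility; subgraphs sharing at least a fraction delta of their nodes are
merged.  Travel to a facility outside the origin's subgraph is approximated
as the local time to the subgraph's gateway facility plus the precomputed
facility-to-facility time, which makes partitioned times an upper bound on
the exact ones.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import StructuralError, ValidationError
from .hazards import Scenario
from .network_model import Amenity, RoadNetwork

__all__ = [
    "ODMatrix",
    "PartitionConfig",
    "Partition",
    "dijkstra_lex",
    "travel_times",
    "shortest_path_edges",
    "partition_network",
    "partitioned_travel_times",
]


def _routing_graph(net: RoadNetwork | Scenario):
    if isinstance(net, Scenario):
        return net.network.graph
    return net.graph


@dataclass
class ODMatrix:
    """Travel times (minutes) from sampled origins to all facilities.

    ``times[i, j]`` is +inf when facility ``j`` cannot be reached from origin
    ``i``; ``dists_km`` carries path lengths for the same trips when computed.
    ``paths`` maps ``(origin_node, dest_node)`` to the winning node sequence
    (present only when requested — criticality needs it, accessibility does
    not).
    """

    origin_ids: list[str]
    dest_ids: list[str]
    times: np.ndarray
    origin_weights: np.ndarray | None = None
    dists_km: np.ndarray | None = None
    paths: dict[tuple[str, str], tuple[str, ...]] | None = None
    out_of_coverage: set[str] = field(default_factory=set)

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.times)

    def isolated_mask(self) -> np.ndarray:
        """True for origins from which no facility is reachable."""
        if self.times.shape[1] == 0:
            return np.ones(self.times.shape[0], dtype=bool)
        return ~self.reachable.any(axis=1)


def dijkstra_lex(
    graph,
    source: str,
    targets: set[str] | None = None,
    weight: str = "travel_time",
    cutoff: float | None = None,
) -> tuple[dict[str, float], dict[str, tuple[str, ...]]]:
    """Single-source Dijkstra with lexicographic node-sequence tie-breaking.

    Returns (distance, path) dicts over settled nodes.  Edges with infinite
    weight (disrupted links) are never relaxed.  With ``cutoff`` set, search
    stops expanding beyond that distance; with ``targets`` set, it stops once
    all targets are settled.
    """
    if source not in graph:
        raise StructuralError(f"unknown node id {source!r}")
    dist: dict[str, float] = {}
    path: dict[str, tuple[str, ...]] = {}
    remaining = set(targets) if targets is not None else None
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        d, seq = heapq.heappop(heap)
        node = seq[-1]
        if node in dist:
            continue
        dist[node] = d
        path[node] = seq
        if remaining is not None:
            remaining.discard(node)
            if not remaining:
                break
        for nbr, data in graph[node].items():
            if nbr in dist:
                continue
            w = data[weight]
            if not math.isfinite(w):
                continue
            nd = d + w
            if cutoff is not None and nd > cutoff:
                continue
            heapq.heappush(heap, (nd, seq + (nbr,)))
    return dist, path


def travel_times(
    network: RoadNetwork | Scenario,
    origins: Sequence[str],
    destinations: Sequence[str],
    weights: np.ndarray | Sequence[float] | None = None,
    return_paths: bool = False,
    with_distance: bool = False,
) -> ODMatrix:
    """Exact O-D travel-time matrix by per-origin Dijkstra.

    ``origins`` and ``destinations`` are node ids (duplicates allowed:
    several origins may snap to the same intersection).  ``t[i, j]`` is zero
    iff origin and destination coincide, +inf when no path survives in the
    (possibly disrupted) network.
    """
    graph = _routing_graph(network)
    for n in list(origins) + list(destinations):
        if n not in graph:
            raise StructuralError(f"unknown node id {n!r}")
    dest_set = set(destinations)
    n_o, n_d = len(origins), len(destinations)
    times = np.full((n_o, n_d), np.inf)
    dists = np.full((n_o, n_d), np.inf) if with_distance else None
    paths: dict[tuple[str, str], tuple[str, ...]] = {} if return_paths else None

    cache: dict[str, tuple[dict, dict]] = {}
    for i, o in enumerate(origins):
        if o not in cache:
            cache[o] = dijkstra_lex(graph, o, targets=dest_set)
        dist, path = cache[o]
        for j, dnode in enumerate(destinations):
            if dnode in dist:
                times[i, j] = dist[dnode]
                if with_distance:
                    seq = path[dnode]
                    dists[i, j] = (
                        sum(graph.edges[a, b]["length"] for a, b in zip(seq, seq[1:])) / 1000.0
                    )
                if return_paths:
                    paths[(o, dnode)] = path[dnode]
    w = None if weights is None else np.asarray(weights, dtype=float)
    return ODMatrix(
        origin_ids=list(origins),
        dest_ids=list(destinations),
        times=times,
        origin_weights=w,
        dists_km=dists,
        paths=paths,
    )


def shortest_path_edges(
    network: RoadNetwork | Scenario, origin: str, destination: str
) -> list[tuple[str, str]] | None:
    """Ordered edge list of the tie-broken shortest path, or None if unreachable.

    The edge-time sum of the returned list equals the travel_times entry for
    the same pair — both use the same tie-break, so times and imputed paths
    stay mutually consistent.
    """
    graph = _routing_graph(network)
    dist, path = dijkstra_lex(graph, origin, targets={destination})
    if destination not in dist:
        return None
    seq = path[destination]
    return list(zip(seq, seq[1:]))


@dataclass
class PartitionConfig:
    """Influence radius lambda (km) and merge threshold delta (node-share fraction)."""

    lambda_km: float = 2.0
    delta: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.lambda_km > 0):
            raise ValidationError(f"lambda must be > 0 km, got {self.lambda_km}")
        if not (0 < self.delta <= 1):
            raise ValidationError(f"delta must be in (0, 1], got {self.delta}")


@dataclass
class Subgraph:
    """One (possibly merged) facility influence region."""

    nodes: frozenset
    amenity_ids: list[str]


@dataclass
class Partition:
    subgraphs: list[Subgraph]
    node_map: dict[str, list[int]]  # node -> indices of containing subgraphs
    out_of_coverage: set[str]
    amenity_nodes: dict[str, str]  # amenity id -> snapped node


def partition_network(
    network: RoadNetwork | Scenario,
    amenities: Sequence[Amenity],
    config: PartitionConfig,
) -> Partition:
    """Split the graph into facility-anchored subgraphs and merge overlaps.

    Each facility's subgraph is the set of nodes within network shortest-path
    distance ``lambda_km`` of its snapped node (distance measured along edge
    lengths, not travel time).  Pairs of subgraphs whose shared-node fraction
    |A ∩ B| / min(|A|, |B|) reaches ``delta`` are merged, transitively, until
    a fixpoint.  Nodes in no subgraph are reported as out of coverage.
    """
    graph = _routing_graph(network)
    cutoff_m = config.lambda_km * 1000.0
    balls: list[set] = []
    members: list[list[str]] = []
    for am in amenities:
        if am.node_id not in graph:
            raise StructuralError(f"amenity {am.id!r} snapped to unknown node {am.node_id!r}")
        dist, _ = dijkstra_lex(graph, am.node_id, weight="length", cutoff=cutoff_m)
        balls.append(set(dist))
        members.append([am.id])

    # union-find merge to fixpoint
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(balls):
            j = i + 1
            while j < len(balls):
                inter = len(balls[i] & balls[j])
                if inter and inter / min(len(balls[i]), len(balls[j])) >= config.delta:
                    balls[i] |= balls[j]
                    members[i] += members[j]
                    del balls[j], members[j]
                    changed = True
                else:
                    j += 1
            i += 1

    subgraphs = [Subgraph(frozenset(b), sorted(m)) for b, m in zip(balls, members)]
    node_map: dict[str, list[int]] = {}
    for idx, sg in enumerate(subgraphs):
        for n in sg.nodes:
            node_map.setdefault(n, []).append(idx)
    out = set(graph.nodes) - set(node_map)
    return Partition(
        subgraphs=subgraphs,
        node_map=node_map,
        out_of_coverage=out,
        amenity_nodes={am.id: am.node_id for am in amenities},
    )


def partitioned_travel_times(
    partition: Partition,
    network: RoadNetwork | Scenario,
    origins: Sequence[str],
    amenities: Sequence[Amenity],
    weights: np.ndarray | Sequence[float] | None = None,
) -> ODMatrix:
    """Approximate O-D times through the partition (an upper bound on exact).

    Within the origin's subgraph, times are local Dijkstra results.  For a
    facility j outside it, the trip is composed as
    ``t(origin -> gateway) + t(gateway -> j)`` where the gateway is the
    time-nearest facility of the origin's subgraph and the facility-to-facility
    leg is precomputed on the full network.  Origins covered by several merged
    subgraphs take the elementwise best composition.  Origins outside every
    subgraph get an all-inf row and are flagged out of coverage.
    """
    graph = _routing_graph(network)
    am_nodes = [am.node_id for am in amenities]
    am_ids = [am.id for am in amenities]
    # facility-to-facility matrix on the full (disrupted) network
    ff = travel_times(network, am_nodes, am_nodes).times

    n_o, n_d = len(origins), len(amenities)
    times = np.full((n_o, n_d), np.inf)
    out_flagged: set[str] = set()

    local_cache: dict[tuple[int, str], dict[str, float]] = {}
    for i, o in enumerate(origins):
        groups = partition.node_map.get(o, [])
        if not groups:
            out_flagged.add(o)
            continue
        for gidx in groups:
            sg = partition.subgraphs[gidx]
            key = (gidx, o)
            if key not in local_cache:
                sub = graph.subgraph(sg.nodes)
                local_targets = {partition.amenity_nodes[a] for a in sg.amenity_ids}
                dist, _ = dijkstra_lex(sub, o, targets=local_targets)
                local_cache[key] = dist
            dist = local_cache[key]
            # local facilities: exact within the subgraph
            local_am = [
                (aid, dist.get(partition.amenity_nodes[aid], math.inf))
                for aid in sg.amenity_ids
            ]
            reachable = [(t, aid) for aid, t in local_am if math.isfinite(t)]
            for aid, t in local_am:
                j = am_ids.index(aid)
                times[i, j] = min(times[i, j], t)
            if not reachable:
                continue
            gw_t, gw_id = min(reachable)  # tie -> smallest amenity id
            gw_j = am_ids.index(gw_id)
            for j in range(n_d):
                if am_ids[j] in sg.amenity_ids:
                    continue
                times[i, j] = min(times[i, j], gw_t + ff[gw_j, j])
    w = None if weights is None else np.asarray(weights, dtype=float)
    return ODMatrix(
        origin_ids=list(origins),
        dest_ids=am_ids,
        times=times,
        origin_weights=w,
        out_of_coverage=out_flagged,
    )
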