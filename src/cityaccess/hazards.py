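"""Hazard layers, network disruption rules and compound-scenario composition.

The impact of a natural shock on the street network is modelled through two
mechanisms, applied per affected edge:

* *speed penalization*: the edge keeps functioning but its free-flow speed is
  divided by a factor rho (default 3, i.e. driving at one third of the
  off-peak speed), used for shallow flooding;
* *full disruption*: the edge carries no traffic at all, modelled as infinite
  travel time, used for deep flooding and for every street within a fixed
  buffer (default 500 m) of a seismic fault line.

Default flood thresholds: depths above 5 cm penalize, depths of 15 cm or more
disrupt.  Hazard footprints act purely as exposure proxies; no fragility
curves or probabilistic sampling are involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from shapely.geometry import LineString
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import ValidationError
from .network_model import RoadNetwork, edge_key, travel_time_minutes

__all__ = [
    "HazardLayer",
    "HazardRule",
    "EdgeStatus",
    "Scenario",
    "buffer_fault_lines",
    "intersect_edges",
    "apply_rule",
    "compose_hazards",
    "baseline_scenario",
]

INTACT = "intact"
PENALIZED = "penalized"
DISRUPTED = "disrupted"

_SEVERITY = {INTACT: 0, PENALIZED: 1, DISRUPTED: 2}


@dataclass
class HazardLayer:
    """A set of hazard footprints of one kind.

    ``geometries`` pairs each shapely geometry with its intensity: flood
    polygons carry a depth in cm; fault geometries (linestrings or polygons)
    carry a return-period label that plays no numerical role.
    """

    id: str
    kind: str  # "flood" | "fault"
    geometries: list[tuple[object, object]]

    def __post_init__(self) -> None:
        if self.kind not in ("flood", "fault"):
            raise ValidationError(f"layer {self.id!r}: unknown hazard kind {self.kind!r}")
        for geom, intensity in self.geometries:
            if geom.is_empty or not geom.is_valid:
                raise ValidationError(f"layer {self.id!r}: empty or invalid geometry")
            if self.kind == "flood" and float(intensity) < 0:
                raise ValidationError(f"layer {self.id!r}: flood depth must be >= 0")


@dataclass
class HazardRule:
    """How a hazard layer translates into edge-level impacts."""

    rho: float = 3.0
    penalize_cm: float = 5.0
    disrupt_cm: float = 15.0
    fault_buffer_m: float = 500.0

    def __post_init__(self) -> None:
        if not (self.rho > 1):
            raise ValidationError(f"rho must be > 1, got {self.rho}")
        if self.disrupt_cm < self.penalize_cm:
            raise ValidationError("disrupt threshold must be >= penalize threshold")
        if not (self.fault_buffer_m > 0):
            raise ValidationError("fault buffer radius must be > 0")


@dataclass
class EdgeStatus:
    """Resolved state of one edge after hazard application."""

    status: str = INTACT
    factor: float | None = None  # applied rho if penalized
    layers: list[str] = field(default_factory=list)


@dataclass
class Scenario:
    """A baseline network together with the disrupted network a hazard set induces.

    ``network`` is a deep copy of the baseline with penalized speeds / infinite
    travel times applied; the baseline itself is never mutated.  ``edge_status``
    records, per canonical edge key, what happened and which layers caused it
    (edges absent from the mapping are intact).
    """

    name: str
    baseline: RoadNetwork
    network: RoadNetwork
    edge_status: dict[tuple[str, str], EdgeStatus] = field(default_factory=dict)

    def status_of(self, u: str, v: str) -> EdgeStatus:
        return self.edge_status.get(edge_key(u, v, self.baseline.directed), EdgeStatus())

    @property
    def disrupted_edges(self) -> set[tuple[str, str]]:
        return {k for k, s in self.edge_status.items() if s.status == DISRUPTED}

    @property
    def penalized_edges(self) -> set[tuple[str, str]]:
        return {k for k, s in self.edge_status.items() if s.status == PENALIZED}


def baseline_scenario(network: RoadNetwork, name: str = "baseline") -> Scenario:
    """The undisrupted scenario: identical travel times, no affected edges."""
    return Scenario(name=name, baseline=network, network=network.copy())


def buffer_fault_lines(geometries: Iterable, radius_m: float) -> list:
    """Planar buffers of fault geometries, unioned and split into polygons.

    Overlapping buffers merge; disjoint faults yield disjoint polygons.
    """
    if not (radius_m > 0):
        raise ValidationError(f"buffer radius must be > 0, got {radius_m}")
    geometries = list(geometries)
    if not geometries:
        return []
    merged = unary_union([g.buffer(radius_m) for g in geometries])
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)


def intersect_edges(
    network: RoadNetwork, hazard_geometries: Sequence[tuple[object, float]]
) -> dict[tuple[str, str], float]:
    """Find edges touched by hazard footprints and their worst intensity.

    An edge is affected iff its geometry (stored shape, else the straight
    chord between its endpoints) intersects any hazard geometry — boundary
    contact counts.  The reported intensity is the maximum over all
    intersecting geometries, so overlapping footprints never dilute impact.
    """
    if not hazard_geometries:
        return {}
    geoms = [g for g, _ in hazard_geometries]
    intensities = [float(i) for _, i in hazard_geometries]
    tree = STRtree(geoms)
    affected: dict[tuple[str, str], float] = {}
    for u, v in network.graph.edges:
        shape: LineString = network.edge_geometry(u, v)
        hits = tree.query(shape, predicate="intersects")
        if len(hits):
            key = edge_key(u, v, network.directed)
            affected[key] = max(intensities[i] for i in hits)
    return affected


def apply_rule(
    network: RoadNetwork,
    affected: dict[tuple[str, str], float],
    rule: HazardRule,
    kind: str = "flood",
    name: str = "hazard",
    layer_id: str | None = None,
) -> Scenario:
    """Turn an affected-edge set into a disrupted scenario.

    Flood edges with depth strictly above ``penalize_cm`` but below
    ``disrupt_cm`` drive at ``speed / rho``; depth at or above ``disrupt_cm``
    disrupts the edge entirely.  Fault-affected edges are always disrupted.
    Depths at or below the penalize threshold leave the edge intact.
    """
    statuses: dict[tuple[str, str], EdgeStatus] = {}
    lid = layer_id or name
    for key, intensity in affected.items():
        if not network.graph.has_edge(*key):
            raise ValidationError(f"affected edge {key} not in network")
        if kind == "fault":
            statuses[key] = EdgeStatus(DISRUPTED, None, [lid])
        elif intensity >= rule.disrupt_cm:
            statuses[key] = EdgeStatus(DISRUPTED, None, [lid])
        elif intensity > rule.penalize_cm:
            statuses[key] = EdgeStatus(PENALIZED, rule.rho, [lid])
    return _materialize(network, statuses, name)


def compose_hazards(
    network: RoadNetwork,
    layers: Sequence[tuple[HazardLayer, HazardRule]],
    name: str = "compound",
) -> Scenario:
    """Apply several hazard layers at once, most severe status per edge winning.

    Severity order: disrupted > penalized > intact.  An edge penalized by
    several layers is slowed once, by the largest applicable rho — penalties
    do not compound multiplicatively.  The layers responsible for each edge's
    state are recorded for reporting.
    """
    if not layers:
        raise ValidationError("compose_hazards requires at least one hazard layer")
    combined: dict[tuple[str, str], EdgeStatus] = {}
    for layer, rule in layers:
        if layer.kind == "fault":
            polys = buffer_fault_lines([g for g, _ in layer.geometries], rule.fault_buffer_m)
            affected = intersect_edges(network, [(p, 0.0) for p in polys])
        else:
            affected = intersect_edges(network, [(g, float(i)) for g, i in layer.geometries])
        part = apply_rule(network, affected, rule, kind=layer.kind, layer_id=layer.id)
        for key, st in part.edge_status.items():
            cur = combined.get(key)
            if cur is None:
                combined[key] = EdgeStatus(st.status, st.factor, [layer.id])
            else:
                cur.layers.append(layer.id)
                if _SEVERITY[st.status] > _SEVERITY[cur.status]:
                    cur.status, cur.factor = st.status, st.factor
                elif st.status == PENALIZED and cur.status == PENALIZED:
                    cur.factor = max(cur.factor, st.factor)
                if cur.status == DISRUPTED:
                    cur.factor = None
    return _materialize(network, combined, name)


def scenario_from_layer(
    network: RoadNetwork, layer: HazardLayer, rule: HazardRule, name: str | None = None
) -> Scenario:
    """Single-hazard scenario: buffer faults if needed, intersect, apply the rule."""
    return compose_hazards(network, [(layer, rule)], name=name or layer.id)


def _materialize(
    network: RoadNetwork, statuses: dict[tuple[str, str], EdgeStatus], name: str
) -> Scenario:
    disrupted = network.copy()
    g = disrupted.graph
    for (u, v), st in statuses.items():
        data = g.edges[u, v]
        if st.status == DISRUPTED:
            data["travel_time"] = math.inf
        elif st.status == PENALIZED:
            data["speed"] = data["speed"] / st.factor
            data["travel_time"] = travel_time_minutes(data["length"], data["speed"])
    return Scenario(name=name, baseline=network, network=disrupted, edge_status=statuses)
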