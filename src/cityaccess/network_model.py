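"""Road-network construction, facility snapping, origin sampling and population allocation.

The road network is an undirected graph ``G(V, E)`` whose vertices are street
intersections and whose edges are street segments.  Every edge carries a length
in meters, a road-class label, a free-flow speed in km/h (looked up in a
:class:`SpeedTable` by road class) and a derived travel time in minutes.

All coordinates throughout the package are planar coordinates in meters
(a projected CRS).  No geodetic math is performed anywhere: buffering,
lattice construction and nearest-node queries all assume a metric plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point
from shapely.prepared import prep

from .errors import StructuralError, ValidationError

__all__ = [
    "RoadNetwork",
    "SpeedTable",
    "PopulationCell",
    "Origin",
    "OriginSet",
    "Amenity",
    "SAMPLING_STRATEGIES",
    "travel_time_minutes",
    "build_network",
    "edge_key",
    "snap_points",
    "assign_nodes_to_cells",
    "sample_origins",
    "allocate_population",
]

#: Sampling strategies for origin selection.
SAMPLING_STRATEGIES = (
    "FIXED_GRID_1KM",
    "CELL_CENTROIDS",
    "NEAREST_10PCT",
    "RANDOM_10PCT",
    "RANDOM_5PCT",
)

_RANDOM_FRACTIONS = {"RANDOM_10PCT": 0.10, "RANDOM_5PCT": 0.05}


def travel_time_minutes(length_m: float, speed_kph: float) -> float:
    """Travel time in minutes for ``length_m`` meters at ``speed_kph`` km/h."""
    return length_m / (speed_kph * 1000.0 / 60.0)


@dataclass
class SpeedTable:
    """Free-flow speed (km/h) per road class, with a default for unknown classes.

    Road-class tables in practice never cover every label found in street data,
    so unknown classes fall back to ``default_kph`` instead of erroring.
    """

    speeds: Mapping[str, float] = field(default_factory=dict)
    default_kph: float = 30.0

    def __post_init__(self) -> None:
        for cls, kph in self.speeds.items():
            if not (kph > 0):
                raise ValidationError(f"speed for road class {cls!r} must be > 0, got {kph}")
        if not (self.default_kph > 0):
            raise ValidationError(f"default speed must be > 0, got {self.default_kph}")

    def lookup(self, road_class: str | None) -> float:
        return float(self.speeds.get(road_class, self.default_kph))


@dataclass
class PopulationCell:
    """A polygonal population-grid cell with a head count."""

    id: str
    geometry: object  # shapely Polygon in projected meters
    population: float

    def __post_init__(self) -> None:
        if self.population < 0 or not math.isfinite(self.population):
            raise ValidationError(f"cell {self.id!r}: population must be a finite count >= 0")
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValidationError(f"cell {self.id!r}: polygon is empty or invalid")


@dataclass(frozen=True)
class Origin:
    """A sampled origin: a network node with an attributed population weight."""

    node_id: str
    cell_id: str
    weight: float = float("nan")


@dataclass
class OriginSet:
    """The sampled origins, the strategy that produced them, and reporting info.

    ``empty_cells`` lists population cells that contained no network node and
    therefore contributed no origins; ``unassigned_nodes`` lists candidate
    nodes (grid-lattice strategy only) that fell outside every cell.
    """

    origins: list[Origin]
    strategy: str
    seed: int | None = None
    empty_cells: list[str] = field(default_factory=list)
    unassigned_nodes: list[str] = field(default_factory=list)

    @property
    def node_ids(self) -> list[str]:
        return [o.node_id for o in self.origins]

    @property
    def weights(self) -> np.ndarray:
        return np.array([o.weight for o in self.origins], dtype=float)

    @property
    def total_population(self) -> float:
        return float(np.nansum(self.weights))


@dataclass
class Amenity:
    """A service facility snapped to a network node.

    The footprint area ``area_m2`` is the Huff-model attractivity proxy:
    larger facilities provide more complex services and draw more users.
    """

    id: str
    name: str
    x: float
    y: float
    node_id: str
    area_m2: float
    service_type: str = "health"

    def __post_init__(self) -> None:
        if not (self.area_m2 > 0):
            raise ValidationError(f"amenity {self.id!r}: area must be > 0, got {self.area_m2}")


class RoadNetwork:
    """An annotated street graph.

    Thin wrapper around a :class:`networkx.Graph` (undirected by default,
    matching the street networks the method is designed for).  Node attributes:
    ``x``, ``y`` (meters).  Edge attributes: ``length`` (m), ``road_class``,
    ``speed`` (km/h), ``travel_time`` (minutes), optional ``geometry``
    (shapely LineString; edges without one use the straight chord u-v).
    """

    def __init__(self, graph: nx.Graph, directed: bool = False):
        self.graph = graph
        self.directed = directed

    # -- basic accessors -------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def node_xy(self, node_id: str) -> tuple[float, float]:
        d = self.graph.nodes[node_id]
        return d["x"], d["y"]

    def edge_geometry(self, u: str, v: str) -> LineString:
        """Stored shape of edge u-v, or the straight chord if none was given."""
        data = self.graph.edges[u, v]
        geom = data.get("geometry")
        if geom is not None:
            return geom
        return LineString([self.node_xy(u), self.node_xy(v)])

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [d["x"] for _, d in self.graph.nodes(data=True)]
        ys = [d["y"] for _, d in self.graph.nodes(data=True)]
        return min(xs), min(ys), max(xs), max(ys)

    def copy(self) -> "RoadNetwork":
        return RoadNetwork(self.graph.copy(), directed=self.directed)

    def _kdtree(self) -> tuple[cKDTree, list[str]]:
        ids = sorted(self.graph.nodes)
        pts = np.array([[self.graph.nodes[i]["x"], self.graph.nodes[i]["y"]] for i in ids])
        return cKDTree(pts), ids


def edge_key(u: str, v: str, directed: bool = False) -> tuple[str, str]:
    """Canonical identifier for an edge: sorted endpoints when undirected."""
    if directed or u <= v:
        return (u, v)
    return (v, u)


def build_network(
    nodes: Iterable[tuple[str, float, float]],
    edges: Iterable[Mapping],
    speed_table: SpeedTable | None = None,
    directed: bool = False,
) -> RoadNetwork:
    """Assemble the road graph from node and edge records.

    Parameters
    ----------
    nodes
        Iterable of ``(id, x, y)`` with projected coordinates in meters.
    edges
        Iterable of mappings with keys ``u``, ``v``, ``length`` (m),
        ``road_class`` and optionally ``speed`` (km/h, overriding the table)
        and ``geometry`` (shapely LineString).
    speed_table
        Road-class to free-flow-speed mapping; defaults to a 30 km/h flat table.
    directed
        Build a directed graph.  The default, undirected, is the configuration
        the methodology was designed and validated for.

    Each edge receives ``travel_time = length / (speed * 1000 / 60)`` minutes.
    Connectivity is not required; disconnected components simply yield
    unreachable origin-destination pairs downstream.
    """
    speed_table = speed_table or SpeedTable()
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()

    for nid, x, y in nodes:
        nid = str(nid)
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"node {nid!r}: coordinates must be finite")
        if nid in g:
            raise ValidationError(f"duplicate node id {nid!r}")
        g.add_node(nid, x=float(x), y=float(y))

    for rec in edges:
        u, v = str(rec["u"]), str(rec["v"])
        if u not in g or v not in g:
            missing = u if u not in g else v
            raise StructuralError(f"edge ({u!r}, {v!r}) references missing node {missing!r}")
        if u == v:
            raise ValidationError(f"self-loop on node {u!r} rejected")
        length = float(rec["length"])
        if not (length > 0):
            raise ValidationError(f"edge ({u!r}, {v!r}): length must be > 0, got {length}")
        road_class = rec.get("road_class")
        speed = float(rec.get("speed") or speed_table.lookup(road_class))
        if not (speed > 0):
            raise ValidationError(f"edge ({u!r}, {v!r}): speed must be > 0, got {speed}")
        g.add_edge(
            u,
            v,
            length=length,
            road_class=road_class,
            speed=speed,
            travel_time=travel_time_minutes(length, speed),
            geometry=rec.get("geometry"),
        )

    return RoadNetwork(g, directed=directed)


def snap_points(
    network: RoadNetwork, points: Sequence[tuple[str, float, float]]
) -> list[tuple[str, str, float]]:
    """Map each point to the Euclidean-nearest network node.

    Returns ``(point_id, node_id, snap_distance_m)`` triples.  Ties within
    1e-9 m are broken by the smallest node id so that snapping is reproducible
    across runs and platforms.
    """
    if network.graph.number_of_nodes() == 0:
        raise StructuralError("cannot snap to an empty network")
    tree, ids = network._kdtree()
    k = min(8, len(ids))
    out: list[tuple[str, str, float]] = []
    for pid, x, y in points:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"point {pid!r}: coordinates must be finite")
        dists, idxs = tree.query([x, y], k=k)
        dists = np.atleast_1d(dists)
        idxs = np.atleast_1d(idxs)
        dmin = dists[0]
        # ids list is sorted, so the smallest qualifying index is the smallest id
        tied = [ids[i] for d, i in zip(dists, idxs) if d <= dmin + 1e-9]
        out.append((str(pid), min(tied), float(dmin)))
    return out


def assign_nodes_to_cells(
    network: RoadNetwork, cells: Sequence[PopulationCell]
) -> dict[str, list[str]]:
    """Partition network nodes among population cells.

    A node belongs to the first cell, in input order, whose polygon covers it
    (boundary-inclusive).  First-in-input-order makes boundary assignment
    deterministic when cells tile the plane and share borders.
    """
    remaining = dict.fromkeys(sorted(network.graph.nodes))
    result: dict[str, list[str]] = {c.id: [] for c in cells}
    for cell in cells:
        prepared = prep(cell.geometry)
        taken = []
        for nid in remaining:
            x, y = network.node_xy(nid)
            if prepared.covers(Point(x, y)):
                result[cell.id].append(nid)
                taken.append(nid)
        for nid in taken:
            del remaining[nid]
    return result


def _ceil_fraction(n: int, frac: float) -> int:
    """ceil(frac * n), but at least 1 — no populated cell loses representation."""
    return max(1, math.ceil(frac * n))


def sample_origins(
    network: RoadNetwork,
    cells: Sequence[PopulationCell],
    strategy: str,
    seed: int | None = None,
    grid_spacing_m: float = 1000.0,
) -> OriginSet:
    """Select a subsample of network nodes to act as trip origins.

    Five strategies are supported (``SAMPLING_STRATEGIES``):

    - ``FIXED_GRID_1KM``: nearest node to each vertex of a 1 km lattice over
      the network bounding box (deduplicated); lattice nodes outside every
      population cell are dropped and reported.
    - ``CELL_CENTROIDS``: nearest node to each cell centroid, one per cell.
    - ``NEAREST_10PCT``: per cell, the 10% of in-cell nodes Euclidean-closest
      to the cell's centroid node (minimum 1).
    - ``RANDOM_10PCT`` / ``RANDOM_5PCT``: per cell, a seeded uniform sample of
      10% / 5% of in-cell nodes (minimum 1).

    Percentages round up with a minimum of one origin per non-empty cell.
    Cells containing no node contribute no origins and are listed in
    ``OriginSet.empty_cells``.  Weights are filled later by
    :func:`allocate_population`.
    """
    if strategy not in SAMPLING_STRATEGIES:
        raise ValidationError(
            f"unknown sampling strategy {strategy!r}; expected one of {SAMPLING_STRATEGIES}"
        )
    if strategy in _RANDOM_FRACTIONS and seed is None:
        raise ValidationError(f"strategy {strategy!r} requires a seed")

    node_cells = assign_nodes_to_cells(network, cells)
    origins: list[Origin] = []
    empty_cells = [c.id for c in cells if not node_cells[c.id]]
    unassigned: list[str] = []

    if strategy == "FIXED_GRID_1KM":
        xmin, ymin, xmax, ymax = network.bounds()
        xs = np.arange(xmin, xmax + grid_spacing_m, grid_spacing_m)
        ys = np.arange(ymin, ymax + grid_spacing_m, grid_spacing_m)
        lattice = [(f"g{i}_{j}", x, y) for i, x in enumerate(xs) for j, y in enumerate(ys)]
        snapped = snap_points(network, lattice)
        chosen = sorted({node for _, node, _ in snapped})
        cell_of = {nid: cid for cid, nids in node_cells.items() for nid in nids}
        for nid in chosen:
            cid = cell_of.get(nid)
            if cid is None:
                unassigned.append(nid)
            else:
                origins.append(Origin(nid, cid))
    elif strategy == "CELL_CENTROIDS":
        pts = [(c.id, c.geometry.centroid.x, c.geometry.centroid.y) for c in cells]
        for cid, node, _ in snap_points(network, pts):
            origins.append(Origin(node, cid))
        empty_cells = []  # every cell gets its centroid-nearest node
    elif strategy == "NEAREST_10PCT":
        for cell in cells:
            in_cell = node_cells[cell.id]
            if not in_cell:
                continue
            cx, cy = cell.geometry.centroid.x, cell.geometry.centroid.y
            # centroid node = the in-cell node nearest the centroid (ties by id)
            center = min(
                in_cell,
                key=lambda n: (_sq_dist(network.node_xy(n), (cx, cy)), n),
            )
            k = _ceil_fraction(len(in_cell), 0.10)
            ranked = sorted(
                in_cell,
                key=lambda n: (_sq_dist(network.node_xy(n), network.node_xy(center)), n),
            )
            for nid in ranked[:k]:
                origins.append(Origin(nid, cell.id))
    else:  # RANDOM_10PCT / RANDOM_5PCT
        frac = _RANDOM_FRACTIONS[strategy]
        rng = np.random.default_rng(seed)
        for cell in cells:  # input order keeps the stream deterministic
            in_cell = sorted(node_cells[cell.id])
            if not in_cell:
                continue
            k = _ceil_fraction(len(in_cell), frac)
            picked = rng.choice(len(in_cell), size=k, replace=False)
            for idx in sorted(picked):
                origins.append(Origin(in_cell[idx], cell.id))

    return OriginSet(
        origins=origins,
        strategy=strategy,
        seed=seed,
        empty_cells=empty_cells,
        unassigned_nodes=unassigned,
    )


def _sq_dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2


def allocate_population(
    cells: Sequence[PopulationCell], origin_set: OriginSet
) -> OriginSet:
    """Distribute each cell's population equally among its selected origins.

    A cell of population ``P`` with ``k`` selected origins gives each origin
    weight ``P / k``, so weights within a cell always sum exactly to the cell
    population (conservation).  Cells that contributed no origin allocate
    nothing.
    """
    pop = {c.id: c.population for c in cells}
    counts: dict[str, int] = {}
    for o in origin_set.origins:
        if o.cell_id is None or o.cell_id not in pop:
            raise ValidationError(f"origin {o.node_id!r} has no cell attribution")
        counts[o.cell_id] = counts.get(o.cell_id, 0) + 1
    new = [replace(o, weight=pop[o.cell_id] / counts[o.cell_id]) for o in origin_set.origins]
    return replace(origin_set, origins=new)
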