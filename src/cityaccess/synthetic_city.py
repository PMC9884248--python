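"""Fully synthetic city generation for testing and tutorials.

Everything the pipeline consumes — road lattice, population grid, facilities,
hazard footprints — can be generated here deterministically from a seed, so
the whole methodology is exercisable without any download.

The generated city is a rows x cols street lattice with 4-neighbour edges
(an idealized orthogonal street grid), tiled by square population cells.
Facilities sit on randomly chosen intersections with lognormal footprint
areas, mimicking the long-tailed size distribution of real healthcare
facilities (many small clinics, few large hospitals).  Hazard bands are
rectangular flood footprints or straight fault lines crossing the lattice, so
the set of affected edges is predictable from geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, box

from .errors import ValidationError
from .hazards import HazardLayer
from .network_model import (
    Amenity,
    PopulationCell,
    RoadNetwork,
    SpeedTable,
    build_network,
)

__all__ = ["CitySpec", "generate_city", "generate_hazard_band", "fig2_fixture"]


@dataclass
class CitySpec:
    """Parameters of a synthetic lattice city.

    Population per cell is drawn uniform in ``pop_range`` (people); facility
    areas are lognormal with the given log-space parameters (median
    ``exp(area_mu_log)`` m^2).  ``arterial_period`` > 0 promotes every k-th
    row/column of streets to the arterial class.
    """

    rows: int = 6
    cols: int = 6
    spacing_m: float = 500.0
    speeds: dict = field(default_factory=lambda: {"local": 30.0, "arterial": 60.0})
    default_speed_kph: float = 30.0
    arterial_period: int = 0
    cell_size_m: float = 1000.0
    pop_range: tuple[float, float] = (200.0, 2000.0)
    n_facilities: int = 3
    area_mu_log: float = math.log(2000.0)
    area_sigma_log: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValidationError("lattice needs at least 2 rows and 2 cols")
        if not (self.spacing_m > 0 and self.cell_size_m > 0):
            raise ValidationError("spacing and cell size must be > 0")
        if self.n_facilities < 0:
            raise ValidationError("facility count must be >= 0")
        for v in (*self.pop_range, self.area_mu_log, self.area_sigma_log):
            if not math.isfinite(v):
                raise ValidationError("distribution parameters must be finite")


def _node_id(r: int, c: int) -> str:
    return f"n{r:03d}_{c:03d}"


def generate_city(
    spec: CitySpec,
) -> tuple[RoadNetwork, list[PopulationCell], list[Amenity]]:
    """Generate the lattice network, population cells and facilities.

    Deterministic under ``spec.seed``: repeated calls with an equal spec give
    identical node/edge sets, populations, facility placements and areas.
    A rows x cols lattice has ``rows*(cols-1) + cols*(rows-1)`` edges.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing_m

    nodes = [
        (_node_id(r, c), c * s, r * s) for r in range(spec.rows) for c in range(spec.cols)
    ]

    def road_class(r_or_c: int) -> str:
        if spec.arterial_period and r_or_c % spec.arterial_period == 0:
            return "arterial"
        return "local"

    edges = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            if c + 1 < spec.cols:  # horizontal street along row r
                edges.append(
                    {"u": _node_id(r, c), "v": _node_id(r, c + 1), "length": s,
                     "road_class": road_class(r)}
                )
            if r + 1 < spec.rows:  # vertical street along column c
                edges.append(
                    {"u": _node_id(r, c), "v": _node_id(r + 1, c), "length": s,
                     "road_class": road_class(c)}
                )
    table = SpeedTable(speeds=dict(spec.speeds), default_kph=spec.default_speed_kph)
    network = build_network(nodes, edges, table)

    # population cells tile the lattice bounding box (half-spacing margin so
    # boundary nodes are covered)
    xmin, ymin = -s / 2, -s / 2
    xmax = (spec.cols - 1) * s + s / 2
    ymax = (spec.rows - 1) * s + s / 2
    cells: list[PopulationCell] = []
    ncx = max(1, math.ceil((xmax - xmin) / spec.cell_size_m))
    ncy = max(1, math.ceil((ymax - ymin) / spec.cell_size_m))
    for iy in range(ncy):
        for ix in range(ncx):
            geom = box(
                xmin + ix * spec.cell_size_m,
                ymin + iy * spec.cell_size_m,
                min(xmin + (ix + 1) * spec.cell_size_m, xmax),
                min(ymin + (iy + 1) * spec.cell_size_m, ymax),
            )
            pop = float(rng.uniform(*spec.pop_range))
            cells.append(PopulationCell(id=f"cell_{iy}_{ix}", geometry=geom, population=pop))

    node_ids = sorted(network.graph.nodes)
    k = min(spec.n_facilities, len(node_ids))
    picked = rng.choice(len(node_ids), size=k, replace=False)
    amenities: list[Amenity] = []
    for rank, idx in enumerate(sorted(picked)):
        nid = node_ids[idx]
        x, y = network.node_xy(nid)
        area = float(rng.lognormal(spec.area_mu_log, spec.area_sigma_log))
        amenities.append(
            Amenity(
                id=f"fac{rank:02d}",
                name=f"Facility {rank}",
                x=x,
                y=y,
                node_id=nid,
                area_m2=area,
                service_type="health",
            )
        )
    return network, cells, amenities


def generate_hazard_band(
    network: RoadNetwork,
    kind: str,
    position_m: float,
    width_m: float = 100.0,
    depth_cm: float = 10.0,
    axis: str = "vertical",
    layer_id: str | None = None,
) -> HazardLayer:
    """A hazard footprint crossing the lattice at a given coordinate.

    ``axis='vertical'`` places the band at x = ``position_m`` spanning the full
    y-extent (and vice versa).  Floods become a rectangle of the given width
    and depth; faults become a straight linestring (width ignored).  A band
    entirely outside the network bounds yields an empty layer with a warning.
    """
    if not (width_m > 0):
        raise ValidationError("band width must be > 0")
    if kind not in ("flood", "fault"):
        raise ValidationError(f"unknown hazard kind {kind!r}")
    xmin, ymin, xmax, ymax = network.bounds()
    margin = 10.0
    lid = layer_id or f"{kind}_band"
    lo, hi = (xmin, xmax) if axis == "vertical" else (ymin, ymax)
    if position_m + width_m / 2 < lo or position_m - width_m / 2 > hi:
        warnings.warn(f"hazard band at {position_m} m lies outside the city bounds")
        return HazardLayer(id=lid, kind=kind, geometries=[])
    if kind == "flood":
        if axis == "vertical":
            geom = box(position_m - width_m / 2, ymin - margin, position_m + width_m / 2, ymax + margin)
        else:
            geom = box(xmin - margin, position_m - width_m / 2, xmax + margin, position_m + width_m / 2)
        return HazardLayer(id=lid, kind="flood", geometries=[(geom, float(depth_cm))])
    if axis == "vertical":
        line = LineString([(position_m, ymin - margin), (position_m, ymax + margin)])
    else:
        line = LineString([(xmin - margin, position_m), (xmax + margin, position_m)])
    return HazardLayer(id=lid, kind="fault", geometries=[(line, "synthetic")])


def fig2_fixture() -> tuple[
    RoadNetwork, list[PopulationCell], list[Amenity], list[HazardLayer]
]:
    """A small hand-coded city for tutorials and worked-example tests.

    Eleven intersections A..K, two healthcare facilities at H and J, four
    population cells Gr11/Gr12/Gr21/Gr22, one flood footprint and one fault
    line.  Qualitative layout (coordinates are illustrative, in meters):

    * fault-affected edges: A-D, D-E, E-B, E-F (within the 500 m buffer);
    * flood-affected edges: E-F, C-F, F-K, F-H, G-H, H-I (depth 8 cm);
    * E-F is hit by both hazards;
    * A's only link is A-D, so disrupting A-D isolates A's population.
    """
    coords = {
        "A": (0.0, 2000.0),
        "B": (2000.0, 2000.0),
        "C": (4000.0, 2000.0),
        "D": (0.0, 1000.0),
        "E": (2000.0, 1000.0),
        "F": (4000.0, 1000.0),
        "G": (1000.0, 0.0),
        "H": (2000.0, 0.0),
        "I": (3000.0, 0.0),
        "J": (5000.0, 0.0),
        "K": (5000.0, 1000.0),
    }
    pairs = [
        ("A", "D"), ("D", "E"), ("E", "B"), ("E", "F"), ("C", "F"),
        ("F", "K"), ("F", "H"), ("G", "H"), ("H", "I"), ("K", "J"),
    ]
    nodes = [(n, x, y) for n, (x, y) in coords.items()]
    edges = [
        {
            "u": u,
            "v": v,
            "length": math.dist(coords[u], coords[v]),
            "road_class": "local",
        }
        for u, v in pairs
    ]
    network = build_network(nodes, edges, SpeedTable(default_kph=30.0))

    cells = [
        PopulationCell("Gr11", box(-500, 500, 2200, 2500), 300.0),
        PopulationCell("Gr12", box(2200, 500, 5500, 2500), 200.0),
        PopulationCell("Gr21", box(-500, -2000, 2200, 500), 200.0),
        PopulationCell("Gr22", box(2200, -2000, 5500, 500), 100.0),
    ]

    amenities = [
        Amenity("H", "Hospital H", *coords["H"], node_id="H", area_m2=4000.0),
        Amenity("J", "Hospital J", *coords["J"], node_id="J", area_m2=2000.0),
    ]

    from shapely.geometry import Polygon

    flood = Polygon(
        [(1500, -300), (3200, -300), (4500, 200), (4500, 1200), (2500, 1200), (2200, 500)]
    )
    fault = LineString([(0, 1500), (2500, 1100)])
    layers = [
        HazardLayer(id="flood", kind="flood", geometries=[(flood, 8.0)]),
        HazardLayer(id="fault", kind="fault", geometries=[(fault, "100yr")]),
    ]
    return network, cells, amenities, layers
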