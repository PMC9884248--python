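"""Readers and writers for the supported plain-text formats.

Supported inputs (all coordinates in a projected metric CRS, meters):

* road network: a GeoJSON FeatureCollection mixing Point features
  (``id``) and LineString features (``u``, ``v``, ``length_m``, ``highway``,
  optional ``speed_kph``); or a CSV pair — nodes ``(id, x, y)`` and edges
  ``(u, v, length_m, highway)``;
* population: GeoJSON polygons with properties ``id`` (optional) and ``pop``;
* facilities: GeoJSON points or CSV with ``id, name, area_m2, service_type``
  (CSV additionally ``x, y``);
* hazard layers: GeoJSON with ``hazard_kind`` in {flood, fault}, ``depth_cm``
  for floods and ``return_period`` as a label.

Outputs are CSV (fixed 6-decimal numeric formatting for reproducible diffs),
GeoJSON, and JSON comparison reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import ValidationError
from .hazards import HazardLayer, Scenario
from .metrics import (
    AccessibilityResult,
    ChoiceMatrix,
    CriticalityResult,
    IsolationResult,
    ScenarioComparison,
)
from .network_model import (
    Amenity,
    PopulationCell,
    RoadNetwork,
    SpeedTable,
    build_network,
    snap_points,
)
from .routing import ODMatrix

FLOAT_FMT = "%.6f"


@dataclass
class ValidationReport:
    """Counts of records dropped or defaulted while loading inputs."""

    dropped: list[str] = field(default_factory=list)
    defaulted: list[str] = field(default_factory=list)

    def drop(self, msg: str) -> None:
        self.dropped.append(msg)

    def summary(self) -> str:
        return f"{len(self.dropped)} dropped, {len(self.defaulted)} defaulted"


def _load_feature_collection(path: str | Path) -> list[dict]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed GeoJSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def _dump_feature_collection(features: list[dict], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def write_network_geojson(network: RoadNetwork, path: str | Path) -> None:
    feats = []
    for nid, d in sorted(network.graph.nodes(data=True)):
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["x"], d["y"]]},
                "properties": {"id": nid},
            }
        )
    for u, v, d in sorted(network.graph.edges(data=True)):
        geom = network.edge_geometry(u, v)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "u": u,
                    "v": v,
                    "length_m": d["length"],
                    "highway": d["road_class"],
                    "speed_kph": d["speed"],
                },
            }
        )
    _dump_feature_collection(feats, path)


def read_network_geojson(
    path: str | Path, speed_table: SpeedTable | None = None
) -> RoadNetwork:
    from shapely.geometry import LineString

    nodes, edges = [], []
    for i, feat in enumerate(_load_feature_collection(path)):
        gtype = feat.get("geometry", {}).get("type")
        props = feat.get("properties", {})
        if gtype == "Point":
            x, y = feat["geometry"]["coordinates"][:2]
            nodes.append((str(props["id"]), x, y))
        elif gtype == "LineString":
            geom = shape(feat["geometry"])
            edges.append(
                {
                    "u": str(props["u"]),
                    "v": str(props["v"]),
                    "length": float(props["length_m"]),
                    "road_class": props.get("highway"),
                    "speed": props.get("speed_kph"),
                    "geometry": geom if len(geom.coords) > 2 else None,
                }
            )
        else:
            raise ValidationError(f"{path}: feature {i}: unsupported geometry {gtype!r}")
    return build_network(nodes, edges, speed_table)


def write_network_csv(network: RoadNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    nd = pd.DataFrame(
        [(n, d["x"], d["y"]) for n, d in sorted(network.graph.nodes(data=True))],
        columns=["id", "x", "y"],
    )
    ed = pd.DataFrame(
        [
            (u, v, d["length"], d["road_class"], d["speed"])
            for u, v, d in sorted(network.graph.edges(data=True))
        ],
        columns=["u", "v", "length_m", "highway", "speed_kph"],
    )
    nd.to_csv(nodes_path, index=False, float_format=FLOAT_FMT)
    ed.to_csv(edges_path, index=False, float_format=FLOAT_FMT)


def read_network_csv(
    nodes_path: str | Path, edges_path: str | Path, speed_table: SpeedTable | None = None
) -> RoadNetwork:
    nd = pd.read_csv(nodes_path, dtype={"id": str})
    ed = pd.read_csv(edges_path, dtype={"u": str, "v": str})
    nodes = [(r.id, r.x, r.y) for r in nd.itertuples()]
    edges = [
        {
            "u": r.u,
            "v": r.v,
            "length": r.length_m,
            "road_class": r.highway if isinstance(r.highway, str) else None,
            "speed": getattr(r, "speed_kph", None),
        }
        for r in ed.itertuples()
    ]
    return build_network(nodes, edges, speed_table)


# ---------------------------------------------------------------------------
# population / facilities / hazards
# ---------------------------------------------------------------------------

def write_population_geojson(cells: Sequence[PopulationCell], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(c.geometry),
            "properties": {"id": c.id, "pop": c.population},
        }
        for c in cells
    ]
    _dump_feature_collection(feats, path)


def read_population_geojson(
    path: str | Path, report: ValidationReport | None = None
) -> list[PopulationCell]:
    cells = []
    for i, feat in enumerate(_load_feature_collection(path)):
        props = feat.get("properties", {})
        try:
            cells.append(
                PopulationCell(
                    id=str(props.get("id", f"cell{i}")),
                    geometry=shape(feat["geometry"]),
                    population=float(props["pop"]),
                )
            )
        except (KeyError, ValidationError, ValueError) as exc:
            if report is None:
                raise ValidationError(f"{path}: feature {i}: {exc}") from exc
            report.drop(f"population feature {i}: {exc}")
    return cells


def write_facilities_geojson(amenities: Sequence[Amenity], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [a.x, a.y]},
            "properties": {
                "id": a.id,
                "name": a.name,
                "area_m2": a.area_m2,
                "service_type": a.service_type,
            },
        }
        for a in amenities
    ]
    _dump_feature_collection(feats, path)


def read_facilities(
    path: str | Path,
    network: RoadNetwork,
    report: ValidationReport | None = None,
) -> list[Amenity]:
    """Read facility points (GeoJSON or CSV) and snap them to the network.

    Rows with non-positive area are rejected and counted in the report.
    """
    path = Path(path)
    records: list[dict] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype={"id": str})
        for r in df.itertuples():
            records.append(
                {
                    "id": r.id,
                    "name": getattr(r, "name", r.id),
                    "x": r.x,
                    "y": r.y,
                    "area_m2": r.area_m2,
                    "service_type": getattr(r, "service_type", "health"),
                }
            )
    else:
        for i, feat in enumerate(_load_feature_collection(path)):
            props = feat.get("properties", {})
            x, y = feat["geometry"]["coordinates"][:2]
            records.append(
                {
                    "id": str(props.get("id", f"fac{i}")),
                    "name": props.get("name", props.get("id", f"fac{i}")),
                    "x": x,
                    "y": y,
                    "area_m2": props.get("area_m2"),
                    "service_type": props.get("service_type", "health"),
                }
            )
    amenities = []
    valid = []
    for rec in records:
        try:
            area = float(rec["area_m2"])
        except (TypeError, ValueError):
            area = -1.0
        if not area > 0:
            msg = f"facility {rec['id']!r}: area_m2 must be > 0 (got {rec['area_m2']!r})"
            if report is None:
                raise ValidationError(msg)
            report.drop(msg)
            continue
        valid.append(rec)
    snapped = snap_points(network, [(r["id"], r["x"], r["y"]) for r in valid])
    for rec, (_, node, _) in zip(valid, snapped):
        amenities.append(
            Amenity(
                id=rec["id"],
                name=str(rec["name"]),
                x=float(rec["x"]),
                y=float(rec["y"]),
                node_id=node,
                area_m2=float(rec["area_m2"]),
                service_type=str(rec["service_type"]),
            )
        )
    return amenities


def write_hazard_geojson(layer: HazardLayer, path: str | Path) -> None:
    feats = []
    for geom, intensity in layer.geometries:
        props = {"hazard_kind": layer.kind}
        if layer.kind == "flood":
            props["depth_cm"] = float(intensity)
        else:
            props["return_period"] = str(intensity)
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    _dump_feature_collection(feats, path)


def read_hazard_geojson(path: str | Path, layer_id: str | None = None) -> HazardLayer:
    geometries = []
    kind = None
    for i, feat in enumerate(_load_feature_collection(path)):
        props = feat.get("properties", {})
        k = props.get("hazard_kind")
        if k not in ("flood", "fault"):
            raise ValidationError(f"{path}: feature {i}: unknown hazard_kind {k!r}")
        if kind is None:
            kind = k
        elif k != kind:
            raise ValidationError(f"{path}: mixed hazard kinds in one layer")
        geom = shape(feat["geometry"])
        intensity = (
            float(props.get("depth_cm", 0.0)) if k == "flood" else props.get("return_period", "")
        )
        geometries.append((geom, intensity))
    if kind is None:
        raise ValidationError(f"{path}: hazard layer has no features")
    return HazardLayer(id=layer_id or Path(path).stem, kind=kind, geometries=geometries)


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def od_matrix_to_csv(od: ODMatrix, path: str | Path) -> None:
    """Long-format export: origin_id, facility_id, minutes, km, reachable."""
    rows = []
    for i, o in enumerate(od.origin_ids):
        for j, d in enumerate(od.dest_ids):
            t = od.times[i, j]
            rows.append(
                {
                    "origin_id": o,
                    "facility_id": d,
                    "minutes": t if np.isfinite(t) else np.nan,
                    "km": (
                        od.dists_km[i, j]
                        if od.dists_km is not None and np.isfinite(od.times[i, j])
                        else np.nan
                    ),
                    "reachable": bool(np.isfinite(t)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def accessibility_to_csv(
    access: AccessibilityResult,
    choice: ChoiceMatrix,
    weights,
    path: str | Path,
) -> None:
    top = choice.top_choice()
    df = pd.DataFrame(
        {
            "origin_id": access.origin_ids,
            "weight": np.asarray(weights, dtype=float),
            "accessibility_min": access.expected_min,
            "isolated": access.isolated,
            "top_choice_id": [t if t is not None else "" for t in top],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def criticality_to_csv(
    crit: CriticalityResult, path: str | Path, names: dict | None = None
) -> None:
    scaled = crit.scaled()
    rows = [
        {
            "edge_id": f"{u}--{v}",
            "u": u,
            "v": v,
            "name": (names or {}).get((u, v), ""),
            "criticality": score,
            "scaled": scaled[(u, v)],
            "rank": rank,
        }
        for rank, ((u, v), score) in enumerate(crit.ranked(), start=1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def criticality_to_geojson(
    crit: CriticalityResult, network: RoadNetwork, path: str | Path
) -> None:
    scaled = crit.scaled()
    feats = []
    for rank, ((u, v), score) in enumerate(crit.ranked(), start=1):
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(network.edge_geometry(u, v)),
                "properties": {
                    "edge_id": f"{u}--{v}",
                    "criticality": score,
                    "scaled": scaled[(u, v)],
                    "rank": rank,
                },
            }
        )
    _dump_feature_collection(feats, path)


def top_k_table(
    crit: CriticalityResult, k: int = 10, names: dict | None = None
) -> pd.DataFrame:
    """The k most critical segments (id, name, score), descending."""
    rows = [
        {
            "edge_id": f"{u}--{v}",
            "name": (names or {}).get((u, v), ""),
            "criticality": score,
        }
        for (u, v), score in crit.ranked()[:k]
    ]
    return pd.DataFrame(rows)


def isolation_to_json(iso: IsolationResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "isolated_population": iso.total_population,
                "isolated_origins": iso.isolated_origins,
            },
            indent=1,
        )
    )


def comparison_to_json(cmp: ScenarioComparison, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cmp.to_dict(), indent=1))
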