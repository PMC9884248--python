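"""End-to-end pipeline: load inputs, build scenarios, evaluate and write results.

For each scenario (baseline, one per hazard layer, and — with two or more
layers — a compound scenario) the pipeline writes the O-D matrix, the choice
matrix, per-origin accessibility, per-edge criticality with a top-k table,
and the isolation report; plus a comparison against the baseline for every
disrupted scenario.  A manifest records the config hash, seed and package
version so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import CityAccessError
from .geojson_io import (
    ValidationReport,
    accessibility_to_csv,
    comparison_to_json,
    criticality_to_csv,
    criticality_to_geojson,
    isolation_to_json,
    od_matrix_to_csv,
    read_facilities,
    read_hazard_geojson,
    read_network_csv,
    read_network_geojson,
    read_population_geojson,
    top_k_table,
)
from .hazards import HazardLayer, Scenario, baseline_scenario, compose_hazards, scenario_from_layer
from .metrics import (
    AccessibilityResult,
    ChoiceMatrix,
    CriticalityResult,
    IsolationResult,
    ServiceImportance,
    accessibility,
    choice_matrix,
    compare_scenarios,
    compound_aggregate,
    criticality,
    isolation,
)
from .network_model import (
    Amenity,
    OriginSet,
    PopulationCell,
    RoadNetwork,
    SpeedTable,
    allocate_population,
    sample_origins,
)
from .routing import travel_times

log = logging.getLogger("cityaccess")


@dataclass
class LoadedInputs:
    network: RoadNetwork
    cells: list[PopulationCell]
    amenities: list[Amenity]
    hazard_layers: list[tuple[HazardLayer, object]]  # (layer, rule)
    report: ValidationReport


@dataclass
class ScenarioResult:
    """All per-scenario measures, bundled for comparison and export."""

    scenario: Scenario
    od: object
    choice: ChoiceMatrix
    access: AccessibilityResult
    crit: CriticalityResult
    iso: IsolationResult


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Read and validate every input the config references."""
    report = ValidationReport()
    table = SpeedTable(speeds=dict(config.speeds), default_kph=config.default_speed_kph)
    if config.network_path:
        network = read_network_geojson(config.network_path, table)
    else:
        network = read_network_csv(config.nodes_path, config.edges_path, table)
    cells = read_population_geojson(config.population_path, report)
    amenities = read_facilities(config.facilities_path, network, report)
    layers = [
        (read_hazard_geojson(h.layer_path), h.rule()) for h in config.hazards
    ]
    log.info(
        "loaded network (%d nodes, %d edges), %d cells, %d facilities, %d hazard layers (%s)",
        network.graph.number_of_nodes(),
        network.graph.number_of_edges(),
        len(cells),
        len(amenities),
        len(layers),
        report.summary(),
    )
    return LoadedInputs(network, cells, amenities, layers, report)


def evaluate_scenario(
    scenario: Scenario,
    origin_set: OriginSet,
    amenities: list[Amenity],
    alpha: float | ServiceImportance = 1.0,
) -> ScenarioResult:
    """Compute O-D times, choices, accessibility, criticality and isolation."""
    nodes = origin_set.node_ids
    weights = origin_set.weights
    od = travel_times(
        scenario,
        nodes,
        [a.node_id for a in amenities],
        weights=weights,
        return_paths=True,
        with_distance=True,
    )
    # relabel destination columns (and path keys) from snapped nodes to
    # facility ids so that two facilities sharing a node stay distinct
    node_of = {a.id: a.node_id for a in amenities}
    od.dest_ids = [a.id for a in amenities]
    od.paths = {
        (o, a.id): od.paths[(o, node_of[a.id])]
        for o in set(nodes)
        for a in amenities
        if (o, node_of[a.id]) in od.paths
    }
    areas = [a.area_m2 for a in amenities]
    choice = choice_matrix(od, areas)
    access = accessibility(od, choice)
    crit = criticality(
        scenario, od, choice, weights=weights, alpha=alpha, amenities=amenities
    )
    iso = isolation(od, weights)
    log.info(
        "scenario %s: %d origins, %.1f isolated population, mean access %.2f min",
        scenario.name,
        len(nodes),
        iso.total_population,
        access.mean,
    )
    return ScenarioResult(scenario, od, choice, access, crit, iso)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis described by ``config``; returns output paths.

    Any stage failure is re-raised annotated with the stage name so a broken
    input is attributable.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "load_inputs"
    try:
        inputs = load_inputs(config)

        stage = "origin_sampling"
        origin_set = sample_origins(
            inputs.network,
            inputs.cells,
            config.strategy,
            seed=config.seed,
            grid_spacing_m=config.grid_spacing_m,
        )
        origin_set = allocate_population(inputs.cells, origin_set)

        stage = "scenario_construction"
        scenarios: list[Scenario] = [baseline_scenario(inputs.network)]
        for layer, rule in inputs.hazard_layers:
            scenarios.append(scenario_from_layer(inputs.network, layer, rule))
        if len(inputs.hazard_layers) >= 2:
            scenarios.append(compose_hazards(inputs.network, inputs.hazard_layers))

        alpha = ServiceImportance(alpha=config.alpha, default=config.default_alpha)

        stage = "evaluation"
        results: dict[str, ScenarioResult] = {}
        for sc in scenarios:
            results[sc.name] = evaluate_scenario(sc, origin_set, inputs.amenities, alpha)

        stage = "export"
        edge_names = {}
        for name, res in results.items():
            d = out_dir / name
            d.mkdir(exist_ok=True)
            od_matrix_to_csv(res.od, d / "od_matrix.csv")
            pd.DataFrame(
                res.choice.probabilities,
                index=res.choice.origin_ids,
                columns=res.choice.dest_ids,
            ).to_csv(d / "choice_matrix.csv", float_format="%.6f")
            accessibility_to_csv(res.access, res.choice, res.od.origin_weights,
                                 d / "accessibility.csv")
            criticality_to_csv(res.crit, d / "criticality.csv", edge_names)
            criticality_to_geojson(res.crit, res.scenario.network, d / "criticality.geojson")
            top_k_table(res.crit, config.top_k, edge_names).to_csv(
                d / "top_segments.csv", index=False, float_format="%.6f"
            )
            isolation_to_json(res.iso, d / "isolation.json")
            outputs[name] = d

        stage = "compound_aggregation"
        hazard_names = [sc.name for sc in scenarios[1:] if sc.name != "compound"]
        if len(hazard_names) >= 2:
            d = out_dir / "compound"
            for mode in config.compound_modes:
                agg = compound_aggregate([results[n].crit for n in hazard_names], mode)
                criticality_to_csv(agg, d / f"criticality_{mode}.csv", edge_names)
            acc = compound_aggregate([results[n].access for n in hazard_names], "max")
            accessibility_to_csv(
                acc, results["compound"].choice, origin_set.weights,
                d / "accessibility_max.csv",
            )

        stage = "comparison"
        base = results["baseline"]
        for name, res in results.items():
            if name == "baseline":
                continue
            cmp = compare_scenarios(
                base.access,
                base.choice,
                res.access,
                res.choice,
                origin_set.weights,
                n_bins=config.comparison_bins,
            )
            p = out_dir / f"comparison_{name}.json"
            comparison_to_json(cmp, p)
            outputs[f"comparison_{name}"] = p

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "scenarios": list(results),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        outputs["manifest"] = out_dir / "manifest.json"
    except CityAccessError as exc:
        raise CityAccessError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return outputs
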