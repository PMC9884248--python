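"""Run configuration: a YAML file describing inputs, parameters and outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .hazards import HazardRule
from .network_model import SAMPLING_STRATEGIES
from .routing import PartitionConfig


@dataclass
class HazardConfig:
    """One hazard layer plus the rule parameters applied to it."""

    layer_path: str
    rho: float = 3.0
    penalize_cm: float = 5.0
    disrupt_cm: float = 15.0
    fault_buffer_m: float = 500.0

    def rule(self) -> HazardRule:
        return HazardRule(
            rho=self.rho,
            penalize_cm=self.penalize_cm,
            disrupt_cm=self.disrupt_cm,
            fault_buffer_m=self.fault_buffer_m,
        )


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Network input is either a single GeoJSON (``network_path``) or a CSV pair
    (``nodes_path`` + ``edges_path``).
    """

    population_path: str
    facilities_path: str
    output_dir: str
    network_path: str | None = None
    nodes_path: str | None = None
    edges_path: str | None = None
    hazards: list[HazardConfig] = field(default_factory=list)
    strategy: str = "RANDOM_5PCT"
    seed: int = 0
    grid_spacing_m: float = 1000.0
    speeds: dict = field(default_factory=dict)
    default_speed_kph: float = 30.0
    partition: PartitionConfig | None = None
    alpha: dict = field(default_factory=dict)
    default_alpha: float = 1.0
    comparison_bins: int = 256
    compound_modes: tuple[str, ...] = ("sum", "max")
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.strategy not in SAMPLING_STRATEGIES:
            raise ValidationError(f"unknown sampling strategy {self.strategy!r}")
        if self.network_path is None and (self.nodes_path is None or self.edges_path is None):
            raise ValidationError("config needs network_path or nodes_path + edges_path")
        for p in self._input_paths():
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    def _input_paths(self) -> list[str]:
        paths = [self.population_path, self.facilities_path]
        paths += [p for p in (self.network_path, self.nodes_path, self.edges_path) if p]
        paths += [h.layer_path for h in self.hazards]
        return paths


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; relative paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p):
        return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

    hazards = [
        HazardConfig(layer_path=resolve(h.pop("layer_path")), **h)
        for h in raw.pop("hazards", [])
    ]
    part = raw.pop("partition", None)
    partition = PartitionConfig(**part) if part else None
    for key in ("network_path", "nodes_path", "edges_path", "population_path",
                "facilities_path", "output_dir"):
        if key in raw and raw[key]:
            raw[key] = resolve(raw[key])
    if "compound_modes" in raw:
        raw["compound_modes"] = tuple(raw["compound_modes"])
    return RunConfig(hazards=hazards, partition=partition, **raw)
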