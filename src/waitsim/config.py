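"""Structured config file: one YAML document drives every pipeline stage.

Block names mirror the dataclass field names exactly, so a config round-trips
through the domain objects without translation tables. Unknown keys are
rejected early with the offending field named.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationTargets
from .errors import ConfigurationError
from .grid import GridSpec
from .hazards import HazardParams
from .prioritization import BudgetConstraint, GroupScheme
from .risk_population import PopulationParams

#: Registry counts used to form default calibration targets (2019 fiscal
#: year referral cohort): referrals, waitlist removals, procedures, waitlist
#: deaths, patients with >= 1 unplanned hospitalization, unscheduled
#: procedures.
DEFAULT_REGISTRY_COUNTS = {
    "referrals": 3030,
    "removed": 803,
    "tavis": 1330,
    "deaths": 81,
    "hospitalized": 756,
    "unscheduled": 202,
}


@dataclass
class RunConfig:
    """Everything a pipeline invocation needs, with defaults for all blocks."""

    population: PopulationParams = field(
        default_factory=lambda: PopulationParams(n_patients=50_000)
    )
    hazards: HazardParams = field(default_factory=HazardParams)
    constraint: BudgetConstraint = field(default_factory=BudgetConstraint)
    scheme: GroupScheme | None = None
    targets: CalibrationTargets | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    n_replicates: int = 100
    seed: int = 0

    def config_hash(self) -> str:
        """Short stable digest of the effective configuration."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d: dict = {
            "population": _dataclass_dict(self.population),
            "hazards": _dataclass_dict(self.hazards),
            "constraint": _dataclass_dict(self.constraint),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "grid": {
                "high_sizes": list(self.grid.high_sizes),
                "medium_sizes": list(self.grid.medium_sizes),
                "high_waits": list(self.grid.high_waits),
                "medium_increments": list(self.grid.medium_increments),
                "include_equal_thirds": self.grid.include_equal_thirds,
                "include_two_group": self.grid.include_two_group,
                "classifier_outcome": self.grid.classifier_outcome,
            },
        }
        if self.scheme is not None:
            d["scheme"] = {
                "sizes": list(self.scheme.sizes),
                "waits_prioritized": list(self.scheme.waits_prioritized),
                "classifier_outcome": self.scheme.classifier_outcome,
            }
        if self.targets is not None:
            d["targets"] = _dataclass_dict(self.targets)
        return d


def _dataclass_dict(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


def _build(cls, block: dict, name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigurationError(f"invalid '{name}' block: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; absent blocks fall back to package defaults."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
    cfg = RunConfig()
    known = {
        "population", "hazards", "constraint", "scheme", "targets", "grid",
        "n_replicates", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    if "population" in raw:
        cfg.population = _build(PopulationParams, raw["population"], "population")
    if "hazards" in raw:
        cfg.hazards = _build(HazardParams, raw["hazards"], "hazards")
    if "constraint" in raw:
        cfg.constraint = _build(BudgetConstraint, raw["constraint"], "constraint")
    if "scheme" in raw and raw["scheme"] is not None:
        block = dict(raw["scheme"])
        if "sizes" in block:
            block["sizes"] = tuple(block["sizes"])
        if "waits_prioritized" in block:
            block["waits_prioritized"] = tuple(block["waits_prioritized"])
        cfg.scheme = _build(GroupScheme, block, "scheme")
    if "targets" in raw and raw["targets"] is not None:
        cfg.targets = _build(CalibrationTargets, raw["targets"], "targets")
    if "grid" in raw:
        block = dict(raw["grid"])
        for key in ("high_sizes", "medium_sizes", "high_waits", "medium_increments"):
            if key in block:
                block[key] = tuple(block[key])
        cfg.grid = _build(GridSpec, block, "grid")
    if "n_replicates" in raw:
        cfg.n_replicates = int(raw["n_replicates"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg


def hazards_to_yaml(hazards: HazardParams, path: str | Path, meta: dict | None = None) -> None:
    doc = {"hazards": _dataclass_dict(hazards)}
    if meta:
        doc["meta"] = meta
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def hazards_from_yaml(path: str | Path) -> HazardParams:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "hazards" not in doc:
        raise ConfigurationError(f"{path} is not a fitted-hazards file (no 'hazards' block)")
    return _build(HazardParams, doc["hazards"], "hazards")
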