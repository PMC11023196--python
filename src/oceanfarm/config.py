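"""Scenario configuration and YAML round-tripping.

A :class:`ScenarioConfig` fully specifies one simulation: the species,
the lattice, the fishery regime and economics, and (optionally) a farm
design.  Configs serialize to/from plain YAML mappings with blocks
``species:``, ``fishery:``, ``farm:`` and top-level simulation controls,
so a scenario is reproducible from a single text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .farm_design import FarmDesign
from .fishing import FisheryConfig
from .life_history import SpeciesParams

__all__ = ["ScenarioConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario to equilibrium."""

    species: SpeciesParams = field(default_factory=SpeciesParams)
    fishery: Optional[FisheryConfig] = field(default_factory=FisheryConfig)
    farm: Optional[FarmDesign] = None
    n_patches: int = 100
    total_biomass_target: float = 1000.0
    max_years: int = 500
    convergence_tol: float = 1e-6
    convergence_window: int = 10
    density_dependent_movement: bool = True

    def with_farm(self, farm: Optional[FarmDesign]) -> "ScenarioConfig":
        return replace(self, farm=farm)

    def without_farm(self) -> "ScenarioConfig":
        return replace(self, farm=None)

    def to_dict(self) -> dict:
        d: dict = {
            "n_patches": self.n_patches,
            "total_biomass_target": self.total_biomass_target,
            "max_years": self.max_years,
            "convergence_tol": self.convergence_tol,
            "convergence_window": self.convergence_window,
            "density_dependent_movement": self.density_dependent_movement,
            "species": dataclasses.asdict(self.species),
        }
        if self.fishery is not None:
            d["fishery"] = dataclasses.asdict(self.fishery)
        if self.farm is not None:
            d["farm"] = dataclasses.asdict(self.farm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        kwargs = {
            k: d[k]
            for k in (
                "n_patches",
                "total_biomass_target",
                "max_years",
                "convergence_tol",
                "convergence_window",
                "density_dependent_movement",
            )
            if k in d
        }
        if "species" in d:
            kwargs["species"] = SpeciesParams(**d["species"])
        kwargs["fishery"] = (
            FisheryConfig(**d["fishery"]) if d.get("fishery") is not None else None
        )
        if d.get("farm") is not None:
            kwargs["farm"] = FarmDesign(**d["farm"])
        return cls(**kwargs)


def load_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
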