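"""Scenario configuration and seeded randomness.

A :class:`ScenarioConfig` carries every parameter shared by the landscape
generator, the habitat-network builder, the dispersal simulation and the
optimisation model.  All randomness in a scenario fans out from a single
integer seed into named substreams, so any stage (landscape, patch draw,
source draw, ...) can be regenerated independently and two runs with the
same ``(config, seed)`` are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

log = logging.getLogger("dendriflow")


class ConfigError(ValueError):
    """Raised when a scenario configuration is invalid."""


#: Named substreams fanned out from the scenario seed, in a fixed order.
SUBSTREAMS = (
    "landcover",
    "streams",
    "patches",
    "qualities",
    "sources",
    "destinations",
    "instances",
)

_INT_FIELDS = {"sim_max_steps", "horizon_block", "seed", "rows", "cols"}
_STR_FIELDS = {"allocation", "growth"}


@dataclass
class ScenarioConfig:
    """Parameters of one scenario.

    Lengths are metres, costs are dispersal cost-units per cell, biomass is
    in arbitrary biomass units.  ``C_max`` is derived, never set directly:
    it is the cost budget equivalent to dispersing ``max_dispersal_m``
    through open agricultural land.
    """

    cell_size_m: float = 100.0
    max_dispersal_m: float = 2500.0
    agriculture_cost: float = 50.0
    forest_cost: float = 75.0
    urban_cost: float = 100.0
    aquatic_cost: float = 25.0
    #: colonisation threshold: minimum viable population in biomass units
    T_SH: float = 10.0
    #: fraction of its carrying capacity a source habitat may emit per step
    S_DIS: float = 0.1
    #: carrying capacity of a perfect-quality (quality = 1) patch
    K_max: float = 100.0
    habitat_fraction: float = 0.10
    source_fraction: float = 0.10
    sim_max_steps: int = 250
    horizon_block: int = 30
    seed: int = 0
    # landscape extent and composition
    rows: int = 150
    cols: int = 150
    #: fraction of grid cells occupied by the stream network
    aquatic_fraction: float = 0.078
    #: percolation density of the random-cluster landcover generator
    cluster_fill: float = 0.55
    proportions: dict[str, float] = field(
        default_factory=lambda: {"agriculture": 0.666, "forest": 0.111, "urban": 0.222}
    )
    #: neighbour-share weighting in the simulation: "survival" or "inverse_cost"
    allocation: str = "survival"
    #: post-threshold growth model: "instant" or "logistic"
    growth: str = "instant"
    growth_rate: float = 0.5
    #: derived cost budget (agriculture_cost x cells of maximum dispersal)
    C_max: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.validate()
        derive_cmax(self)

    def validate(self) -> None:
        if not 0.0 < self.S_DIS < 1.0:
            raise ConfigError(f"S_DIS must lie in (0, 1), got {self.S_DIS}")
        if self.T_SH <= 0:
            raise ConfigError(f"T_SH must be positive, got {self.T_SH}")
        for name in ("agriculture_cost", "forest_cost", "urban_cost", "aquatic_cost"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("habitat_fraction", "source_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.K_max <= 0:
            raise ConfigError(f"K_max must be positive, got {self.K_max}")
        for name in ("cell_size_m", "max_dispersal_m", "growth_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("sim_max_steps", "horizon_block", "rows", "cols"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 < self.aquatic_fraction < 1.0:
            raise ConfigError(f"aquatic_fraction must lie in (0, 1), got {self.aquatic_fraction}")
        if not 0.0 < self.cluster_fill <= 1.0:
            raise ConfigError(f"cluster_fill must lie in (0, 1], got {self.cluster_fill}")
        if self.allocation not in ("survival", "inverse_cost"):
            raise ConfigError(f"allocation must be 'survival' or 'inverse_cost', got {self.allocation!r}")
        if self.growth not in ("instant", "logistic"):
            raise ConfigError(f"growth must be 'instant' or 'logistic', got {self.growth!r}")

    # -- seeded randomness -------------------------------------------------

    def rng(self, stage: str) -> np.random.Generator:
        """Return the named per-stage random substream of this scenario."""
        return substream(self.seed, stage)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str) -> None:
        d = self.to_dict()
        d.pop("C_max")  # derived
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def derive_cmax(config: ScenarioConfig) -> float:
    """Derive the dispersal cost budget ``C_max`` and store it on *config*.

    The budget equals the cost of crossing ``max_dispersal_m / cell_size_m``
    cells of agricultural land; the cell count must be integral.
    """
    ratio = config.max_dispersal_m / config.cell_size_m
    cells = round(ratio)
    if abs(ratio - cells) > 1e-9 or cells < 1:
        raise ConfigError(
            f"cell_size_m ({config.cell_size_m}) must divide "
            f"max_dispersal_m ({config.max_dispersal_m})"
        )
    config.C_max = config.agriculture_cost * cells
    return config.C_max


def substream(seed: int, stage: str) -> np.random.Generator:
    """Derive the named random substream of a scenario seed."""
    try:
        key = SUBSTREAMS.index(stage)
    except ValueError:
        raise ValueError(f"unknown substream {stage!r}; known: {SUBSTREAMS}") from None
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def load_config(path: str) -> ScenarioConfig:
    """Load and validate a scenario configuration from a JSON file.

    Missing fields take their documented defaults; an unknown or ill-typed
    field raises :class:`ConfigError` naming the field.
    """
    with open(path) as fh:
        data = json.load(fh)
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a JSON object")
    known = {f.name for f in dataclasses.fields(ScenarioConfig) if f.init}
    for key, value in data.items():
        if key == "C_max":
            raise ConfigError("C_max is derived from agriculture_cost and the dispersal distance; do not set it")
        if key not in known:
            raise ConfigError(f"unknown configuration field {key!r}")
        if key in _INT_FIELDS:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"field {key!r} must be an integer, got {value!r}")
        elif key in _STR_FIELDS:
            if not isinstance(value, str):
                raise ConfigError(f"field {key!r} must be a string, got {value!r}")
        elif key == "proportions":
            if not isinstance(value, dict) or not all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in value.values()
            ):
                raise ConfigError("field 'proportions' must map class names to numbers")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"field {key!r} must be a number, got {value!r}")
    try:
        return ScenarioConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
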