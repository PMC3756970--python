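"""Simulation parameters: validation, derived fecundity quantities, file I/O.

The parameter set describes a broadcast-spawning reef fish whose pelagic
larvae drift on ocean currents for a fixed number of days before settling.
Defaults correspond to a panther-grouper-like life history: 40-day larval
duration, instantaneous larval mortality Z_p = 0.2 d⁻¹, adult mortality
Z = 0.26 y⁻¹, 15,000 viable larvae per monthly spawn packed into 20
transport kernels, and habitat tolerances of 16–32.82 °C, 1–40 m depth and
0.10–99.981 µg L⁻¹ chlorophyll.  The current weight dominates the neighbor
scoring (0.90 raw, normalized against the three 0.02 habitat weights).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModelConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "viable_propagules",
    "larvae_per_kernel",
    "per_cycle_hazards",
]


class ConfigError(ValueError):
    """A configuration value violates its documented constraint."""


@dataclass
class ModelConfig:
    """Full parameter set of one simulation.

    Ranges are (min, max) inclusive; weights are relative and normalized to
    sum to one on construction.  ``cycles`` counts 30-day monthly steps.
    """

    cycles: int = 78                  # monthly steps (60 in the original table)
    grid_size: float = 6.0            # lattice resolution, arc-minutes
    sst_range: tuple[float, float] = (16.0, 32.820)     # °C
    sst_weight: float = 0.02
    cc_range: tuple[float, float] = (0.10, 99.981)      # µg L⁻¹
    cc_weight: float = 0.02
    depth_range: tuple[float, float] = (1.0, 40.0)      # m, positive down
    depth_weight: float = 0.02
    current_weight: float = 0.90
    propagule_duration: float = 40.0  # D, days adrift before settlement
    propagule_mortality: float = 0.2  # Z_p, d⁻¹ instantaneous larval mortality
    breeding_age: int = 18            # A_b, months from settlement to maturity
    adult_mortality: float = 0.26     # Z, y⁻¹ instantaneous adult mortality
    egg_quantity: float = 200_000.0   # eggs per spawn
    fertilization_rate: float = 0.25
    hatching_rate: float = 0.30
    propagule_quantity: int | None = None  # Q viable larvae; derived if None
    kernel_count: int = 20            # K transport kernels per spawn
    breeding_window: tuple[int, int] = (1, 12)  # first, last calendar month
    spawns_per_cycle: int = 1
    starting_month: int = 1           # SM, 1 = January
    rng_seed: int | None = None
    # behaviour flags
    mortality_mode: str = "hazard"    # "hazard": 1-exp(-Z/12) per cycle; "literal": Z per cycle
    min_current_speed: float = 0.01   # m s⁻¹ floor so per-cell dwell stays finite
    graded_suitability: bool = False  # triangular score inside range instead of binary
    founder_immortal: bool = False    # exempt the founder from the adult Z test

    def __post_init__(self) -> None:
        self._validate()
        total = self.sst_weight + self.cc_weight + self.depth_weight + self.current_weight
        self.sst_weight /= total
        self.cc_weight /= total
        self.depth_weight /= total
        self.current_weight /= total
        if self.propagule_quantity is None:
            self.propagule_quantity = viable_propagules(
                self.egg_quantity, self.fertilization_rate, self.hatching_rate
            )

    def _validate(self) -> None:
        def fail(name: str, msg: str) -> None:
            raise ConfigError(f"{name}: {msg}")

        if self.cycles < 1:
            fail("cycles", "must be >= 1")
        if self.grid_size <= 0:
            fail("grid_size", "must be > 0")
        for name in ("sst_range", "cc_range", "depth_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                fail(name, f"min {lo} exceeds max {hi}")
        weights = {
            "sst_weight": self.sst_weight,
            "cc_weight": self.cc_weight,
            "depth_weight": self.depth_weight,
            "current_weight": self.current_weight,
        }
        for name, w in weights.items():
            if w < 0:
                fail(name, "must be >= 0")
        if sum(weights.values()) <= 0:
            fail("current_weight", "at least one weight must be > 0")
        if self.propagule_duration <= 0:
            fail("propagule_duration", "must be > 0")
        if self.propagule_mortality < 0:
            fail("propagule_mortality", "must be >= 0")
        if self.adult_mortality < 0:
            fail("adult_mortality", "must be >= 0")
        if self.breeding_age < 0:
            fail("breeding_age", "must be >= 0")
        if self.kernel_count < 1:
            fail("kernel_count", "must be >= 1")
        if self.egg_quantity < 0:
            fail("egg_quantity", "must be >= 0")
        for name in ("fertilization_rate", "hatching_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                fail(name, "must lie in [0, 1]")
        if self.propagule_quantity is not None and self.propagule_quantity < 0:
            fail("propagule_quantity", "must be >= 0")
        if not 1 <= self.starting_month <= 12:
            fail("starting_month", "must lie in 1..12")
        lo, hi = self.breeding_window
        if not (1 <= lo <= 12 and 1 <= hi <= 12):
            fail("breeding_window", "months must lie in 1..12")
        if self.spawns_per_cycle < 0:
            fail("spawns_per_cycle", "must be >= 0")
        if self.mortality_mode not in ("hazard", "literal"):
            fail("mortality_mode", "must be 'hazard' or 'literal'")
        if self.min_current_speed <= 0:
            fail("min_current_speed", "must be > 0")

    def replace(self, **changes) -> "ModelConfig":
        """New config with ``changes`` applied and invariants re-checked."""
        return dataclasses.replace(self, **changes)

    def month_in_breeding_window(self, calendar_month: int) -> bool:
        lo, hi = self.breeding_window
        if lo <= hi:
            return lo <= calendar_month <= hi
        return calendar_month >= lo or calendar_month <= hi  # wraps past December

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sst_range", "cc_range", "depth_range", "breeding_window"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        """Stable short hash for run-provenance sidecars."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_TUPLE_FIELDS = {"sst_range", "cc_range", "depth_range", "breeding_window"}
_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelConfig)}


def load_config(path: str | Path) -> ModelConfig:
    """Read a flat key-value YAML file; unspecified fields take defaults.

    Raises :class:`ConfigError` naming the offending field on unknown keys
    or invariant violations.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat mapping, got {type(raw).__name__}")
    kwargs = {}
    for key, value in raw.items():
        if key not in _FIELD_NAMES:
            raise ConfigError(f"{key}: unknown parameter")
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"{key}: expected a [min, max] pair")
            value = tuple(value)
        kwargs[key] = value
    return ModelConfig(**kwargs)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write every field as flat YAML so a run can be reproduced exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=None)
    )


def viable_propagules(egg_quantity: float, fertilization_rate: float,
                      hatching_rate: float) -> int:
    """Viable larvae per spawn: eggs × fertilization × hatching, rounded.

    With the default 200,000 eggs, 25% fertilization and 30% hatching this
    gives the canonical 15,000 larvae per monthly spawning event.
    """
    if not 0.0 <= fertilization_rate <= 1.0:
        raise ConfigError("fertilization_rate: must lie in [0, 1]")
    if not 0.0 <= hatching_rate <= 1.0:
        raise ConfigError("hatching_rate: must lie in [0, 1]")
    if egg_quantity < 0:
        raise ConfigError("egg_quantity: must be >= 0")
    return round(egg_quantity * fertilization_rate * hatching_rate)


def larvae_per_kernel(Q: float, K: int) -> tuple[int, float]:
    """Split Q viable larvae across K kernels.

    Returns ``(larvae_per_kernel, kernel_ratio)`` where the ratio K/Q is
    rounded to 4 decimals (0.0013 for the default 15,000 larvae / 20
    kernels, i.e. ~750 larvae per kernel).
    """
    if K < 1:
        raise ConfigError("kernel_count: must be >= 1")
    return round(Q / K), round(K / Q, 4)


def per_cycle_hazards(config: ModelConfig) -> tuple[float, float]:
    """Per-event survival/death probabilities from the instantaneous rates.

    Returns ``(larval_transport_survival, adult_monthly_death)``:
    exp(−Z_p·D) for a kernel surviving its whole drift, and the monthly
    adult death probability.  In the default ``hazard`` mode the annual
    rate Z converts to 1 − exp(−Z/12) per 30-day cycle; ``literal`` mode
    uses Z directly as a per-cycle probability (the rule "random value
    falls below Z" taken at face value).
    """
    survival = math.exp(-config.propagule_mortality * config.propagule_duration)
    if config.mortality_mode == "hazard":
        death = 1.0 - math.exp(-config.adult_mortality / 12.0)
    else:
        death = min(1.0, config.adult_mortality)
    return survival, death
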