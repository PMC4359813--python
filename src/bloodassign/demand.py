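"""Seeded synthetic generator of daily request and donation volumes.

Each day and each blood type draws an independent percentage u between the
configured lower and upper bounds; the day's volume for that type is
round(u/100 × share × initial_volume × turnover), where share is the type's
normalized population proportion.  Seven built-in scenarios cover the study
grid: initial volumes 500/1000/2000, horizons of 90 and 365 days, and
balanced ([25,75]/[25,75]) or skewed bounds.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .blood_types import TYPE_ORDER, BloodType, PROPORTIONS_NORMALIZED
from .dpso import PSOParams

__all__ = [
    "ScenarioConfig",
    "daily_requests",
    "daily_donations",
    "builtin_datasets",
    "dataset",
    "load_config",
    "save_config",
]

Bounds = Tuple[float, float]


@dataclass(frozen=True)
class ScenarioConfig:
    """A full simulation scenario.

    Parameters
    ----------
    initial_volume : total units in the bank on day 0, split by proportions.
    horizon : number of simulated days.
    request_bounds, donation_bounds : (lower %, upper %) of each type's
        proportional share of the initial volume drawn per day.
    seed : master seed; the simulator derives independent substreams for
        requests, donations and the swarm from it.
    turnover : scale factor on the per-day base volume (1.0 = the share of
        the initial volume itself).
    shelf_life : days a unit stays usable.
    """

    initial_volume: int = 500
    horizon: int = 90
    request_bounds: Bounds = (25.0, 75.0)
    donation_bounds: Bounds = (25.0, 75.0)
    seed: int = 0
    turnover: float = 1.0
    shelf_life: int = 30
    pso: PSOParams = field(default_factory=PSOParams)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("request_bounds", self.request_bounds),
            ("donation_bounds", self.donation_bounds),
        ):
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"{name} must satisfy 0 <= lower <= upper <= 100")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 day")
        if self.initial_volume < 0:
            raise ValueError("initial_volume must be non-negative")
        if self.turnover < 0:
            raise ValueError("turnover must be non-negative")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _draw(cfg: ScenarioConfig, rng: np.random.Generator, bounds: Bounds) -> Dict[BloodType, int]:
    lo, hi = bounds
    u = rng.uniform(lo, hi, size=len(TYPE_ORDER))
    out = {}
    for pct, t in zip(u, TYPE_ORDER):
        base = float(PROPORTIONS_NORMALIZED[t]) * cfg.initial_volume * cfg.turnover
        out[t] = _round_half_up(pct / 100.0 * base)
    return out


def daily_requests(
    cfg: ScenarioConfig, rng: np.random.Generator, day: int
) -> Dict[BloodType, int]:
    """One day's requested units per type (independent draw per type)."""
    return _draw(cfg, rng, cfg.request_bounds)


def daily_donations(
    cfg: ScenarioConfig, rng: np.random.Generator, day: int
) -> Dict[BloodType, int]:
    """One day's donated units per type; same contract as requests."""
    return _draw(cfg, rng, cfg.donation_bounds)


#: (initial_volume, horizon, request_bounds, donation_bounds)
_DATASET_GRID = (
    (500, 90, (25.0, 75.0), (25.0, 75.0)),
    (1000, 90, (25.0, 75.0), (25.0, 75.0)),
    (2000, 90, (25.0, 75.0), (25.0, 75.0)),
    (1000, 90, (25.0, 75.0), (30.0, 75.0)),
    (1000, 90, (30.0, 75.0), (25.0, 75.0)),
    (500, 365, (25.0, 75.0), (25.0, 75.0)),
    (1000, 365, (25.0, 75.0), (25.0, 75.0)),
)


def builtin_datasets(seed: int = 0) -> Tuple[ScenarioConfig, ...]:
    """The seven built-in scenarios, in order (dataset 1 is index 0)."""
    return tuple(
        ScenarioConfig(v, h, rb, db, seed=seed) for v, h, rb, db in _DATASET_GRID
    )


def dataset(number: int, seed: int = 0, **overrides) -> ScenarioConfig:
    """Built-in scenario by its 1-based number, with optional field overrides."""
    if not 1 <= number <= len(_DATASET_GRID):
        raise ValueError(f"dataset number must be in 1..{len(_DATASET_GRID)}")
    cfg = builtin_datasets(seed)[number - 1]
    return replace(cfg, **overrides) if overrides else cfg


# -- config file round-trip ------------------------------------------------

def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["request_bounds"] = list(cfg.request_bounds)
    d["donation_bounds"] = list(cfg.donation_bounds)
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    pso = d.pop("pso", {}) or {}
    for key in ("request_bounds", "donation_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(pso=PSOParams(**pso), **d)


def save_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> ScenarioConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
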