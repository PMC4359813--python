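"""Daily operating loop of the blood bank.

Each simulated day: record opening stock, draw the day's requests, choose
an assignment (swarm-optimized or greedy baseline), issue the supplied
units FIFO and book the imports, enqueue the day's donations, and finally
incinerate units older than the shelf life.  Imports arrive from outside
the bank and are transfused immediately; they never enter the queues.
Requests, donations and the swarm draw from three independent substreams
of the scenario seed, so optimizer and baseline runs can be compared on
identical demand streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .blood_types import TYPE_ORDER, BloodType
from .inventory import Bank
from .demand import ScenarioConfig, daily_donations, daily_requests
from .assignment import KnapsackDay, SupplyPlan, bottom_up_assign
from .dpso import optimize_day

__all__ = ["DailyRecord", "RunSummary", "RunResult", "run", "summarize", "records_to_frame"]

_FIELDS = ("available", "requested", "supplied", "imported", "donated", "expired")

# substream tags hashed into the seed sequence
_STREAM_REQUESTS, _STREAM_DONATIONS, _STREAM_SWARM = 1, 2, 3


@dataclass(frozen=True)
class DailyRecord:
    """Per-type unit counts for one simulated day.

    ``available`` is the opening stock (before any issue); ``supplied`` and
    ``imported`` partition the day's demand, so per type
    requested = supplied-to-that-knapsack + imported-to-that-knapsack holds
    in the baseline, and in aggregate (Σ supplied + Σ imported = Σ requested)
    in optimizer mode, where a knapsack may be filled with compatible units
    of other types.
    """

    day: int
    available: Dict[BloodType, int]
    requested: Dict[BloodType, int]
    supplied: Dict[BloodType, int]
    imported: Dict[BloodType, int]
    donated: Dict[BloodType, int]
    expired: Dict[BloodType, int]


@dataclass(frozen=True)
class RunSummary:
    """Horizon means per type plus run totals, as the result tables report."""

    mean_available: Dict[BloodType, float]
    mean_requested: Dict[BloodType, float]
    mean_supplied: Dict[BloodType, float]
    mean_imported: Dict[BloodType, float]
    total_imported: int
    total_requested: int
    total_expired: int

    @property
    def import_to_request_ratio(self) -> float:
        """Σ imported / Σ requested over the whole horizon (0 if no demand)."""
        if self.total_requested == 0:
            return 0.0
        return self.total_imported / self.total_requested

    def to_frame(self) -> pd.DataFrame:
        """Result-table layout: one row per measure, one column per type."""
        cols = [t.label for t in TYPE_ORDER]
        data = {
            "Available in bank": [self.mean_available[t] for t in TYPE_ORDER],
            "Requested": [self.mean_requested[t] for t in TYPE_ORDER],
            "Supplied": [self.mean_supplied[t] for t in TYPE_ORDER],
            "Imported into bank": [self.mean_imported[t] for t in TYPE_ORDER],
        }
        return pd.DataFrame(data, index=cols).T


@dataclass(frozen=True)
class RunResult:
    records: List[DailyRecord]
    summary: RunSummary
    trace: List[Tuple[int, int, int]]  # (day, iterations, gbest fitness)

    def __iter__(self):  # allows: records, summary = run(cfg)
        return iter((self.records, self.summary))


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, *extra]))


def run(cfg: ScenarioConfig, mode: str = "pso") -> RunResult:
    """Simulate the bank over ``cfg.horizon`` days.

    ``mode`` selects the assignment engine: ``"pso"`` runs the swarm each
    day (seeded with the greedy solution, early-stopped at the max-flow
    bound); ``"baseline"`` uses the greedy bottom-up assignment alone.
    Returns the per-day records, the horizon summary and, in pso mode, the
    per-day (iterations, best fitness) convergence trace.
    """
    if mode not in ("pso", "baseline"):
        raise ValueError("mode must be 'pso' or 'baseline'")
    bank = Bank.with_initial_stock(cfg.initial_volume, day=0, shelf_life=cfg.shelf_life)
    rng_req = _rng(cfg.seed, _STREAM_REQUESTS)
    rng_don = _rng(cfg.seed, _STREAM_DONATIONS)

    records: List[DailyRecord] = []
    trace: List[Tuple[int, int, int]] = []
    for day in range(1, cfg.horizon + 1):
        available = bank.stock_levels()
        requests = daily_requests(cfg, rng_req, day)

        if mode == "pso":
            result = optimize_day(
                KnapsackDay(requests, available),
                cfg.pso,
                _rng(cfg.seed, _STREAM_SWARM, day),
            )
            plan = result.plan
            trace.append((day, result.iterations, result.fitness))
        else:
            _, plan = bottom_up_assign(requests, available)

        for t, n in plan.supplied.items():
            if n:
                bank.dequeue_supply(t, n)

        donations = daily_donations(cfg, rng_don, day)
        bank.enqueue_donations(day, donations)
        expired = bank.expire(day)

        records.append(
            DailyRecord(
                day=day,
                available=available,
                requested=requests,
                supplied=dict(plan.supplied),
                imported=dict(plan.imported),
                donated=donations,
                expired=expired,
            )
        )
    return RunResult(records, summarize(records), trace)


def summarize(records: List[DailyRecord]) -> RunSummary:
    """Arithmetic means per type over the horizon, plus run totals."""
    if not records:
        raise ValueError("cannot summarize an empty run")
    n = len(records)

    def mean_of(field: str) -> Dict[BloodType, float]:
        return {
            t: sum(getattr(r, field)[t] for r in records) / n for t in TYPE_ORDER
        }

    total_imported = sum(sum(r.imported.values()) for r in records)
    total_requested = sum(sum(r.requested.values()) for r in records)
    total_expired = sum(sum(r.expired.values()) for r in records)
    return RunSummary(
        mean_available=mean_of("available"),
        mean_requested=mean_of("requested"),
        mean_supplied=mean_of("supplied"),
        mean_imported=mean_of("imported"),
        total_imported=total_imported,
        total_requested=total_requested,
        total_expired=total_expired,
    )


def records_to_frame(records: List[DailyRecord]) -> pd.DataFrame:
    """Long-form table: one row per (day, type) with all six unit counts."""
    rows = []
    for r in records:
        for t in TYPE_ORDER:
            rows.append(
                {
                    "day": r.day,
                    "type": t.label,
                    **{f: getattr(r, f)[t] for f in _FIELDS},
                }
            )
    return pd.DataFrame(rows)
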