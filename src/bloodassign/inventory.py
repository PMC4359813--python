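"""FIFO, age-tracked perishable store of red-cell units.

Each blood type has its own queue: donated units are enqueued at the back,
supplied units are dequeued from the front, so the oldest stock is always
issued first.  Units whose age strictly exceeds the shelf life (30 days by
default) are incinerated at end of day.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

from .blood_types import BloodType, initial_stock

__all__ = ["BloodUnit", "Bank", "DEFAULT_SHELF_LIFE"]

DEFAULT_SHELF_LIFE = 30


@dataclass(frozen=True)
class BloodUnit:
    """A single red-cell unit: its type and the day it entered the bank."""

    type: BloodType
    donated_on: int

    def age(self, day: int) -> int:
        return day - self.donated_on


class Bank:
    """Per-type FIFO queues of blood units.

    Queues store donation days only (the type is the queue key); front of
    each queue is the oldest unit.  All mutating operations preserve the
    non-decreasing age order, provided days are fed in chronological order.
    """

    def __init__(
        self,
        stock: Optional[Mapping[BloodType, Iterable[int]]] = None,
        shelf_life: int = DEFAULT_SHELF_LIFE,
    ) -> None:
        if shelf_life <= 0:
            raise ValueError("shelf_life must be positive")
        self.shelf_life = shelf_life
        self.queues: Dict[BloodType, deque] = {t: deque() for t in BloodType}
        if stock:
            for t, days in stock.items():
                self.queues[t].extend(sorted(days))

    @classmethod
    def with_initial_stock(
        cls, total: int, day: int = 0, shelf_life: int = DEFAULT_SHELF_LIFE
    ) -> "Bank":
        """Bank seeded with `total` units split by population proportions.

        All seed units carry ``donated_on = day`` (fresh stock), so the
        warm-up period is not distorted by a burst of expiries.
        """
        counts = initial_stock(total)
        return cls({t: [day] * n for t, n in counts.items()}, shelf_life)

    # -- operations --------------------------------------------------------

    def enqueue_donations(self, day: int, donations: Mapping[BloodType, int]) -> None:
        """Append freshly donated units at the back of their type queues."""
        for t, n in donations.items():
            if n < 0:
                raise ValueError(f"negative donation count for {t.label}")
            self.queues[t].extend([day] * n)

    def dequeue_supply(self, type: BloodType, n: int) -> List[BloodUnit]:
        """Remove and return the `n` oldest units of `type`, oldest first.

        Raises if `n` exceeds the current stock: callers must route excess
        demand to importation before drawing from the bank.
        """
        q = self.queues[type]
        if n < 0:
            raise ValueError("cannot dequeue a negative number of units")
        if n > len(q):
            raise ValueError(
                f"requested {n} units of {type.label} but only {len(q)} in stock"
            )
        return [BloodUnit(type, q.popleft()) for _ in range(n)]

    def expire(self, day: int) -> Dict[BloodType, int]:
        """Incinerate every unit older than the shelf life; return counts.

        The predicate is strict (age > shelf_life): a unit is still usable
        on the day its age equals the shelf life and removed after.
        """
        removed = {}
        for t, q in self.queues.items():
            n = 0
            while q and day - q[0] > self.shelf_life:
                q.popleft()
                n += 1
            removed[t] = n
        return removed

    def stock_levels(self) -> Dict[BloodType, int]:
        return {t: len(q) for t, q in self.queues.items()}

    def total_units(self) -> int:
        return sum(len(q) for q in self.queues.values())

    def max_age(self, day: int) -> int:
        """Age of the oldest unit in the bank (−1 if empty)."""
        fronts = [day - q[0] for q in self.queues.values() if q]
        return max(fronts, default=-1)

    # -- snapshots ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Aggregated snapshot: one row per (type, donated_on) with a count."""
        rows = []
        for t, q in self.queues.items():
            counts: Dict[int, int] = {}
            for d in q:
                counts[d] = counts.get(d, 0) + 1
            for d in sorted(counts):
                rows.append({"type": t.label, "donated_on": d, "count": counts[d]})
        return pd.DataFrame(rows, columns=["type", "donated_on", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shelf_life: int = DEFAULT_SHELF_LIFE) -> "Bank":
        df = pd.read_csv(Path(path))
        stock: Dict[BloodType, List[int]] = {t: [] for t in BloodType}
        for _, row in df.iterrows():
            stock[BloodType.from_label(str(row["type"]))].extend(
                [int(row["donated_on"])] * int(row["count"])
            )
        return cls(stock, shelf_life)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        levels = ", ".join(f"{t.label}:{len(q)}" for t, q in self.queues.items())
        return f"Bank({levels})"
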