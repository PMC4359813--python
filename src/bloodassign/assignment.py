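"""Compatibility-constrained assignment of blood units to daily requests.

Each day's requests induce one knapsack per blood type with positive
demand; the knapsack's capacity is the demanded unit count and only
compatible donor units may be placed in it.  A candidate assignment is a
symbol string, grouped by knapsack in the canonical type order
(O+, O−, A+, A−, B+, B−, C+, C−), one symbol per demanded unit.  Units the
bank cannot cover are imported; the objective throughout is the total
number of imported units.

This module provides the string representation plus its repair operator,
the fitness (import count), the greedy bottom-up baseline that spends the
least-flexible compatible stock first, and an exact minimum-import oracle
via maximum flow on the donor→receiver bipartite graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .blood_types import (
    CODE_OF,
    COMPAT_MATRIX,
    TYPE_ORDER,
    BloodType,
    compatible_donors,
)

__all__ = [
    "Assignment",
    "SupplyPlan",
    "KnapsackDay",
    "bottom_up_assign",
    "fitness",
    "repair",
    "min_import_oracle",
    "plan_from_assignment",
]

#: char code -> type code lookup (-1 = invalid symbol)
_SYMBOL_LUT = np.full(128, -1, dtype=np.int8)
for _t in TYPE_ORDER:
    _SYMBOL_LUT[ord(_t.symbol)] = CODE_OF[_t]

_SYMBOLS = np.array([t.symbol for t in TYPE_ORDER])


def _demand_vector(requests: Mapping[BloodType, int]) -> np.ndarray:
    d = np.zeros(8, dtype=np.int64)
    for t, n in requests.items():
        if n < 0:
            raise ValueError(f"negative demand for {t.label}")
        d[CODE_OF[t]] = n
    return d


def _stock_vector(stock: Mapping[BloodType, int]) -> np.ndarray:
    s = np.zeros(8, dtype=np.int64)
    for t, n in stock.items():
        if n < 0:
            raise ValueError(f"negative stock for {t.label}")
        s[CODE_OF[t]] = n
    return s


def _counts_to_mapping(v: np.ndarray) -> Dict[BloodType, int]:
    return {t: int(v[i]) for i, t in enumerate(TYPE_ORDER)}


@dataclass(frozen=True)
class Assignment:
    """A grouped symbol string: one donor symbol per requested unit.

    ``codes`` holds the integer type code of each placed unit; ``demands``
    is the 8-vector of knapsack capacities in canonical order, so group g
    occupies ``demands[:g].sum() : demands[:g+1].sum()``.
    """

    codes: np.ndarray
    demands: np.ndarray

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int8)
        demands = np.asarray(self.demands, dtype=np.int64)
        if demands.shape != (8,):
            raise ValueError("demands must be a length-8 vector")
        if codes.ndim != 1 or len(codes) != int(demands.sum()):
            raise ValueError(
                f"assignment length {len(codes)} != total demand {int(demands.sum())}"
            )
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "demands", demands)

    @classmethod
    def from_symbols(cls, symbols: str, requests: Mapping[BloodType, int]) -> "Assignment":
        codes = _SYMBOL_LUT[np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = symbols[int(np.argmax(codes < 0))]
            raise ValueError(f"unknown blood-type symbol {bad!r}")
        return cls(codes, _demand_vector(requests))

    @property
    def symbols(self) -> str:
        return "".join(_SYMBOLS[self.codes])

    @property
    def receivers(self) -> np.ndarray:
        """Per-dimension knapsack (receiver) code."""
        return np.repeat(np.arange(8, dtype=np.int8), self.demands)

    def groups(self) -> Dict[BloodType, str]:
        """Symbol string of each knapsack with positive demand."""
        out, start = {}, 0
        for i, t in enumerate(TYPE_ORDER):
            n = int(self.demands[i])
            if n:
                out[t] = "".join(_SYMBOLS[self.codes[start : start + n]])
            start += n
        return out

    def used_counts(self) -> np.ndarray:
        """Units of each donor type placed anywhere in the string."""
        return np.bincount(self.codes, minlength=8).astype(np.int64)

    def is_valid(self) -> bool:
        """True iff every symbol is compatible with its knapsack's type."""
        return bool(COMPAT_MATRIX[self.receivers, self.codes].all())

    def __len__(self) -> int:
        return len(self.codes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Assignment)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.demands, other.demands)
        )


@dataclass(frozen=True)
class SupplyPlan:
    """How a day's demand was met: units drawn from the bank vs imported."""

    supplied: Dict[BloodType, int]
    imported: Dict[BloodType, int]

    @property
    def total_supplied(self) -> int:
        return sum(self.supplied.values())

    @property
    def total_imported(self) -> int:
        return sum(self.imported.values())

    @property
    def total(self) -> int:
        """T = S + Σ imports: every demanded unit is either supplied or imported."""
        return self.total_supplied + self.total_imported


@dataclass(frozen=True)
class KnapsackDay:
    """One day's assignment instance: per-type demand and available stock."""

    requests: Dict[BloodType, int]
    stock: Dict[BloodType, int]

    @property
    def demand_vector(self) -> np.ndarray:
        return _demand_vector(self.requests)

    @property
    def stock_vector(self) -> np.ndarray:
        return _stock_vector(self.stock)

    @property
    def dimension(self) -> int:
        """Particle length: total units requested that day."""
        return int(self.demand_vector.sum())


def bottom_up_assign(
    requests: Mapping[BloodType, int], stock: Mapping[BloodType, int]
) -> Tuple[Assignment, SupplyPlan]:
    """Greedy cross-matching baseline.

    Knapsacks are processed in canonical type order; each is filled from a
    working copy of the stock following the ``compatible_donors`` preference
    order (own type first, O− last).  Whatever remains after O− is booked as
    an import of the requested type, so every knapsack ends exactly full.
    """
    demands = _demand_vector(requests)
    work = _stock_vector(stock).copy()
    supplied = np.zeros(8, dtype=np.int64)
    imported = np.zeros(8, dtype=np.int64)
    pieces = []
    for r in TYPE_ORDER:
        remaining = int(demands[CODE_OF[r]])
        for donor in compatible_donors(r):
            if remaining == 0:
                break
            dcode = CODE_OF[donor]
            take = min(remaining, int(work[dcode]))
            if take:
                pieces.append(np.full(take, dcode, dtype=np.int8))
                work[dcode] -= take
                supplied[dcode] += take
                remaining -= take
        if remaining:
            rcode = CODE_OF[r]
            pieces.append(np.full(remaining, rcode, dtype=np.int8))
            imported[rcode] += remaining
    codes = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int8)
    plan = SupplyPlan(_counts_to_mapping(supplied), _counts_to_mapping(imported))
    return Assignment(codes, demands), plan


def fitness(a: Assignment, stock: Mapping[BloodType, int]) -> int:
    """Total units the assignment must import: Σ_type max(0, used − stock).

    Requires a compatibility-valid assignment (run ``repair`` first);
    invariant under permutations of symbols within a knapsack group.
    """
    if not a.is_valid():
        raise ValueError("assignment contains incompatible placements; repair first")
    used = a.used_counts()
    short = used - _stock_vector(stock)
    return int(np.clip(short, 0, None).sum())


def repair(a: Assignment) -> Assignment:
    """Replace every incompatible symbol with its knapsack's own type symbol.

    Idempotent; the result always satisfies the placement constraint.
    """
    receivers = a.receivers
    valid = COMPAT_MATRIX[receivers, a.codes]
    if valid.all():
        return a
    return Assignment(np.where(valid, a.codes, receivers), a.demands)


def plan_from_assignment(
    a: Assignment, stock: Mapping[BloodType, int]
) -> SupplyPlan:
    """Decode an assignment against stock: cap each type's use at its stock,
    book the residual as imports of that (placed) type."""
    used = a.used_counts()
    s = _stock_vector(stock)
    supplied = np.minimum(used, s)
    imported = used - supplied
    return SupplyPlan(_counts_to_mapping(supplied), _counts_to_mapping(imported))


def min_import_oracle(
    requests: Mapping[BloodType, int], stock: Mapping[BloodType, int]
) -> int:
    """Exact minimum total imports over all compatibility-valid assignments.

    Total demand minus the value of a maximum flow on the bipartite graph
    source → donor types (stock capacities) → compatible receiver types
    (demand capacities) → sink.
    """
    demands = _demand_vector(requests)
    s = _stock_vector(stock)
    total_demand = int(demands.sum())
    if total_demand == 0:
        return 0
    g = nx.DiGraph()
    for i, t in enumerate(TYPE_ORDER):
        if s[i]:
            g.add_edge("src", ("d", i), capacity=int(s[i]))
        if demands[i]:
            g.add_edge(("r", i), "sink", capacity=int(demands[i]))
    for r in range(8):
        if demands[r] == 0:
            continue
        for d in range(8):
            if s[d] and COMPAT_MATRIX[r, d]:
                g.add_edge(("d", d), ("r", r))  # uncapacitated
    if "src" not in g or "sink" not in g:
        return total_demand
    flow = nx.maximum_flow_value(g, "src", "sink")
    return total_demand - int(flow)
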