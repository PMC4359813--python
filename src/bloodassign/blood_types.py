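"""Static model of the eight ABO/Rhesus blood types.

The bank handles red-cell units of the eight Rhesus-qualified ABO types,
written here with single-character symbols: uppercase for Rh-positive,
lowercase for Rh-negative, and ``C`` standing for AB (so ``C+`` is the
universal receiver and ``o`` = O− the universal donor).  This module holds
the compatibility matrix, the per-type numeric values used by the discrete
PSO transform (receivable-donor count out of 27), and the South African
population proportions used to split volumes across types.
"""

from __future__ import annotations

from enum import Enum
from fractions import Fraction
from functools import lru_cache
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BloodType",
    "RECEIVES",
    "PROPORTIONS_RAW",
    "PROPORTIONS_NORMALIZED",
    "compatible_donors",
    "donor_reach",
    "type_value",
    "initial_stock",
    "rhesus_split",
    "compatibility_table",
    "values_table",
]


class BloodType(Enum):
    """One of the 8 Rhesus-qualified blood types.

    Member order is the canonical knapsack order used throughout the
    package: O+, O−, A+, A−, B+, B−, C+, C−.  The enum value is the
    one-character symbol (uppercase = Rh-positive).
    """

    O_POS = "O"
    O_NEG = "o"
    A_POS = "A"
    A_NEG = "a"
    B_POS = "B"
    B_NEG = "b"
    C_POS = "C"
    C_NEG = "c"

    @property
    def symbol(self) -> str:
        return self.value

    @property
    def is_positive(self) -> bool:
        return self.value.isupper()

    @property
    def rhesus(self) -> str:
        return "+" if self.is_positive else "-"

    @property
    def label(self) -> str:
        """Human-readable name, e.g. ``"O+"`` or ``"C-"``."""
        return self.value.upper() + self.rhesus

    @classmethod
    def from_symbol(cls, symbol: str) -> "BloodType":
        try:
            return cls(symbol)
        except ValueError:
            raise ValueError(f"unknown blood-type symbol {symbol!r}") from None

    @classmethod
    def from_label(cls, label: str) -> "BloodType":
        label = label.replace("−", "-").replace("–", "-")
        for t in cls:
            if t.label == label:
                return t
        raise ValueError(f"unknown blood-type label {label!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BloodType.{self.name}"


#: Canonical (knapsack) ordering of the types; index = integer code.
TYPE_ORDER: Tuple[BloodType, ...] = tuple(BloodType)
CODE_OF: Dict[BloodType, int] = {t: i for i, t in enumerate(TYPE_ORDER)}

_B = BloodType

#: receiver -> set of donor types whose red cells it can safely receive.
#: ABO/Rh cross-match rules: identical type always works, Rh− can serve the
#: matching Rh+ type, O serves A/B/AB of matching-or-weaker Rh, and AB+ (C+)
#: receives everything while O− (o) receives only itself.
RECEIVES: Dict[BloodType, frozenset] = {
    _B.O_POS: frozenset({_B.O_POS, _B.O_NEG}),
    _B.O_NEG: frozenset({_B.O_NEG}),
    _B.A_POS: frozenset({_B.A_POS, _B.A_NEG, _B.O_POS, _B.O_NEG}),
    _B.A_NEG: frozenset({_B.A_NEG, _B.O_NEG}),
    _B.B_POS: frozenset({_B.B_POS, _B.B_NEG, _B.O_POS, _B.O_NEG}),
    _B.B_NEG: frozenset({_B.B_NEG, _B.O_NEG}),
    _B.C_POS: frozenset(BloodType),
    _B.C_NEG: frozenset({_B.C_NEG, _B.A_NEG, _B.B_NEG, _B.O_NEG}),
}

#: Population share of each type, in percent, as published for South Africa.
#: The printed figures sum to 101; ``PROPORTIONS_NORMALIZED`` rescales them
#: to an exact probability distribution.
PROPORTIONS_RAW: Dict[BloodType, int] = {
    _B.O_POS: 39,
    _B.O_NEG: 7,
    _B.A_POS: 32,
    _B.A_NEG: 5,
    _B.B_POS: 12,
    _B.B_NEG: 2,
    _B.C_POS: 3,
    _B.C_NEG: 1,
}

_RAW_SUM = sum(PROPORTIONS_RAW.values())  # 101

PROPORTIONS_NORMALIZED: Dict[BloodType, Fraction] = {
    t: Fraction(p, _RAW_SUM) for t, p in PROPORTIONS_RAW.items()
}


@lru_cache(maxsize=None)
def donor_reach(donor: BloodType) -> int:
    """Number of receiver types this donor's red cells can serve."""
    return sum(donor in RECEIVES[r] for r in BloodType)


@lru_cache(maxsize=None)
def compatible_donors(receiver: BloodType) -> Tuple[BloodType, ...]:
    """Donor types usable for `receiver`, in cross-match preference order.

    The receiver's own type comes first; the remaining compatible donors
    follow in ascending donor reach (how many receiver types that donor can
    serve), so the least flexible stock is spent first.  Ties are broken by
    same-Rhesus-as-receiver first, then alphabetical symbol.  O− (reach 8)
    is therefore always last.
    """
    others = sorted(
        (d for d in RECEIVES[receiver] if d is not receiver),
        key=lambda d: (
            donor_reach(d),
            d.is_positive != receiver.is_positive,
            d.symbol.upper(),
        ),
    )
    return (receiver, *others)


def type_value(t: BloodType) -> Fraction:
    """PSO numeric value of a type: receivable-donor count over 27.

    27 is the total number of YES cells in the compatibility matrix, so the
    eight values sum to exactly 1.  The two-decimal figures used in display
    (0.15, 0.07, ...) are rounding only; arithmetic uses the exact rational.
    """
    return Fraction(len(RECEIVES[t]), 27)


def rhesus_split() -> Tuple[int, int]:
    """(sum of Rh-positive shares, sum of Rh-negative shares), in percent."""
    pos = sum(p for t, p in PROPORTIONS_RAW.items() if t.is_positive)
    neg = sum(p for t, p in PROPORTIONS_RAW.items() if not t.is_positive)
    return pos, neg


def initial_stock(total: int) -> Dict[BloodType, int]:
    """Split `total` units across types by the normalized proportions.

    Uses largest-remainder rounding so the counts sum exactly to `total`.
    Remainder ties go to the larger population share first, then canonical
    order, which keeps the allocation deterministic.
    """
    if total < 0:
        raise ValueError("total stock must be non-negative")
    quotas = {t: PROPORTIONS_NORMALIZED[t] * total for t in BloodType}
    counts = {t: int(q) for t, q in quotas.items()}
    shortfall = total - sum(counts.values())
    by_remainder = sorted(
        BloodType,
        key=lambda t: (quotas[t] - counts[t], PROPORTIONS_RAW[t], -CODE_OF[t]),
        reverse=True,
    )
    for t in by_remainder[:shortfall]:
        counts[t] += 1
    return counts


def compatibility_table() -> pd.DataFrame:
    """The receiver × donor compatibility matrix as a boolean DataFrame."""
    labels = [t.label for t in TYPE_ORDER]
    data = [[d in RECEIVES[r] for d in TYPE_ORDER] for r in TYPE_ORDER]
    return pd.DataFrame(data, index=labels, columns=labels)


def values_table() -> pd.DataFrame:
    """Per-type value (exact and 2-dp display) and population share."""
    rows = []
    for t in TYPE_ORDER:
        v = type_value(t)
        rows.append(
            {
                "type": t.label,
                "value": f"{v.numerator}/{v.denominator}",
                "value_float": round(float(v), 2),
                "proportion_pct": PROPORTIONS_RAW[t],
            }
        )
    return pd.DataFrame(rows).set_index("type")


# --- integer-coded views used by the vectorized optimizer -----------------

#: boolean matrix, COMPAT_MATRIX[receiver_code, donor_code]
COMPAT_MATRIX = np.array(
    [[d in RECEIVES[r] for d in TYPE_ORDER] for r in TYPE_ORDER], dtype=bool
)

#: float value per type code (exact rationals cast to double)
VALUE_ARRAY = np.array([float(type_value(t)) for t in TYPE_ORDER])

#: DONOR_ORDER_MATRIX[r, i] = code of the i-th preferred donor for receiver
#: code r; unused tail padded with the receiver's own code.
#: DONOR_COUNT[r] = number of compatible donors.
DONOR_COUNT = np.array([len(RECEIVES[t]) for t in TYPE_ORDER])
DONOR_ORDER_MATRIX = np.array(
    [
        [CODE_OF[d] for d in compatible_donors(r)]
        + [CODE_OF[r]] * (8 - len(RECEIVES[r]))
        for r in TYPE_ORDER
    ],
    dtype=np.int8,
)
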