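"""Half-up rounding helpers.

Report-level rounding is half-up (0.5 rounds away from zero), not
banker's rounding, so that printed shares like 46% from 16/35 come out
as a reader computes them by hand.  Ratios of integer counts are formed
in ``Decimal`` to avoid float-representation artifacts at the rounding
boundary.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def ratio_round(numerator: int, denominator: int, ndigits: int) -> float:
    """Half-up rounding of an exact integer ratio."""
    if denominator == 0:
        raise ZeroDivisionError("ratio_round with zero denominator")
    quantum = Decimal(1).scaleb(-ndigits)
    exact = Decimal(numerator) / Decimal(denominator)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 0) -> float:
    """``100 * count / total`` rounded half-up to ``ndigits`` decimals."""
    return ratio_round(100 * count, total, ndigits)


def exact_fraction(numerator: int, denominator: int) -> Fraction:
    """Exact rational value of a count ratio (for tests and invariants)."""
    return Fraction(numerator, denominator)
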