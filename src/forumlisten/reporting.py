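"""Display arithmetic shared by all reporting layers.

Every percentage printed anywhere in the package goes through :func:`pct`
so that rounding behaviour (half-up, fixed decimals) is defined in exactly
one place and reports stay re-derivable from the integer counts stored
alongside them.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), not banker's rounding."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    Exact rational arithmetic is used before rounding so binary floating
    point cannot flip a boundary case.
    """
    if denominator == 0:
        raise ZeroDivisionError("pct: zero denominator")
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)


def combined_count(*counts: int) -> int:
    """Sum of integer counts (summary aggregation for combined mentions)."""
    total = 0
    for c in counts:
        if c != int(c) or c < 0:
            raise ValueError(f"counts must be non-negative integers, got {c!r}")
        total += int(c)
    return total


def significance_tier(p: float | None, tiers: tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
    """Map a p-value onto the tiered annotation used in report tables.

    Returns one of ``"p<.001"``, ``"p<.01"``, ``"p<.05"`` or ``"ns"``.
    """
    if p is None:
        return "na"
    a5, a1, a01 = tiers
    if not (a5 > a1 > a01):
        raise ValueError("alpha tiers must be strictly decreasing")
    if p < a01:
        return "p<.001"
    if p < a1:
        return "p<.01"
    if p < a5:
        return "p<.05"
    return "ns"
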