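"""Shared rounding conventions.

Every rounded quantity in the package (displayed weighting coefficients,
integer gap-area totals, even-panel medians, percentages) uses the same
convention: round half away from zero. Python's built-in ``round`` uses
banker's rounding, which would silently disagree on exact halves.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    >>> round_half_away(2.5)
    3.0
    >>> round_half_away(-2.5)
    -3.0
    >>> round_half_away(100 / 24, 2)
    4.17
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
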