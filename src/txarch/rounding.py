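"""Half-up decimal rounding for reported percentages.

Python's built-in ``round`` is banker's rounding; published percentages in this
field are conventionally rounded half-up, so summaries go through here.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero on the half."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, decimals: int) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Raises ``ValueError`` on a zero denominator.
    """
    if denominator == 0:
        raise ValueError("percentage undefined for zero denominator")
    if decimals not in (1, 2):
        raise ValueError("decimals must be 1 or 2")
    return round_half_up(100.0 * numerator / denominator, decimals)
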