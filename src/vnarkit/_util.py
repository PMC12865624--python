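"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero-half up.

    Python's built-in ``round`` uses banker's rounding (0.5 -> 0); printed
    repertoire percentages follow the conventional half-up rule instead
    (37.45 -> 37.5 at one decimal, 72.5 -> 73 at zero decimals).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 0) -> float | int:
    """100*count/total rounded half-up; returns an int when ndigits == 0."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = round_half_up(100.0 * count / total, ndigits)
    return int(pct) if ndigits == 0 else pct
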