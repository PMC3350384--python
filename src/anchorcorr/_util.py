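"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places with ties going away from zero.

    Summary tables in this package report percentages rounded half-up
    (so 37.5% -> 38%, 66.67% -> 67%), which differs from Python's
    built-in banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct_half_up(k: float, total: float, ndigits: int = 0) -> float:
    """Percentage ``100*k/total`` rounded half-up."""
    if total == 0:
        raise ValueError("cannot compute a percentage of a zero total")
    return round_half_up(100.0 * k / total, ndigits)
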