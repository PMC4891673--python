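"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def ratio_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact percentage ``numerator / denominator * 100`` rounded half-up.

    Report tables round half-up (so 13/15 -> 86.67, 437/926 -> 47.19);
    float banker's rounding would disagree on ties, hence Decimal.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round a float half-up (report convention; avoids banker's rounding)."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(exp, rounding=ROUND_HALF_UP))
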