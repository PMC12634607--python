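"""Small shared helpers: half-up rounding and percentage formatting.

Printed pharmacovigilance tables round half-up (2.5 -> 3), whereas Python's
built-in ``round`` uses banker's rounding; every percentage the package
reports goes through :func:`round_half_up` so count and percentage columns
stay mutually consistent.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percentage"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 2) -> float | None:
    """``100 * count / total`` rounded half-up; ``None`` when total is 0."""
    if total == 0:
        return None
    return round_half_up(100.0 * count / total, ndigits)
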