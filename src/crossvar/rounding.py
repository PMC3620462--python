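"""Shared report-time rounding.

All internal arithmetic is exact (integer counts, :class:`~decimal.Decimal`
ratios); rounding happens once, at report time.  Percentages round half away
from zero to 2 decimal places.  Empty denominators yield ``None`` (rendered
"NA", never "0.00%").
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_DOWN, ROUND_HALF_UP


def round_half_away(x: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimal places."""
    d = x if isinstance(x, Decimal) else Decimal(str(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def round_half_toward_zero(x: float | Decimal, ndigits: int = 2) -> float:
    """Round to nearest with ties toward zero (used for derived differences
    such as callability gains, so a gain is never overstated)."""
    d = x if isinstance(x, Decimal) else Decimal(str(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_DOWN))


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float | None:
    """``100 * numerator / denominator`` rounded half away from zero, or
    ``None`` for a zero denominator."""
    if denominator == 0:
        return None
    ratio = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    return round_half_away(ratio, ndigits)


def fmt_pct(value: float | None, ndigits: int = 2) -> str:
    return "NA" if value is None else f"{value:.{ndigits}f}%"
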