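"""Report-precision rounding.

All printed percentages and table entries use round-half-up at the column's
precision (2 decimals for tables, integers for prose-style figures), computed
through :mod:`decimal` so that count ratios round exactly rather than through
binary floating point.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def _as_decimal(x) -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, (int,)):
        return Decimal(x)
    return Decimal(str(float(x)))


def round_half_up(x, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(_as_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part, whole, ndigits: int = 2) -> float:
    """``100 * part / whole`` rounded half-up; exact for integer counts."""
    whole = _as_decimal(whole)
    if whole == 0:
        raise ValueError("percentage undefined for a zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    frac = 100 * _as_decimal(part) / whole
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))
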