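"""Presentation formatting for report tables."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def format_scientific(p: float) -> str:
    """Render a p-value in upper-case E-notation: 3 significant digits,
    two-digit signed exponent (e.g. ``1.56E-15``).

    Rounding is half-even on the decimal representation, so boundary cases
    like 6.275e-9 render as 6.28E-09.  Values at or above 0.001 are still
    rendered in E-notation for column uniformity.  Input must lie in (0, 1].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    d = Decimal(repr(p))
    q = d.quantize(Decimal(1).scaleb(d.adjusted() - 2), rounding=ROUND_HALF_EVEN)
    exp = q.adjusted()
    mantissa = q.scaleb(-exp)
    return f"{mantissa:.2f}E{exp:+03d}"
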