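"""Presentation-layer rounding.

All model arithmetic is done at full float precision; rounding happens only
when numbers are rendered. Reports use round-half-up (the convention of the
published tables this model reproduces), which differs from Python's builtin
banker's rounding.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero-ward up.

    >>> round_half_up(22.217, 1)
    22.2
    >>> round_half_up(0.5)
    1.0
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def render_percent(fraction: float, ndigits: int = 1) -> float:
    """Render a fraction in [0, 1] as a percent with ``ndigits`` decimals."""
    return round_half_up(100.0 * fraction, ndigits)
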