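"""Half-up decimal rounding for reported scores and percentages."""

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Works on the shortest decimal representation of the float and absorbs
    accumulated binary noise with six guard digits first, so a mean that
    lands at 0.544999...9 still rounds to 0.55 like the exact 0.545 would.
    """
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
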