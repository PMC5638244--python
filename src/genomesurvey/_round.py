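"""Half-up decimal rounding of ratios (as printed tables round them)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(numerator, denominator, decimals: int) -> float:
    """``numerator / denominator`` half-up rounded to ``decimals`` places.

    The division runs in :class:`~decimal.Decimal` arithmetic so that
    values exactly on a .5 boundary round up, not to even.
    """
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
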