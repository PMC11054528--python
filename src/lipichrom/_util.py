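"""Small shared numerics helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in :func:`round` uses banker's rounding (ties to even),
    which disagrees with the 2-decimal convention of published index tables
    on exact half values (e.g. 0.125 -> 0.12 instead of 0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
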