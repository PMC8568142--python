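"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, digits: int = 2) -> float:
    """Round with ties away from zero at the given decimal place.

    Published tables round half-up (1.265 -> 1.27), whereas Python's builtin
    ``round`` is banker's; table-comparison modes use this helper.
    """
    quantum = Decimal(1).scaleb(-digits)
    return float(
        Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    )
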