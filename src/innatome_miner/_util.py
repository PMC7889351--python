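"""Shared helpers: half-up rounding and percent rendering."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; composition tables in
    this package follow the half-up convention instead (2.5 -> 3, 34.955 -> 34.96).
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
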