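"""Decimal-backed rounding helpers.

All user-facing rounding in the package goes through these functions so
that ties are resolved half-up (the convention of the printed tables)
rather than by the banker's rounding of the builtin ``round``.  Values
are routed through ``repr`` to obtain the shortest round-tripping
decimal literal, which avoids binary-float artefacts such as
``Decimal(2.675) == 2.67499...``.
"""

from __future__ import annotations

import math
from decimal import ROUND_CEILING, ROUND_FLOOR, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_to_int", "INT_ROUNDING_MODES"]

INT_ROUNDING_MODES = ("floor", "half_up", "ceiling")


def _as_decimal(value: float) -> Decimal:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value!r}")
    return Decimal(repr(value))


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places with ties going away from zero."""
    quantum = Decimal(1).scaleb(-int(decimals))
    return float(_as_decimal(value).quantize(quantum, rounding=ROUND_HALF_UP))


def round_to_int(value: float, mode: str) -> int:
    """Round to an integer under one of ``floor``, ``half_up``, ``ceiling``."""
    dec = _as_decimal(value)
    if mode == "floor":
        return int(dec.to_integral_value(rounding=ROUND_FLOOR))
    if mode == "half_up":
        return int(dec.to_integral_value(rounding=ROUND_HALF_UP))
    if mode == "ceiling":
        return int(dec.to_integral_value(rounding=ROUND_CEILING))
    raise ValueError(f"unknown rounding mode {mode!r}; expected one of {INT_ROUNDING_MODES}")
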