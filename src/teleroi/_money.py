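"""Exact-decimal money arithmetic.

All engine arithmetic runs on :class:`decimal.Decimal` so that cent-level
wage-table figures are carried exactly; rounding happens only at the defined
reporting points (cents for per-clinic line items, whole dollars for annual
cells), always half-up, matching how health-service finance tables are
printed.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Union

CENT = Decimal("0.01")
DOLLAR = Decimal("1")

Numeric = Union[int, float, str, Decimal]


def to_decimal(value: Numeric) -> Decimal:
    """Convert a number to ``Decimal`` without binary-float artefacts.

    Floats are converted through ``repr`` so that a YAML ``50.61`` becomes
    exactly ``Decimal("50.61")``.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):  # includes numpy float subclasses
        return Decimal(repr(float(value)))
    return Decimal(value)


def round_cents(value: Numeric) -> Decimal:
    """Round to 2 decimals, half-up (per-clinic line items)."""
    return to_decimal(value).quantize(CENT, rounding=ROUND_HALF_UP)


def round_dollars(value: Numeric) -> int:
    """Round to whole dollars, half-up (annual report cells)."""
    return int(to_decimal(value).quantize(DOLLAR, rounding=ROUND_HALF_UP))
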