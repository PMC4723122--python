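"""Concentration unit handling.

Canonical internal units are mg/L for concentrations, L for volumes, mL/min
for clearances, mg for mass and minutes for time.  All conversion happens at
the I/O boundary; everything downstream assumes canonical units.
"""

from __future__ import annotations

from .errors import SchemaError

#: Controlled vocabulary of concentration units accepted in sample sheets.
CONCENTRATION_UNITS = {
    "mg/L": 1.0,
    "mg/dL": 10.0,
    "g/L": 1000.0,
    "g/dL": 10000.0,
}


def to_mg_per_l(value: float, unit: str) -> float:
    """Convert a concentration to canonical mg/L.

    Raises :class:`SchemaError` for units outside the controlled vocabulary.
    """
    try:
        factor = CONCENTRATION_UNITS[unit]
    except KeyError:
        raise SchemaError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(CONCENTRATION_UNITS)}"
        ) from None
    return value * factor


def from_mg_per_l(value: float, unit: str) -> float:
    """Convert a canonical mg/L concentration into ``unit``."""
    try:
        factor = CONCENTRATION_UNITS[unit]
    except KeyError:
        raise SchemaError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(CONCENTRATION_UNITS)}"
        ) from None
    return value / factor
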