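"""Length-unit handling.

All internal comparisons are carried out in millimetres; centimetre
inputs are converted on the way in (1 cm = 10 mm) and only converted
back for display.
"""

from __future__ import annotations

#: Conversion factors into the canonical unit (mm).
_TO_MM = {"mm": 1.0, "cm": 10.0}

#: Comparison tolerance at specification boundaries, in mm.  Unit
#: conversion must never flip an exact boundary case such as "1 cm"
#: against an upper bound of 10 mm.
BOUNDARY_TOL_MM = 1e-9


def to_mm(value: float, unit: str) -> float:
    """Convert *value* in *unit* (``cm`` or ``mm``) to millimetres."""
    try:
        factor = _TO_MM[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; expected 'cm' or 'mm'") from None
    return value * factor


def from_mm(value_mm: float, unit: str) -> float:
    """Convert millimetres back into *unit*."""
    try:
        factor = _TO_MM[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; expected 'cm' or 'mm'") from None
    return value_mm / factor


def leq(a: float, b: float) -> bool:
    """a <= b up to the boundary tolerance."""
    return a <= b + BOUNDARY_TOL_MM


def geq(a: float, b: float) -> bool:
    """a >= b up to the boundary tolerance."""
    return a >= b - BOUNDARY_TOL_MM
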