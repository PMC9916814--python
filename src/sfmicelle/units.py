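"""Conversion of dimensionless lattice quantities to physical units."""

from __future__ import annotations

from typing import Optional

from .segments import UnitConversions

__all__ = ["convert_units"]

_KINDS = ("length", "concentration", "potential")


def convert_units(value: float, kind: str,
                  conversions: Optional[UnitConversions] = None) -> float:
    """Convert a dimensionless lattice quantity to physical units.

    ``length``: lattice units -> nanometers (factor ``b``),
    ``concentration``: volume fraction -> molarity (factor ``k``),
    ``potential``: kT/e units -> volts (factor ``kT/e``).

    >>> convert_units(0.01, "concentration")
    0.1
    """
    conv = conversions if conversions is not None else UnitConversions()
    if kind == "length":
        return value * conv.b * 1e9
    if kind == "concentration":
        return value * conv.k
    if kind == "potential":
        return value * conv.kT_over_e
    raise ValueError(f"unknown conversion kind {kind!r}; expected one of {_KINDS}")
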