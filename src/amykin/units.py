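"""Unit-bearing scalar parsing.

All quantities are carried internally in base SI-molar units: concentrations
in M, times in s, frequencies in Hz, shifts in ppm, temperatures in K and
energies in kcal/mol.  Config files and CLI inputs may state values with SI
prefixes ("70 mM", "50 uM", "750 us", "60.8 MHz"); this module converts them.
"""

from __future__ import annotations

import re

# unit -> (dimension, factor to base unit)
_UNITS: dict[str, tuple[str, float]] = {
    "M": ("concentration", 1.0),
    "mM": ("concentration", 1e-3),
    "uM": ("concentration", 1e-6),
    "µM": ("concentration", 1e-6),
    "μM": ("concentration", 1e-6),
    "nM": ("concentration", 1e-9),
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    "us": ("time", 1e-6),
    "µs": ("time", 1e-6),
    "μs": ("time", 1e-6),
    "ns": ("time", 1e-9),
    "h": ("time", 3600.0),
    "min": ("time", 60.0),
    "Hz": ("frequency", 1.0),
    "kHz": ("frequency", 1e3),
    "MHz": ("frequency", 1e6),
    "ppm": ("shift", 1.0),
    "K": ("temperature", 1.0),
    "kcal/mol": ("energy", 1.0),
    "1/s": ("rate", 1.0),
    "s^-1": ("rate", 1.0),
    "1/M/s": ("bimolecular_rate", 1.0),
    "M^-1s^-1": ("bimolecular_rate", 1.0),
}

_NUMBER = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?")


class UnitError(ValueError):
    """Raised for malformed quantities or unknown units."""


def parse_quantity(text: str | float | int, expect: str | None = None) -> float:
    """Parse ``"70 mM"`` -> 0.07.  Bare numbers pass through unchanged.

    Parameters
    ----------
    text : str or number
        A value with an optional unit suffix.
    expect : str, optional
        Dimension name ("concentration", "time", "frequency", ...); if given,
        a unit of a different dimension raises :class:`UnitError`.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    m = _NUMBER.match(s)
    if not m:
        raise UnitError(f"cannot parse quantity {text!r}")
    value = float(m.group(0))
    unit = s[m.end():].strip()
    if not unit:
        return value
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r} in {text!r}")
    dim, factor = _UNITS[unit]
    if expect is not None and dim != expect:
        raise UnitError(f"expected a {expect}, got {unit!r} in {text!r}")
    return value * factor


def format_molar(value: float) -> str:
    """Render a molar concentration with a readable SI prefix."""
    if value == 0:
        return "0 M"
    for unit, fac in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9)):
        if abs(value) >= fac:
            return f"{value / fac:g} {unit}"
    return f"{value:g} M"
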