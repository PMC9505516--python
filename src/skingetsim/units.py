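"""Unit helpers.

Everything inside the package is SI: lengths in metres, fields in V/m,
conductivities in S/m.  Published skin-layer tables and device envelopes mix
µm/mm/cm and V/cm, so the converters below are used at the configuration
boundary and nowhere else.
"""

from __future__ import annotations

#: multiply a value in V/cm by this to obtain V/m
V_PER_CM = 100.0

#: multiply a value in mm by this to obtain m
MM = 1e-3

#: multiply a value in µm by this to obtain m
UM = 1e-6

#: multiply a value in cm by this to obtain m
CM = 1e-2

_LENGTH = {"m": 1.0, "cm": CM, "mm": MM, "um": UM, "µm": UM}
_FIELD = {"V/m": 1.0, "V/cm": V_PER_CM}


def length_to_m(value: float, unit: str) -> float:
    """Convert a length in the given unit ('m', 'cm', 'mm', 'um') to metres."""
    try:
        return value * _LENGTH[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}") from None


def field_to_v_per_m(value: float, unit: str) -> float:
    """Convert a field magnitude in 'V/m' or 'V/cm' to V/m."""
    try:
        return value * _FIELD[unit]
    except KeyError:
        raise ValueError(f"unknown field unit {unit!r}") from None
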