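"""Pressure-unit handling.

All internal computation in pvshell is done in kPa; mmHg appears only at
the I/O boundary (clinical convention and the usual axis unit of published
PV plots).
"""

from __future__ import annotations

from .errors import DomainError

#: 1 kPa in mmHg (conventional conversion factor).
MMHG_PER_KPA = 7.500617

PRESSURE_UNITS = ("kPa", "mmHg")


def convert_pressure(value, from_unit: str, to_unit: str):
    """Convert a pressure (scalar or array) between kPa and mmHg.

    The conversion uses 1 kPa = 7.500617 mmHg and is an exact round trip
    to floating-point precision.
    """
    for u in (from_unit, to_unit):
        if u not in PRESSURE_UNITS:
            raise DomainError(f"unknown pressure unit {u!r}; expected one of {PRESSURE_UNITS}")
    if from_unit == to_unit:
        return value
    if from_unit == "kPa":  # -> mmHg
        return value * MMHG_PER_KPA
    return value / MMHG_PER_KPA


def kpa_to_mmhg(value):
    return value * MMHG_PER_KPA


def mmhg_to_kpa(value):
    return value / MMHG_PER_KPA
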