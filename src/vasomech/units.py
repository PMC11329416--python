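"""Pressure unit handling. Internal unit is kPa; mmHg accepted at I/O."""

from __future__ import annotations

import numpy as np

MMHG_TO_KPA = 0.133322

_CONVERSIONS = {"kpa": 1.0, "mmhg": MMHG_TO_KPA}


def _factor(unit: str) -> float:
    try:
        return _CONVERSIONS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown pressure unit {unit!r}; use 'kPa' or 'mmHg'") from None


def to_kpa(value, unit: str):
    """Convert a pressure (scalar or array) from `unit` to kPa."""
    out = np.asarray(value, dtype=float) * _factor(unit)
    return out if out.ndim else float(out)


def from_kpa(value, unit: str):
    """Convert a pressure in kPa to `unit`."""
    out = np.asarray(value, dtype=float) / _factor(unit)
    return out if out.ndim else float(out)
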