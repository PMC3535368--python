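"""Concentration and time unit helpers.

Internal canonical units are molar and seconds throughout the package;
user-facing times are minutes and user-facing concentrations carry explicit
"uM"/"mM"/"M" suffixes.  Conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import re

from .errors import ConfigurationError

SECONDS_PER_MINUTE = 60.0

_CONC_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
}

_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]+)\s*$")


def parse_conc(text: str | float) -> float:
    """Parse a concentration like ``"500uM"`` or ``"2 mM"`` into molar.

    Bare numbers (str or float) are taken as molar.  The numeric part is
    parsed with :func:`float`, so the suffixed form round-trips bit-exactly
    for any value representable in the given unit.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _CONC_RE.match(text)
    if m is None:
        try:
            return float(text)
        except ValueError:
            raise ConfigurationError(f"cannot parse concentration: {text!r}") from None
    value, unit = m.groups()
    if unit not in _CONC_UNITS:
        raise ConfigurationError(
            f"unknown concentration unit {unit!r} in {text!r} "
            f"(expected one of {sorted(_CONC_UNITS)})"
        )
    return float(value) * _CONC_UNITS[unit]


def minutes_to_seconds(t_min: float) -> float:
    return t_min * SECONDS_PER_MINUTE


def seconds_to_minutes(t_s: float) -> float:
    return t_s / SECONDS_PER_MINUTE
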