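"""Minimal unit handling for configuration input.

All internal quantities are SI: molar (M) for concentrations, seconds (s)
for times, s^-1 for first-order rates and M^-1 s^-1 for second-order rates.
Configuration files may tag values with a unit string (e.g. ``"nM"`` or
``"1/(nM*s)"``); this module converts them to SI on load.
"""

from __future__ import annotations

from .exceptions import ConfigError

#: multiplicative factor to molar
_CONCENTRATION = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "μM": 1e-6,  # μM (Greek mu)
    "nM": 1e-9,
    "pM": 1e-12,
}

_TIME = {"s": 1.0, "min": 60.0, "h": 3600.0}

_FIRST_ORDER = {"1/s", "s^-1", "s-1", "/s"}

# Dimension names used by callers to declare what a field should be.
CONCENTRATION = "concentration"
TIME = "time"
FIRST_ORDER_RATE = "first_order_rate"
SECOND_ORDER_RATE = "second_order_rate"
DIMENSIONLESS = "dimensionless"


def parse_unit(unit: str) -> tuple[float, str]:
    """Return ``(factor_to_si, dimension)`` for a unit string.

    Raises :class:`ConfigError` for unrecognised units.
    """
    u = unit.strip()
    if u in ("", "1", "-"):
        return 1.0, DIMENSIONLESS
    if u in _CONCENTRATION:
        return _CONCENTRATION[u], CONCENTRATION
    if u in _TIME:
        return _TIME[u], TIME
    if u in _FIRST_ORDER:
        return 1.0, FIRST_ORDER_RATE
    # second-order rates: "1/(M*s)", "1/(nM*s)", "M^-1 s^-1", ...
    compact = u.replace(" ", "")
    if compact.startswith("1/(") and compact.endswith("*s)"):
        conc = compact[3:-3]
        if conc in _CONCENTRATION:
            return 1.0 / _CONCENTRATION[conc], SECOND_ORDER_RATE
    for conc, factor in _CONCENTRATION.items():
        if compact in (f"{conc}^-1s^-1", f"{conc}-1s-1"):
            return 1.0 / factor, SECOND_ORDER_RATE
    raise ConfigError(f"unrecognised unit string: {unit!r}")


def to_si(value: float, unit: str, expected_dimension: str | None = None,
          field: str = "") -> float:
    """Convert a tagged value to SI, optionally checking its dimension."""
    factor, dimension = parse_unit(unit)
    if expected_dimension is not None and dimension != expected_dimension:
        where = f" for field {field!r}" if field else ""
        raise ConfigError(
            f"unit {unit!r}{where} has dimension {dimension}, "
            f"expected {expected_dimension}"
        )
    return float(value) * factor
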