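"""Reaction network for bivalent KH-domain binding to a bipartite RNA.

A di-domain protein (KH3-KH4) recognises a 28-nt RNA element carrying one
cognate site for each domain.  Either domain can bind first, giving one of
two open 1:1 complexes.  The singly-bound protein can then capture the
second site on the *same* RNA — a first-order "ring closure" that loops the
RNA around the di-domain — or a second protein can bind the free site,
giving a 2:1 protein:RNA complex.  The network has six species::

    R + P  <->  C3          (kon3 / koff3)   KH3 engaged
    R + P  <->  C4          (kon4 / koff4)   KH4 engaged
    C3     <->  CC          (kC4  / koff4)   KH4 closes the ring
    C4     <->  CC          (kC3  / koff3)   KH3 closes the ring
    C3 + P <->  D           (kon4 / koff4)   second protein's KH4 binds
    C4 + P <->  D           (kon3 / koff3)   second protein's KH3 binds

Each protein in the 2:1 complex D engages exactly one site, so single-domain
rate constants govern its formation and loss.  A 1:2 protein:RNA species
(one protein bridging two RNAs) is not modelled: at sub-nanomolar RNA and
micromolar-scale single-site Kds it is never populated.

Closing rates are not directly measurable; :func:`derive_closing_rates`
reconstructs them from the overall di-domain dissociation constant and the
single-domain kinetics via the thermodynamic cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

from . import units
from .exceptions import ConfigError, InvalidStateError, ParameterError

__all__ = [
    "KineticParameters",
    "MixtureConditions",
    "SpeciesState",
    "SpeciesRates",
    "mass_action_rhs",
    "derive_closing_rates",
    "cycle_consistency_ratio",
    "effective_dissociation_rate",
    "ZIPCODE_KH34_PARAMETERS",
    "ZIPCODE_CONDITIONS",
]

#: relative tolerance below which a parameter set is considered to satisfy
#: detailed balance around the binding/closing cycle
CYCLE_RTOL = 1e-3

_FIELD_DIMENSIONS = {
    "kon3": units.SECOND_ORDER_RATE,
    "koff3": units.FIRST_ORDER_RATE,
    "kon4": units.SECOND_ORDER_RATE,
    "koff4": units.FIRST_ORDER_RATE,
    "kC3": units.FIRST_ORDER_RATE,
    "kC4": units.FIRST_ORDER_RATE,
}

_SI_UNIT = {
    units.SECOND_ORDER_RATE: "1/(M*s)",
    units.FIRST_ORDER_RATE: "1/s",
    units.CONCENTRATION: "M",
}


@dataclass(frozen=True)
class KineticParameters:
    """The six rate constants of the binding/closing network.

    Parameters
    ----------
    kon3, kon4 : float
        Association rate constants of KH3 and KH4 for their cognate RNA
        sites (M^-1 s^-1).
    koff3, koff4 : float
        Dissociation rate constants of the engaged KH3 / KH4 domain (s^-1).
        These apply wherever that single contact is broken: open 1:1
        complexes, closed-complex opening, and protein loss from the 2:1
        complex.
    kC3, kC4 : float
        Ring-closure rates (s^-1); ``kC3`` applies when KH3 is the second
        domain to bind, ``kC4`` when KH4 is.
    """

    kon3: float
    koff3: float
    kon4: float
    koff4: float
    kC3: float
    kC4: float

    def __post_init__(self):
        for name in _FIELD_DIMENSIONS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(
                    f"{name} must be finite and non-negative, got {v!r}"
                )

    @property
    def Kd3(self) -> float:
        """Single-site dissociation constant of KH3, koff3/kon3 (M)."""
        if self.kon3 <= 0:
            raise ParameterError("Kd3 undefined: kon3 must be positive")
        return self.koff3 / self.kon3

    @property
    def Kd4(self) -> float:
        """Single-site dissociation constant of KH4, koff4/kon4 (M)."""
        if self.kon4 <= 0:
            raise ParameterError("Kd4 undefined: kon4 must be positive")
        return self.koff4 / self.kon4

    def is_thermodynamically_consistent(self, rtol: float = CYCLE_RTOL) -> bool:
        """Whether the binding/closing cycle supports a true equilibrium."""
        return abs(cycle_consistency_ratio(self) - 1.0) <= rtol

    def swapped(self) -> "KineticParameters":
        """Exchange the KH3 and KH4 domain labels."""
        return KineticParameters(
            kon3=self.kon4, koff3=self.koff4,
            kon4=self.kon3, koff4=self.koff3,
            kC3=self.kC4, kC4=self.kC3,
        )

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        """Flat mapping with explicit SI unit strings."""
        return {
            name: {"value": getattr(self, name), "unit": _SI_UNIT[dim]}
            for name, dim in _FIELD_DIMENSIONS.items()
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "KineticParameters":
        """Build from a mapping of ``{"value": x, "unit": "..."}`` entries.

        Bare numbers are accepted and taken to be SI.  Unknown keys raise
        :class:`ConfigError`.
        """
        unknown = set(mapping) - set(_FIELD_DIMENSIONS)
        if unknown:
            raise ConfigError(f"unknown rate constant(s): {sorted(unknown)}")
        kwargs = {}
        for name, entry in mapping.items():
            if isinstance(entry, dict):
                try:
                    value, unit = entry["value"], entry["unit"]
                except KeyError as exc:
                    raise ConfigError(
                        f"{name}: expected 'value' and 'unit' keys"
                    ) from exc
                kwargs[name] = units.to_si(
                    value, unit, _FIELD_DIMENSIONS[name], field=name
                )
            else:
                kwargs[name] = float(entry)
        return cls(**kwargs)


@dataclass(frozen=True)
class MixtureConditions:
    """Total protein and RNA concentrations of the mixture (M)."""

    P_tot: float
    R_tot: float

    def __post_init__(self):
        for name in ("P_tot", "R_tot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(
                    f"{name} must be finite and non-negative, got {v!r}"
                )

    def replace(self, **changes) -> "MixtureConditions":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "P_tot": {"value": self.P_tot, "unit": "M"},
            "R_tot": {"value": self.R_tot, "unit": "M"},
        }

    @classmethod
    def from_dict(cls, mapping: dict) -> "MixtureConditions":
        unknown = set(mapping) - {"P_tot", "R_tot"}
        if unknown:
            raise ConfigError(f"unknown condition key(s): {sorted(unknown)}")
        kwargs = {}
        for name, entry in mapping.items():
            if isinstance(entry, dict):
                try:
                    value, unit = entry["value"], entry["unit"]
                except KeyError as exc:
                    raise ConfigError(
                        f"{name}: expected 'value' and 'unit' keys"
                    ) from exc
                kwargs[name] = units.to_si(
                    value, unit, units.CONCENTRATION, field=name
                )
            else:
                kwargs[name] = float(entry)
        return cls(**kwargs)


# order of species in array form; shared with the integrator core
SPECIES = ("R", "P", "C3", "C4", "CC", "D")

#: round-off allowance when validating non-negativity of concentrations (M)
NEGATIVE_TOL = 1e-15


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (M) of the six species at one instant.

    ``R`` free RNA, ``P`` free protein, ``C3``/``C4`` open 1:1 complexes
    with KH3 / KH4 engaged, ``CC`` the closed (RNA-looped) 1:1 complex and
    ``D`` the 2:1 protein:RNA complex.
    """

    R: float
    P: float
    C3: float
    C4: float
    CC: float
    D: float

    def __post_init__(self):
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidStateError(f"{name} is not finite: {v!r}")
            if v < -NEGATIVE_TOL:
                raise InvalidStateError(f"{name} is negative: {v!r}")

    @property
    def bound_rna(self) -> float:
        """Total RNA in any protein-containing species (M)."""
        return self.C3 + self.C4 + self.CC + self.D

    @property
    def total_rna(self) -> float:
        return self.R + self.bound_rna

    @property
    def total_protein(self) -> float:
        return self.P + self.C3 + self.C4 + self.CC + 2.0 * self.D

    def as_array(self):
        import numpy as np

        return np.array([self.R, self.P, self.C3, self.C4, self.CC, self.D])

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(*(float(v) for v in y))

    @classmethod
    def all_free(cls, conditions: MixtureConditions) -> "SpeciesState":
        return cls(R=conditions.R_tot, P=conditions.P_tot,
                   C3=0.0, C4=0.0, CC=0.0, D=0.0)

    def check_conservation(self, conditions: MixtureConditions,
                           rtol: float = 1e-9) -> None:
        """Raise :class:`InvalidStateError` if mass balance is violated."""
        r_scale = max(conditions.R_tot, NEGATIVE_TOL)
        p_scale = max(conditions.P_tot, NEGATIVE_TOL)
        if abs(self.total_rna - conditions.R_tot) > rtol * r_scale:
            raise InvalidStateError(
                f"RNA not conserved: {self.total_rna!r} vs {conditions.R_tot!r}"
            )
        if abs(self.total_protein - conditions.P_tot) > rtol * p_scale:
            raise InvalidStateError(
                f"protein not conserved: {self.total_protein!r} "
                f"vs {conditions.P_tot!r}"
            )


class SpeciesRates(NamedTuple):
    """Per-species time derivatives (M s^-1), same field order as the state."""

    dR: float
    dP: float
    dC3: float
    dC4: float
    dCC: float
    dD: float


def mass_action_rhs(state: SpeciesState,
                    params: KineticParameters) -> SpeciesRates:
    """Mass-action time derivatives of all six species.

    RNA and protein mass are conserved by construction:
    ``dR+dC3+dC4+dCC+dD = 0`` and ``dP+dC3+dC4+dCC+2*dD = 0`` hold to
    machine precision for any state.
    """
    R, P = state.R, state.P
    C3, C4, CC, D = state.C3, state.C4, state.CC, state.D
    p = params

    a3 = p.kon3 * R * P          # R + P -> C3
    a4 = p.kon4 * R * P          # R + P -> C4
    b3 = p.kon4 * C3 * P         # C3 + P -> D
    b4 = p.kon3 * C4 * P         # C4 + P -> D
    open_cc = (p.koff3 + p.koff4) * CC
    open_d = (p.koff3 + p.koff4) * D

    # pairwise grouping keeps a KH3<->KH4 label swap bitwise-exact and
    # mirrors the compiled rate law in loopbind._core
    release = p.koff3 * C3 + p.koff4 * C4
    dR = release - (a3 + a4)
    dC3 = a3 - (p.koff3 + p.kC4) * C3 + p.koff4 * CC - b3 + p.koff4 * D
    dC4 = a4 - (p.koff4 + p.kC3) * C4 + p.koff3 * CC - b4 + p.koff3 * D
    dCC = (p.kC4 * C3 + p.kC3 * C4) - open_cc
    dD = (b3 + b4) - open_d
    dP = release - (a3 + a4) - (b3 + b4) + open_d
    return SpeciesRates(dR, dP, dC3, dC4, dCC, dD)


def derive_closing_rates(kon3: float, koff3: float, kon4: float, koff4: float,
                         Kd_overall: float) -> tuple[float, float]:
    """Reconstruct the ring-closure rates from measurable quantities.

    The closure steps are intramolecular and cannot be observed directly.
    At equilibrium, however, the overall di-domain dissociation constant
    ties them to the single-domain kinetics.  Taking the closed complex to
    dominate the bound population,

        Kd_overall ~= R*P/CC = Kd3 * koff4/kC4 = Kd4 * koff3/kC3,

    which inverts to::

        kC3 = Kd4 * koff3 / Kd_overall,   kC4 = Kd3 * koff4 / Kd_overall.

    The returned pair always satisfies ``kC4/kC3 = kon4/kon3`` and therefore
    closes the thermodynamic cycle exactly
    (:func:`cycle_consistency_ratio` = 1).

    Parameters are the single-domain rate constants (SI) and the measured
    di-domain dissociation constant (M).  Returns ``(kC3, kC4)`` in s^-1.
    """
    for name, v in (("kon3", kon3), ("koff3", koff3), ("kon4", kon4),
                    ("koff4", koff4), ("Kd_overall", Kd_overall)):
        if not (math.isfinite(v) and v > 0):
            raise ParameterError(f"{name} must be finite and positive, got {v!r}")
    Kd3 = koff3 / kon3
    Kd4 = koff4 / kon4
    kC3 = Kd4 * koff3 / Kd_overall
    kC4 = Kd3 * koff4 / Kd_overall
    return kC3, kC4


def cycle_consistency_ratio(params: KineticParameters) -> float:
    """Detailed-balance ratio of the R+P -> C3 -> CC -> C4 -> R+P cycle.

    Returns ``(kon3*kC4)/(kon4*kC3)``, the product of forward over reverse
    rate constants around the cycle (the koff factors cancel).  A value of
    one means the network supports a true equilibrium with no circulating
    flux; anything else implies the closed complex is held together more
    (or less) tightly through one pathway than the other.
    """
    if params.kon4 <= 0 or params.kC3 <= 0:
        raise ParameterError(
            "cycle ratio undefined: kon4 and kC3 must be positive"
        )
    return (params.kon3 * params.kC4) / (params.kon4 * params.kC3)


def effective_dissociation_rate(params: KineticParameters) -> float:
    """Escape rate of RNA from the closed complex with no rebinding.

    When free protein is removed (a wash step), the closed complex can only
    release the RNA by opening one contact (koff3 or koff4) and then, before
    the ring re-closes, losing the other.  The escape probability of each
    open intermediate is koff/(koff + kC), giving::

        k_eff = koff4 * koff3/(koff3 + kC4) + koff3 * koff4/(koff4 + kC3)

    (first term: KH4 contact opens at koff4, then KH3 releases before KH4
    re-closes).  The approximation treats the open complexes as short-lived,
    so it is accurate when closure is much faster than dissociation
    (kC >> koff) — the avidity regime.
    """
    p = params
    d1 = p.koff3 + p.kC4
    d2 = p.koff4 + p.kC3
    if d1 <= 0 or d2 <= 0:
        raise ParameterError(
            "effective rate undefined: koff3+kC4 and koff4+kC3 must be positive"
        )
    return p.koff4 * p.koff3 / d1 + p.koff3 * p.koff4 / d2


#: Rate constants for chicken ZBP1 (IMP1) KH3-KH4 binding the beta-actin
#: Zipcode RNA at 25 C, as measured by BLI for the single domains and with
#: closing rates derived from the 20 nM di-domain Kd via the thermodynamic
#: cycle (kC4 = 9.333 = 2 * kon4/kon3 keeps the cycle exactly consistent
#: after rounding kC3 to 2).
ZIPCODE_KH34_PARAMETERS = KineticParameters(
    kon3=3.0e4, koff3=0.046,
    kon4=1.4e5, koff4=0.13,
    kC3=2.0, kC4=9.333,
)

#: Cell-like reference concentrations: ~0.2 uM ZBP1 (fibroblast range
#: 0.05-0.5 uM) and ~0.4 nM beta-actin mRNA (~500 copies per neuron).
ZIPCODE_CONDITIONS = MixtureConditions(P_tot=0.2e-6, R_tot=0.4e-9)
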