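"""Steady-state analysis: direct solvers, apparent Kd, and sweeps.

Two independent routes to the equilibrium state are provided.

:func:`steady_state_solve` treats the stationarity conditions of the four
complexes together with RNA conservation as a linear system at fixed free
protein, then iterates the free-protein update from protein conservation to
a fixed point.  It works for any parameter set, including ones that violate
detailed balance (where the "steady state" carries a circulating flux).

:func:`detailed_balance_state` builds the state purely from equilibrium
constants and is only valid when the binding/closing cycle is
thermodynamically consistent.  It serves as a closed-form cross-check on
the linear solver and on the ODE integrator.

The apparent dissociation constant of the overall interaction is defined
as free protein times free RNA over all protein-bound RNA,
``Kd_app = P*R/(C3+C4+CC+D)``; for a single 1:1 reaction this reduces to
the ordinary koff/kon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, ParameterError
from .model import (
    CYCLE_RTOL,
    KineticParameters,
    MixtureConditions,
    SpeciesState,
    cycle_consistency_ratio,
    effective_dissociation_rate,
)

__all__ = [
    "EquilibriumSummary",
    "steady_state_solve",
    "detailed_balance_state",
    "apparent_kd",
    "fraction_bound",
    "summarize",
    "protein_sweep",
    "closing_rate_sweep",
]


@dataclass(frozen=True)
class EquilibriumSummary:
    """Steady-state snapshot: species, fraction of RNA bound, apparent Kd.

    ``fraction_bound`` is (C3+C4+CC+D)/R_tot in [0, 1]; ``Kd_app`` is
    infinite when no RNA is bound.  ``time_to_equilibrium`` is only set by
    the kinetic route (:func:`loopbind.simulate.run_to_equilibrium`).
    """

    state: SpeciesState
    fraction_bound: float
    Kd_app: float
    time_to_equilibrium: float | None = None

    def to_dict(self) -> dict:
        out = {f"{name}_M": getattr(self.state, name)
               for name in ("R", "P", "C3", "C4", "CC", "D")}
        out["fraction_bound"] = self.fraction_bound
        out["Kd_app_M"] = self.Kd_app
        if self.time_to_equilibrium is not None:
            out["time_to_equilibrium_s"] = self.time_to_equilibrium
        return out


def apparent_kd(state: SpeciesState) -> float:
    """``P_free * R_free / (C3 + C4 + CC + D)`` (M)."""
    bound = state.bound_rna
    if bound <= 0:
        raise ParameterError("apparent Kd undefined: no RNA is bound")
    return state.P * state.R / bound


def fraction_bound(state: SpeciesState, R_tot: float) -> float:
    return state.bound_rna / R_tot if R_tot > 0 else 0.0


def summarize(state: SpeciesState, conditions: MixtureConditions,
              time_to_equilibrium: float | None = None) -> EquilibriumSummary:
    frac = fraction_bound(state, conditions.R_tot)
    kd = apparent_kd(state) if state.bound_rna > 0 else math.inf
    return EquilibriumSummary(state=state, fraction_bound=frac, Kd_app=kd,
                              time_to_equilibrium=time_to_equilibrium)


def _complexes_at_fixed_protein(params: KineticParameters, P: float,
                                R_tot: float) -> np.ndarray:
    """Solve stationarity of (C3, C4, CC, D) + RNA conservation at fixed P.

    Linear system in (R, C3, C4, CC, D).
    """
    p = params
    koff_sum = p.koff3 + p.koff4
    A = np.array([
        # dC3/dt = 0
        [p.kon3 * P, -(p.koff3 + p.kC4 + p.kon4 * P), 0.0, p.koff4, p.koff4],
        # dC4/dt = 0
        [p.kon4 * P, 0.0, -(p.koff4 + p.kC3 + p.kon3 * P), p.koff3, p.koff3],
        # dCC/dt = 0
        [0.0, p.kC4, p.kC3, -koff_sum, 0.0],
        # dD/dt = 0
        [0.0, p.kon4 * P, p.kon3 * P, 0.0, -koff_sum],
        # RNA conservation
        [1.0, 1.0, 1.0, 1.0, 1.0],
    ])
    b = np.array([0.0, 0.0, 0.0, 0.0, R_tot])
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            f"singular steady-state system (rates {params!r}); the network "
            "has no unique stationary composition"
        ) from exc


def steady_state_solve(params: KineticParameters,
                       conditions: MixtureConditions,
                       rtol: float = 1e-12,
                       max_iter: int = 1000) -> SpeciesState:
    """Direct stationary state of the network.

    At fixed free protein the stationarity conditions of the complexes are
    linear in the RNA species; free protein is then refreshed from protein
    conservation and the solve repeated until the fixed point converges to
    ``rtol``.  Protein depletion by the RNA is therefore handled exactly,
    although it is tiny whenever R_tot << P_tot.
    """
    P_tot, R_tot = conditions.P_tot, conditions.R_tot
    if R_tot == 0.0:
        return SpeciesState(R=0.0, P=P_tot, C3=0.0, C4=0.0, CC=0.0, D=0.0)
    P = P_tot
    sol = None
    for _ in range(max_iter):
        sol = _complexes_at_fixed_protein(params, P, R_tot)
        _, C3, C4, CC, D = sol
        P_new = max(0.0, P_tot - (C3 + C4 + CC + 2.0 * D))
        if abs(P_new - P) <= rtol * max(P_tot, 1e-30):
            P = P_new
            break
        P = P_new
    else:
        raise ConvergenceError(
            f"free-protein fixed point did not converge in {max_iter} "
            "iterations",
            last_state=SpeciesState.from_array(
                np.array([sol[0], P, sol[1], sol[2], sol[3], sol[4]])),
        )
    sol = _complexes_at_fixed_protein(params, P, R_tot)
    R, C3, C4, CC, D = (max(0.0, v) for v in sol)
    return SpeciesState(R=R, P=P, C3=C3, C4=C4, CC=CC, D=D)


def detailed_balance_state(params: KineticParameters,
                           conditions: MixtureConditions,
                           rtol: float = 1e-12,
                           max_iter: int = 1000) -> SpeciesState:
    """Equilibrium state from the equilibrium constants alone.

    Species ratios at equilibrium::

        C3/R = P/Kd3        C4/R = P/Kd4
        CC/C3 = kC4/koff4   D/C3 = P/Kd4

    with free protein from conservation (fixed-point iteration, exact in
    the R_tot << P_tot limit after one pass).  Refuses parameter sets whose
    cycle-consistency ratio deviates from 1 by more than 1e-3, since a
    network with circulating flux has no equilibrium of this form.
    """
    ratio = cycle_consistency_ratio(params)
    if abs(ratio - 1.0) > CYCLE_RTOL:
        raise ParameterError(
            f"detailed balance violated: cycle consistency ratio {ratio:.6g} "
            "differs from 1 by more than 1e-3; use steady_state_solve"
        )
    P_tot, R_tot = conditions.P_tot, conditions.R_tot
    if R_tot == 0.0:
        return SpeciesState(R=0.0, P=P_tot, C3=0.0, C4=0.0, CC=0.0, D=0.0)
    Kd3, Kd4 = params.Kd3, params.Kd4
    closure = params.kC4 / params.koff4 if params.koff4 > 0 else 0.0

    P = P_tot
    for _ in range(max_iter):
        r3 = P / Kd3
        r4 = P / Kd4
        rcc = r3 * closure
        rd = r3 * r4
        R = R_tot / (1.0 + r3 + r4 + rcc + rd)
        C3, C4, CC, D = r3 * R, r4 * R, rcc * R, rd * R
        P_new = max(0.0, P_tot - (C3 + C4 + CC + 2.0 * D))
        if abs(P_new - P) <= rtol * max(P_tot, 1e-30):
            P = P_new
            break
        P = P_new
    else:
        raise ConvergenceError(
            f"free-protein fixed point did not converge in {max_iter} "
            "iterations")
    r3 = P / Kd3
    r4 = P / Kd4
    R = R_tot / (1.0 + r3 + r4 + r3 * closure + r3 * r4)
    return SpeciesState(R=R, P=P, C3=r3 * R, C4=r4 * R,
                        CC=r3 * closure * R, D=r3 * r4 * R)


def _monotone(values) -> bool:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return True
    diffs = np.diff(arr)
    return bool(np.all(diffs > 0) or np.all(diffs < 0))


_SWEEP_SPECIES_COLUMNS = ["R_M", "P_M", "C3_M", "C4_M", "CC_M", "D_M"]


def _sweep_row(params: KineticParameters,
               conditions: MixtureConditions) -> dict:
    state = steady_state_solve(params, conditions)
    kd = apparent_kd(state) if state.bound_rna > 0 else math.inf
    row = {
        "Kd_app_M": kd,
        "fraction_bound": fraction_bound(state, conditions.R_tot),
        "k_off_eff_s": effective_dissociation_rate(params),
    }
    for name, col in zip(("R", "P", "C3", "C4", "CC", "D"),
                         _SWEEP_SPECIES_COLUMNS):
        row[col] = getattr(state, name)
    return row


def protein_sweep(params: KineticParameters, P_values, R_tot: float) -> pd.DataFrame:
    """Equilibrium summaries over a series of total protein concentrations.

    ``P_values`` (M) must be strictly monotone.  Returns one row per value
    with apparent Kd, fraction bound, the full species breakdown and the
    analytic effective off-rate.
    """
    P_values = list(P_values)
    if not P_values:
        raise ParameterError("P_values must be non-empty")
    if any(v < 0 for v in P_values):
        raise ParameterError("P_values must be non-negative")
    if not _monotone(P_values):
        raise ParameterError("P_values must be strictly monotone")
    rows = []
    for P in P_values:
        try:
            row = _sweep_row(params, MixtureConditions(P_tot=P, R_tot=R_tot))
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"steady state failed at P_tot = {P} M: {exc}") from exc
        row = {"P_tot_M": P, **row}
        rows.append(row)
    return pd.DataFrame(rows)


def closing_rate_sweep(params: KineticParameters, kC3_values,
                       conditions: MixtureConditions | None = None,
                       preserve_ratio: bool = True) -> pd.DataFrame:
    """Equilibrium summaries over a series of KH3 closing rates.

    With ``preserve_ratio`` (the default) kC4 is co-scaled so kC4/kC3 keeps
    its baseline value, which preserves thermodynamic consistency of the
    cycle; with the flag off, kC4 stays at its baseline value and the swept
    sets generally violate detailed balance (the steady state then carries
    a small circulating flux).
    """
    from .model import ZIPCODE_CONDITIONS

    if conditions is None:
        conditions = ZIPCODE_CONDITIONS
    kC3_values = list(kC3_values)
    if not kC3_values:
        raise ParameterError("kC3_values must be non-empty")
    if any(v <= 0 for v in kC3_values):
        raise ParameterError("kC3_values must be positive")
    if not _monotone(kC3_values):
        raise ParameterError("kC3_values must be strictly monotone")
    if params.kC3 <= 0:
        raise ParameterError("baseline kC3 must be positive for a sweep")
    baseline_ratio = params.kC4 / params.kC3
    rows = []
    for kC3 in kC3_values:
        kC4 = kC3 * baseline_ratio if preserve_ratio else params.kC4
        swept = params.replace(kC3=kC3, kC4=kC4)
        try:
            row = _sweep_row(swept, conditions)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"steady state failed at kC3 = {kC3} /s: {exc}") from exc
        rows.append({"kC3_s": kC3, "kC4_s": kC4, **row})
    return pd.DataFrame(rows)
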