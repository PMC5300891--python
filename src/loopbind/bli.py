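"""Biolayer-interferometry (BLI) kinetic analysis.

Implements the classical 1:1-Langmuir workflow for a sensorgram series
recorded at increasing analyte (protein) concentrations:

1. fit each association phase with a mono-exponential rise to get the
   observed rate kobs;
2. kon is the slope of kobs against analyte concentration (for 1:1
   kinetics kobs = kon*[P] + koff, so the intercept estimates koff);
3. Kd comes from fitting the equilibrium (plateau) responses with the
   binding hyperbola Req = Rmax*[P]/([P] + Kd);
4. koff = Kd * kon, cross-checked against a direct mono-exponential fit of
   the dissociation phases.

The 1:1 model is applied even for the bivalent di-domain analyte: with
ring closure much faster than domain release, the closed complex makes the
association phase effectively single-exponential and the slow
closure-limited off-rate dominates dissociation, so the Langmuir analysis
returns well-defined apparent constants.

Sensorgram traces are stored as plain (time, response) tables; file I/O is
a two-column CSV plus a JSON side-car holding the analyte concentration
and phase boundaries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitError, ParameterError

__all__ = [
    "Sensorgram",
    "ExponentialFit",
    "ResponseFit",
    "BLIFitResult",
    "exponential_fit",
    "kon_from_kobs",
    "kd_from_responses",
    "analyze_bli_dataset",
]


@dataclass(frozen=True)
class Sensorgram:
    """One BLI trace: response vs time at a single analyte concentration.

    ``phase_bounds = (t_assoc_start, t_assoc_end, t_dissoc_end)`` in
    seconds, ordered and inside the recorded time range.
    """

    analyte_concentration: float
    times: np.ndarray
    response: np.ndarray
    phase_bounds: tuple[float, float, float]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        response = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "response", response)
        if times.ndim != 1 or times.shape != response.shape:
            raise ParameterError("times and response must be equal-length 1-D")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ParameterError("times must be strictly increasing")
        t0, t1, t2 = self.phase_bounds
        if not (t0 < t1 <= t2):
            raise ParameterError(
                f"phase bounds must be ordered, got {self.phase_bounds}")
        if t0 < times[0] - 1e-9 or t2 > times[-1] + 1e-9:
            raise ParameterError("phase bounds outside the recorded range")

    def association(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, response) of the association phase, t rebased to zero."""
        t0, t1, _ = self.phase_bounds
        mask = (self.times >= t0) & (self.times <= t1)
        return self.times[mask] - t0, self.response[mask]

    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, response) of the dissociation phase, t rebased to zero."""
        _, t1, t2 = self.phase_bounds
        mask = (self.times >= t1) & (self.times <= t2)
        return self.times[mask] - t1, self.response[mask]

    def plateau_response(self, tail_fraction: float = 0.1) -> float:
        """Mean response over the last ``tail_fraction`` of association."""
        t, r = self.association()
        if len(t) == 0:
            raise ParameterError("empty association phase")
        cutoff = t[-1] * (1.0 - tail_fraction)
        tail = r[t >= cutoff]
        return float(tail.mean())

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "response": self.response}).to_csv(
            path, index=False, float_format="%.17g")
        sidecar = {
            "analyte_concentration_M": self.analyte_concentration,
            "phase_bounds_s": list(self.phase_bounds),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "Sensorgram":
        path = Path(path)
        frame = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            analyte_concentration=meta["analyte_concentration_M"],
            times=frame["time_s"].to_numpy(),
            response=frame["response"].to_numpy(),
            phase_bounds=tuple(meta["phase_bounds_s"]),
        )


@dataclass(frozen=True)
class ExponentialFit:
    rate: float           # s^-1
    amplitude: float      # response units
    offset: float         # response units
    rate_stderr: float    # standard error of the rate from the fit


@dataclass(frozen=True)
class ResponseFit:
    Kd: float             # M
    Rmax: float           # response units
    saturation_reached: bool  # False when max [P] < Kd/2 (Kd poorly bounded)


@dataclass(frozen=True)
class BLIFitResult:
    """Kinetic constants extracted from a sensorgram series."""

    kobs_per_concentration: list[tuple[float, float]]
    kon: float
    kobs_intercept: float
    Kd: float
    Rmax: float
    koff_from_kd_kon: float
    koff_direct: float
    koff_consistent: bool
    saturation_reached: bool = True

    def to_json(self, path) -> None:
        payload = {
            "kobs_per_concentration": [
                {"concentration_M": c, "kobs_s": k}
                for c, k in self.kobs_per_concentration
            ],
            "kon_per_M_s": self.kon,
            "kobs_intercept_s": self.kobs_intercept,
            "Kd_M": self.Kd,
            "Rmax": self.Rmax,
            "koff_from_kd_kon_s": self.koff_from_kd_kon,
            "koff_direct_s": self.koff_direct,
            "koff_consistent": self.koff_consistent,
            "saturation_reached": self.saturation_reached,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def exponential_fit(times, values, mode: str) -> ExponentialFit:
    """Least-squares mono-exponential fit of one phase.

    ``mode='rise'`` fits ``A*(1 - exp(-k t)) + c``; ``mode='decay'`` fits
    ``A*exp(-k t) + c``.  Requires at least five points and a signal that
    actually evolves; raises :class:`FitError` for flat input, failed
    convergence or a non-positive fitted rate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if mode not in ("rise", "decay"):
        raise ParameterError(f"mode must be 'rise' or 'decay', got {mode!r}")
    if t.size < 5:
        raise FitError("need at least 5 points for an exponential fit")
    span = float(np.ptp(y))
    if span <= 0 or not np.isfinite(span):
        raise FitError("signal is constant; rate is unidentifiable")
    t = t - t[0]

    # crude rate guess: time to cover ~63% of the span
    target = y[0] + 0.632 * (y[-1] - y[0])
    crossed = np.nonzero((y - target) * (y[0] - target) < 0)[0]
    t63 = t[crossed[0]] if crossed.size else t[-1] / 3.0
    k0 = 1.0 / max(t63, t[-1] * 1e-3)

    if mode == "rise":
        def model(tt, A, k, c):
            return A * (1.0 - np.exp(-k * tt)) + c
        p0 = (y[-1] - y[0], k0, y[0])
    else:
        def model(tt, A, k, c):
            return A * np.exp(-k * tt) + c
        p0 = (y[0] - y[-1], k0, y[-1])

    try:
        with warnings.catch_warnings():
            # noiseless input makes the covariance singular; that is fine
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    A, k, c = popt
    if not np.isfinite(k) or k <= 0:
        raise FitError(f"fitted rate is not positive: {k!r}")
    kerr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else math.nan
    return ExponentialFit(rate=float(k), amplitude=float(A),
                          offset=float(c), rate_stderr=kerr)


def kon_from_kobs(concentrations, kobs_values) -> tuple[float, float]:
    """Slope and intercept of the kobs-vs-concentration line.

    For 1:1 kinetics kobs = kon*[P] + koff, so the slope is kon
    (M^-1 s^-1) and the intercept estimates koff (s^-1).  Needs at least
    three distinct concentrations.
    """
    conc = np.asarray(concentrations, dtype=float)
    kobs = np.asarray(kobs_values, dtype=float)
    if conc.shape != kobs.shape or conc.ndim != 1:
        raise ParameterError("concentrations and kobs must be equal-length 1-D")
    if np.unique(conc).size < 3:
        raise FitError("need at least 3 distinct concentrations for kon")
    fit = stats.linregress(conc, kobs)
    return float(fit.slope), float(fit.intercept)


def kd_from_responses(concentrations, equilibrium_responses) -> ResponseFit:
    """Fit the equilibrium-response titration with a binding hyperbola.

    ``Req = Rmax*[P]/([P] + Kd)``, unweighted least squares.  Needs at
    least four concentrations; when the highest concentration is below
    Kd/2 the plateau is unconstrained and the result is flagged with
    ``saturation_reached=False``.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(equilibrium_responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ParameterError(
            "concentrations and responses must be equal-length 1-D")
    if conc.size < 4:
        raise FitError("need at least 4 concentrations for a Kd fit")
    if np.all(resp == 0):
        raise FitError("all responses are zero; no binding signal")

    def hyperbola(P, Rmax, Kd):
        return Rmax * P / (P + Kd)

    p0 = (float(resp.max()), float(np.median(conc)))
    try:
        popt, _ = optimize.curve_fit(hyperbola, conc, resp, p0=p0,
                                     maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"hyperbola fit did not converge: {exc}") from exc
    Rmax, Kd = popt
    if not np.isfinite(Kd) or Kd <= 0:
        raise FitError(f"fitted Kd is not positive: {Kd!r}")
    return ResponseFit(Kd=float(Kd), Rmax=float(Rmax),
                       saturation_reached=bool(conc.max() >= Kd / 2.0))


#: relative disagreement between koff = Kd*kon and the direct dissociation
#: fit below which the two routes are declared consistent
KOFF_CONSISTENCY_TOL = 0.25


def analyze_bli_dataset(sensorgrams: list[Sensorgram]) -> BLIFitResult:
    """Full kinetic analysis of a concentration series of sensorgrams.

    Runs the per-trace association fits, the kobs-slope kon, the
    equilibrium-response Kd, koff = Kd*kon, and the direct dissociation
    cross-check (mean of the per-trace decay rates).  All traces must
    share the same phase boundaries.
    """
    if len(sensorgrams) < 3:
        raise ParameterError("need at least 3 sensorgrams")
    concs = [s.analyte_concentration for s in sensorgrams]
    if len(set(concs)) < 3:
        raise ParameterError("need at least 3 distinct concentrations")
    bounds = {s.phase_bounds for s in sensorgrams}
    if len(bounds) != 1:
        raise ParameterError(
            f"inconsistent phase boundaries across traces: {sorted(bounds)}")

    kobs_pairs = []
    plateaus = []
    koff_rates = []
    for s in sensorgrams:
        t_a, r_a = s.association()
        rise = exponential_fit(t_a, r_a, "rise")
        kobs_pairs.append((s.analyte_concentration, rise.rate))
        # equilibrium response = fitted asymptote; at the slowest (lowest
        # concentration) trace the recorded signal may still sit a few
        # percent below its plateau, which a raw tail average would
        # propagate straight into the Kd
        plateaus.append(rise.amplitude + rise.offset)
        t_d, r_d = s.dissociation()
        koff_rates.append(exponential_fit(t_d, r_d, "decay").rate)

    kon, intercept = kon_from_kobs(concs, [k for _, k in kobs_pairs])
    resp_fit = kd_from_responses(concs, plateaus)
    koff = resp_fit.Kd * kon
    koff_direct = float(np.mean(koff_rates))
    consistent = (abs(koff_direct - koff) / koff_direct
                  < KOFF_CONSISTENCY_TOL) if koff_direct > 0 else False
    return BLIFitResult(
        kobs_per_concentration=kobs_pairs,
        kon=kon,
        kobs_intercept=intercept,
        Kd=resp_fit.Kd,
        Rmax=resp_fit.Rmax,
        koff_from_kd_kon=koff,
        koff_direct=koff_direct,
        koff_consistent=consistent,
        saturation_reached=resp_fit.saturation_reached,
    )
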