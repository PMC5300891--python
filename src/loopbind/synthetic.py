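"""Synthetic BLI datasets and reference parameter sets.

Every stage of the analysis can be exercised without downloads: this
module fabricates sensorgram series with known ground truth following the
same 1:1-Langmuir forms the fitting pipeline assumes —

* association  ``R(t) = Req * (1 - exp(-kobs t))`` with
  ``kobs = kon*[P] + koff`` and ``Req = Rmax*[P]/([P] + koff/kon)``,
* dissociation ``R(t) = R(t_assoc) * exp(-koff (t - t_assoc))``,
* i.i.d. additive Gaussian noise of configurable standard deviation.

Three presets mirror the acquisition conditions for the ZBP1/Zipcode
constructs: the KH3-KH4 di-domain titrated 5-160 nM and the two
single-functional-domain mutants (one domain knocked out by a GxxG->GDDG
mutation) titrated 125-8000 nM, each with the apparent rate constants
measured for that construct.  Trace durations per preset are chosen so the
slowest trace reaches >= 95% of its plateau.

What the generator does *not* emulate: sensor loading variability,
baseline drift, reference-channel artefacts or mass-transport limitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bli import Sensorgram
from .exceptions import ParameterError
from .model import (
    KineticParameters,
    MixtureConditions,
    ZIPCODE_CONDITIONS,
    ZIPCODE_KH34_PARAMETERS,
)

__all__ = [
    "GroundTruth",
    "simulate_sensorgram",
    "generate_bli_dataset",
    "zipcode_defaults",
    "PRESETS",
]


@dataclass(frozen=True)
class GroundTruth:
    """True constants behind a generated dataset (for recovery studies)."""

    kon: float
    koff: float
    concentrations: tuple[float, ...]
    Rmax: float
    noise_sd: float
    seed: int | None

    @property
    def Kd(self) -> float:
        return self.koff / self.kon

    def to_dict(self) -> dict:
        return {
            "kon_per_M_s": self.kon,
            "koff_s": self.koff,
            "Kd_M": self.Kd,
            "concentrations_M": list(self.concentrations),
            "Rmax": self.Rmax,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def simulate_sensorgram(kon: float, koff: float, P: float, Rmax: float,
                        t_assoc: float, t_dissoc: float,
                        noise_sd: float = 0.0,
                        seed=None, dt: float = 1.0) -> Sensorgram:
    """One synthetic 1:1-Langmuir sensorgram at analyte concentration ``P``.

    ``seed`` may be an int, None or a :class:`numpy.random.Generator`.
    With ``P = 0`` the trace is flat at zero (plus noise).
    """
    for name, v in (("kon", kon), ("koff", koff), ("t_assoc", t_assoc),
                    ("t_dissoc", t_dissoc), ("dt", dt)):
        if not v > 0:
            raise ParameterError(f"{name} must be positive, got {v!r}")
    if P < 0 or noise_sd < 0 or Rmax < 0:
        raise ParameterError("P, Rmax and noise_sd must be non-negative")

    times = np.arange(0.0, t_assoc + t_dissoc + 0.5 * dt, dt)
    kobs = kon * P + koff
    Kd = koff / kon
    Req = Rmax * P / (P + Kd)
    response = np.where(
        times <= t_assoc,
        Req * (1.0 - np.exp(-kobs * times)),
        Req * (1.0 - np.exp(-kobs * t_assoc))
        * np.exp(-koff * (times - t_assoc)),
    )
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        response = response + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(
        analyte_concentration=P,
        times=times,
        response=response,
        phase_bounds=(0.0, t_assoc, t_assoc + t_dissoc),
    )


#: acquisition presets: apparent 1:1 constants and two-fold titration
#: series per construct; durations let the slowest trace reach its plateau
PRESETS = {
    "didomain": {
        "kon": 1.6e5, "koff": 0.0033,
        "concentrations": tuple(c * 1e-9 for c in (5, 10, 20, 40, 80, 160)),
        "t_assoc": 900.0, "t_dissoc": 900.0, "dt": 1.0,
    },
    "kh3_only": {
        "kon": 3.0e4, "koff": 0.046,
        "concentrations": tuple(
            c * 1e-9 for c in (125, 250, 500, 1000, 2000, 4000, 8000)),
        "t_assoc": 120.0, "t_dissoc": 120.0, "dt": 0.1,
    },
    "kh4_only": {
        "kon": 1.4e5, "koff": 0.13,
        "concentrations": tuple(
            c * 1e-9 for c in (125, 250, 500, 1000, 2000, 4000, 8000)),
        "t_assoc": 60.0, "t_dissoc": 60.0, "dt": 0.05,
    },
}


def generate_bli_dataset(protein: str = "didomain", noise_sd: float = 0.0,
                         seed: int | None = None, Rmax: float = 1.0,
                         ) -> tuple[list[Sensorgram], GroundTruth]:
    """Full concentration series for one construct preset.

    Deterministic in ``(protein, noise_sd, seed)``: per-trace noise streams
    are spawned from a single seed sequence, so regenerating with the same
    arguments gives byte-identical data.
    """
    if protein not in PRESETS:
        raise ParameterError(
            f"unknown preset {protein!r}; available: {sorted(PRESETS)}")
    preset = PRESETS[protein]
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(
                len(preset["concentrations"]))]
    traces = [
        simulate_sensorgram(
            preset["kon"], preset["koff"], P, Rmax,
            preset["t_assoc"], preset["t_dissoc"],
            noise_sd=noise_sd, seed=rng, dt=preset["dt"],
        )
        for P, rng in zip(preset["concentrations"], rngs)
    ]
    truth = GroundTruth(
        kon=preset["kon"], koff=preset["koff"],
        concentrations=preset["concentrations"],
        Rmax=Rmax, noise_sd=noise_sd, seed=seed,
    )
    return traces, truth


def write_bli_dataset(traces: list[Sensorgram], truth: GroundTruth,
                      out_dir) -> None:
    """One CSV (+ JSON side-car) per trace plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, trace in enumerate(traces):
        name = f"trace_{i:02d}.csv"
        trace.to_csv(out_dir / name)
        names.append(name)
    manifest = {"traces": names, "ground_truth": truth.to_dict()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_bli_dataset(in_dir) -> list[Sensorgram]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return [Sensorgram.from_csv(in_dir / name) for name in manifest["traces"]]


def zipcode_defaults() -> tuple[KineticParameters, MixtureConditions]:
    """Reference rate constants and cell-like concentrations.

    Returns the measured/derived ZBP1 KH3-KH4 / Zipcode parameter set
    (kon3 = 3.0e4, koff3 = 0.046, kon4 = 1.4e5, koff4 = 0.13 in SI;
    kC3 = 2, kC4 = 9.333 s^-1) and the base mixture (0.2 uM protein,
    0.4 nM RNA).
    """
    return ZIPCODE_KH34_PARAMETERS, ZIPCODE_CONDITIONS
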