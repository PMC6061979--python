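"""Submembrane Ca2+ shell dynamics.

Ca2+ entering through voltage-gated Ca2+ channels is assumed to distribute
instantaneously within a thin shell just below the membrane; its decay back
to baseline is lumped into a single exponential:

    d[Ca]i/dt = -i_Ca / (2 F d)  -  ([Ca]i - [Ca]i_inf) / tau_r

with i_Ca the Ca2+ current density (negative when inward, so inward current
raises [Ca]i), d the shell depth and tau_r the removal time constant.  The
removal term is written in its stabilizing orientation, relaxing [Ca]i
toward baseline.  Working units are mV, ms, mM, mA/cm2, with depth given in
um and converted to cm internally; with those units the influx term is
-i_Ca/(2*F*d_cm) in mM/ms.

No sarcoplasmic-reticulum release or uptake, buffering, exchangers or pumps
are represented: this shell is a forcing function that supplies a realistic
[Ca]i signal to the Ca2+-dependent K+ channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channels import TemperatureContext

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "CalciumShellSpec",
    "CalciumState",
    "ca_influx_rate",
    "ca_shell_step",
    "ca_reversal",
]

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalciumShellSpec:
    """Shell geometry and removal kinetics.

    depth        shell depth in um (physiological range ~0.1-0.6).
    baseline     resting [Ca]i in mM (150 nM default).
    tau_removal  exponential removal time constant, ms.
    floor        lowest admissible [Ca]i in mM; results below it are clamped
                 with a logged warning.
    ca_out       extracellular [Ca] in mM, used for the Nernst potential.
    dynamic_eca  if true the Ca2+ reversal potential tracks [Ca]i; otherwise
                 it is held fixed at ``e_ca_fixed``.
    """

    depth: float = 0.1
    baseline: float = 150e-6
    tau_removal: float = 20.0
    floor: float = 1e-6
    ca_out: float = 2.0
    dynamic_eca: bool = False
    e_ca_fixed: float = 51.0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.tau_removal <= 0 or self.baseline <= 0:
            raise ValueError("depth, tau_removal and baseline must be positive")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass
class CalciumState:
    """Instantaneous shell [Ca]i (mM) and Ca2+ reversal potential (mV)."""

    ca_i: float
    e_ca: float = 51.0


def ca_influx_rate(i_ca, spec: CalciumShellSpec):
    """d[Ca]i/dt (mM/ms) contributed by a Ca2+ current density in mA/cm2.

    Negative (inward) current gives a positive rate.
    """
    depth_cm = spec.depth * 1e-4
    return -np.asarray(i_ca, dtype=float) / (2.0 * FARADAY * depth_cm)


def ca_shell_step(
    state: CalciumState,
    i_ca: float,
    dt: float,
    spec: CalciumShellSpec,
    temp: TemperatureContext | None = None,
) -> CalciumState:
    """One forward-Euler step of the shell ODE; [Ca]i stays positive."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dca = ca_influx_rate(i_ca, spec) - (state.ca_i - spec.baseline) / spec.tau_removal
    ca = state.ca_i + dt * float(dca)
    if ca < spec.floor:
        log.warning("shell [Ca]i hit the %.3g mM floor; clamping", spec.floor)
        ca = spec.floor
    e_ca = (
        ca_reversal(ca, spec.ca_out, temp or TemperatureContext(37.0))
        if spec.dynamic_eca
        else spec.e_ca_fixed
    )
    return CalciumState(ca_i=ca, e_ca=e_ca)


def ca_reversal(ca_i, ca_o, temp: TemperatureContext) -> float:
    """Nernst potential of Ca2+ in mV: (RT/2F) ln([Ca]o/[Ca]i)."""
    ca_i = np.asarray(ca_i, dtype=float)
    ca_o = np.asarray(ca_o, dtype=float)
    if np.any(ca_i <= 0) or np.any(ca_o <= 0):
        raise ValueError("concentrations must be positive")
    rt_over_2f = GAS_CONSTANT * (temp.celsius + 273.15) / (2.0 * FARADAY) * 1e3
    out = rt_over_2f * np.log(ca_o / ca_i)
    return float(out) if out.ndim == 0 else out
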