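"""Hodgkin-Huxley-type ion channel kinetics.

Every conductance in the detrusor smooth muscle (DSM) cell model except the
BK channel (see :mod:`detrusor.bk`) is described in the classical
Hodgkin-Huxley form

    I = gmax * m**x * h**y * (V - Erev)

with first-order gating kinetics

    dm/dt = (m_inf(V) - m) / tau_m(V)

and Boltzmann steady states

    m_inf(V) = 1 / (1 + exp((V + Vhalf) / S)).

The slope ``S`` is signed: with this literal form, activation gates carry a
negative slope and inactivation gates a positive one (the hyperpolarization-
activated channel is the exception, its "activation" grows with
hyperpolarization and therefore uses a positive slope).

Units throughout: mV, ms, mM, S/cm2, mA/cm2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "TauSpec",
    "GatingVariableSpec",
    "CaHillSpec",
    "LigandSpec",
    "HHChannelSpec",
    "TemperatureContext",
    "temperature_adjust",
    "boltzmann_steady_state",
    "time_constant",
    "gating_step",
    "hh_current",
    "hill",
    "katp_activation",
    "sk_apamin_scaling",
]

#: admissible membrane-voltage window over which kinetics must be well defined
V_RANGE = (-150.0, 60.0)


@dataclass(frozen=True)
class TauSpec:
    """Gating time constant, constant or bell-shaped in voltage.

    tau(V) = tau0 + amp / cosh((V + vmid) / sigma)

    ``amp = 0`` gives a voltage-independent time constant.  All values in ms.
    """

    tau0: float
    amp: float = 0.0
    vmid: float = 0.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.tau0 <= 0.0 and self.amp <= 0.0:
            raise ValueError("time constant must be positive at every voltage")
        if self.sigma == 0.0:
            raise ValueError("sigma must be nonzero")

    def __call__(self, v):
        import numpy as np

        return self.tau0 + self.amp / np.cosh((v + self.vmid) / self.sigma)


@dataclass(frozen=True)
class GatingVariableSpec:
    """One gating variable: Boltzmann steady state plus relaxation time.

    ``half_potential`` is the value added to V inside the exponential, so the
    midpoint of the curve sits at V = -half_potential.  ``exponent`` is the
    power the gate is raised to in the current equation; 0 means the gate is
    absent (its factor is one).
    """

    half_potential: float
    slope: float
    tau: TauSpec
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.slope == 0.0:
            raise ValueError("slope must be nonzero")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")


@dataclass(frozen=True)
class CaHillSpec:
    """Hill-type calcium dependence multiplying a gate's steady state.

    factor = ca**n / (ca**n + kd**n), ca and kd in mM.
    """

    kd: float
    n: float = 2.0

    def __post_init__(self) -> None:
        if self.kd <= 0.0 or self.n <= 0.0:
            raise ValueError("kd and n must be positive")


@dataclass(frozen=True)
class LigandSpec:
    """Equilibrium ligand modulation of a conductance (Hill descriptor).

    ``kind`` is 'atp_inhibition' (KATP: open at low ATP, shut at high ATP) or
    'apamin_block' (SK: conductance scaled down by the toxin).  ``half`` is
    the half-effect concentration in the ligand's own units (mM for ATP).
    """

    kind: str
    half: float
    n: float = 1.0
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("atp_inhibition", "apamin_block"):
            raise ValueError(f"unknown ligand kind {self.kind!r}")
        if self.half <= 0.0 or self.n <= 0.0:
            raise ValueError("half and n must be positive")
        if self.concentration < 0.0:
            raise ValueError("ligand concentration must be nonnegative")


@dataclass(frozen=True)
class HHChannelSpec:
    """Full description of one HH-type conductance."""

    name: str
    gmax: float
    erev: float
    activation: GatingVariableSpec
    inactivation: Optional[GatingVariableSpec] = None
    ca_dependence: Optional[CaHillSpec] = None
    ligand_dependence: Optional[LigandSpec] = None
    is_calcium_carrier: bool = False

    def __post_init__(self) -> None:
        if self.gmax < 0.0:
            raise ValueError("gmax must be nonnegative")
        if not math.isfinite(self.erev):
            raise ValueError("erev must be finite")


@dataclass(frozen=True)
class TemperatureContext:
    """Operating temperature and the rate multiplier it implies.

    tadj = 2**((celsius - 37) / 10); rates are multiplied by tadj, so all
    relaxation time constants are divided by it.  Steady states are not
    temperature dependent.
    """

    celsius: float
    tadj: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.celsius <= 50.0):
            raise ValueError("temperature outside the plausible 0-50 degC range")
        object.__setattr__(self, "tadj", 2.0 ** ((self.celsius - 37.0) / 10.0))


def temperature_adjust(celsius: float) -> TemperatureContext:
    """Return the temperature context for an operating temperature in degC."""
    return TemperatureContext(celsius)


def boltzmann_steady_state(v, gate: GatingVariableSpec):
    """Steady-state open fraction 1 / (1 + exp((V + Vhalf) / S)).

    Accepts scalars or arrays; rejects non-finite voltages.
    """
    import numpy as np

    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    out = 1.0 / (1.0 + np.exp((v + gate.half_potential) / gate.slope))
    return float(out) if out.ndim == 0 else out


def time_constant(v, gate: GatingVariableSpec, temp: TemperatureContext | None = None):
    """Gating time constant at voltage ``v``, temperature-scaled if given."""
    tau = gate.tau(v)
    if temp is not None:
        tau = tau / temp.tadj
    return tau


def gating_step(
    m: float,
    v: float,
    gate: GatingVariableSpec,
    dt: float,
    temp: TemperatureContext | None = None,
):
    """One forward-Euler step of dm/dt = (m_inf - m)/tau, clamped to [0, 1]."""
    import numpy as np

    if dt <= 0.0:
        raise ValueError("dt must be positive")
    tau = time_constant(v, gate, temp)
    if np.any(np.asarray(tau) <= 0.0):
        raise ValueError("configured time constant is not positive")
    minf = boltzmann_steady_state(v, gate)
    out = m + dt * (minf - m) / tau
    return float(np.clip(out, 0.0, 1.0)) if np.isscalar(out) or np.ndim(out) == 0 else np.clip(out, 0.0, 1.0)


def hh_current(v, m, h, spec: HHChannelSpec):
    """Ionic current density gmax * m**x * h**y * (V - Erev) in mA/cm2.

    For channels without an inactivation gate pass ``h = 1`` (or any value;
    a missing gate contributes a factor of one because its exponent is 0).
    """
    x = spec.activation.exponent
    y = spec.inactivation.exponent if spec.inactivation is not None else 0
    po = m**x * (h**y if y else 1.0)
    return spec.gmax * po * (v - spec.erev)


def hill(c, kd: float, n: float):
    """Hill saturation c**n / (c**n + kd**n); 0 at c = 0, 1/2 at c = kd."""
    import numpy as np

    c = np.asarray(c, dtype=float)
    out = np.where(c > 0, c**n / (c**n + kd**n), 0.0)
    return float(out) if out.ndim == 0 else out


def katp_activation(atp: float, spec: HHChannelSpec) -> float:
    """ATP-dependent steady-state availability of the KATP conductance.

    KATP channels are shut at physiological ATP and open as ATP falls; this
    is the equilibrium Hill descriptor 1 / (1 + (ATP/K)**n): 1 at zero ATP,
    1/2 at the half-inhibition constant, 0 at saturating ATP.
    """
    if atp < 0.0:
        raise ValueError("ATP concentration must be nonnegative")
    lig = spec.ligand_dependence
    if lig is None or lig.kind != "atp_inhibition":
        raise ValueError(f"channel {spec.name!r} has no ATP descriptor")
    return 1.0 / (1.0 + (atp / lig.half) ** lig.n)


def sk_apamin_scaling(apamin: float, spec: HHChannelSpec) -> float:
    """Fractional SK conductance remaining in the presence of apamin.

    Equilibrium block: 1 at zero toxin, 1/2 at the IC50, tending to 0 at
    saturating concentration.  Multiplies the SK maximal conductance.
    """
    if apamin < 0.0:
        raise ValueError("apamin concentration must be nonnegative")
    lig = spec.ligand_dependence
    if lig is None or lig.kind != "apamin_block":
        raise ValueError(f"channel {spec.name!r} has no apamin descriptor")
    return 1.0 / (1.0 + (apamin / lig.half) ** lig.n)
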