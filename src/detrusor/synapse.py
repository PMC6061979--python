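"""Synaptic conductance time courses and current.

Spike-type action potentials in detrusor smooth muscle are triggered by
purinergic (ATP) synaptic input; subthreshold inputs appear as spontaneous
depolarizations (SDs).  Three standard conductance waveforms are provided:

single_exp   g(t) = gmax * exp(-(t-t0)/tau)                      (t >= t0)
alpha        g(t) = gmax * ((t-t0)/tau) * exp(1 - (t-t0)/tau)
biexp        g(t) = gmax * f * (exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise))

The biexponential normalization f is computed analytically from the peak
time t_peak = t0 + (tau_d tau_r / (tau_d - tau_r)) * ln(tau_d / tau_r) so
that the waveform's maximum equals gmax exactly.

The synaptic current is the usual conductance-based form
I = g(t) * (V - e_syn), in nA with g in uS and V in mV.  The reversal
potential defaults to 0 mV, appropriate for a nonselective purinergic
cation conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SynapseSpec", "syn_conductance", "syn_current"]

_MODELS = ("single_exp", "alpha", "biexp")


@dataclass(frozen=True)
class SynapseSpec:
    """One synaptic conductance: waveform, peak amplitude and timing.

    gmax in uS, times in ms, e_syn in mV.  ``tau`` serves the single_exp and
    alpha models; ``tau_rise``/``tau_decay`` serve the biexp model and must
    satisfy tau_rise < tau_decay.
    """

    model: str = "biexp"
    gmax: float = 0.0095
    onset: float = 0.0
    tau: float = 50.0
    tau_rise: float = 15.0
    tau_decay: float = 25.0
    e_syn: float = 0.0
    compartment: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.gmax < 0:
            raise ValueError("gmax must be nonnegative")
        if self.tau <= 0 or self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.model == "biexp" and self.tau_rise >= self.tau_decay:
            raise ValueError("biexp requires tau_rise < tau_decay")

    @property
    def peak_time(self) -> float:
        """Time of the conductance maximum."""
        if self.model == "single_exp":
            return self.onset
        if self.model == "alpha":
            return self.onset + self.tau
        td, tr = self.tau_decay, self.tau_rise
        return self.onset + td * tr / (td - tr) * math.log(td / tr)

    @property
    def biexp_norm(self) -> float:
        """Amplitude normalization making the biexp peak equal gmax."""
        tp = self.peak_time - self.onset
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))


def syn_conductance(t, spec: SynapseSpec):
    """Synaptic conductance (uS) at time ``t`` (ms); zero before onset."""
    t = np.asarray(t, dtype=float)
    rel = t - spec.onset
    if spec.model == "single_exp":
        g = spec.gmax * np.exp(-rel / spec.tau)
    elif spec.model == "alpha":
        g = spec.gmax * (rel / spec.tau) * np.exp(1.0 - rel / spec.tau)
    else:
        g = (
            spec.gmax
            * spec.biexp_norm
            * (np.exp(-rel / spec.tau_decay) - np.exp(-rel / spec.tau_rise))
        )
    g = np.where(rel < 0, 0.0, np.maximum(g, 0.0))
    return float(g) if g.ndim == 0 else g


def syn_current(v, t, spec: SynapseSpec):
    """Synaptic current I = g(t) (V - e_syn), in nA (g in uS, V in mV)."""
    return syn_conductance(t, spec) * (np.asarray(v, dtype=float) - spec.e_syn)
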