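"""Single-cell protocol engines: current clamp, voltage clamp, synaptic drive.

The cell is a single isopotential compartment carrying the full channel
complement.  Protocols are schedules of rectangular segments (current in nA
for current clamp, command voltage in mV for voltage clamp) plus optional
synaptic conductance inputs; every run returns a :class:`SimulationTrace`
holding the voltage, the per-channel current densities and the shell [Ca]i
on the fixed integration grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import E_SYN, ModelConfig, default_config
from .engine import CompartmentModel, EngineState, InstabilityError
from .engine_kernel import HAVE_NUMBA, run_kernel
from .synapse import SynapseSpec, syn_conductance

__all__ = [
    "StimulusProtocol",
    "SimulationTrace",
    "MembraneState",
    "init_state",
    "run_protocol",
    "run_current_clamp",
    "run_voltage_clamp",
    "run_synaptic",
    "standard_pulse_protocol",
    "long_pulse_protocol",
    "standard_synaptic_protocol",
    "VoltageClampResult",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """A stimulation schedule.

    mode      'current_clamp', 'voltage_clamp' or 'synaptic'.
    segments  ordered, non-overlapping (start_ms, duration_ms, amplitude)
              triples; amplitude is nA for current clamp and mV for voltage
              clamp.
    holding   holding potential (mV) between voltage-clamp segments.
    synapses  synaptic conductance inputs (synaptic mode).
    duration  total simulated time in ms.
    settle    unstimulated time simulated before t = 0 so the cell sits at
              its emergent rest when the schedule starts.
    """

    mode: str = "current_clamp"
    segments: Tuple[Tuple[float, float, float], ...] = ()
    holding: float = -50.0
    synapses: Tuple[SynapseSpec, ...] = ()
    duration: float = 500.0
    settle: float = 0.0
    compartment: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp", "synaptic"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        last_end = -np.inf
        for start, dur, _ in self.segments:
            if start < 0 or dur < 0:
                raise ValueError("segment times must be nonnegative")
            if start < last_end:
                raise ValueError("segments must be ordered and non-overlapping")
            last_end = start + dur

    def amplitude_at(self, t: float) -> Optional[float]:
        for start, dur, amp in self.segments:
            if start <= t < start + dur:
                return amp
        return None


@dataclass
class SimulationTrace:
    """Time series produced by one run.

    ``v`` and ``ca`` have shape (n_samples,) for a single recording site or
    (n_samples, n_sites) for several; ``currents`` maps channel name to a
    series of current densities in mA/cm2 (single-site runs only).
    """

    time: np.ndarray
    v: np.ndarray
    currents: Dict[str, np.ndarray] = field(default_factory=dict)
    ca: Optional[np.ndarray] = None
    sites: Tuple[str, ...] = ("soma",)
    metadata: Dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time}
        if self.v.ndim == 1:
            data["v_mV"] = self.v
        else:
            for k, site in enumerate(self.sites):
                data[f"v_{site}_mV"] = self.v[:, k]
        if self.ca is not None:
            if self.ca.ndim == 1:
                data["ca_mM"] = self.ca
            else:
                for k, site in enumerate(self.sites):
                    data[f"ca_{site}_mM"] = self.ca[:, k]
        for name, series in self.currents.items():
            data[f"i_{name}_mA_cm2"] = series
        return pd.DataFrame(data)


@dataclass
class MembraneState:
    """Spec-level snapshot of one compartment (voltage, gates, BK, calcium)."""

    v: float
    gates: Dict[str, Dict[str, float]]
    bk: np.ndarray
    ca_i: float
    e_ca: float
    t: float = 0.0


def _to_membrane_state(model: CompartmentModel, st: EngineState) -> MembraneState:
    gates: Dict[str, Dict[str, float]] = {}
    for k, ch in enumerate(model.config.channels):
        entry = {"m": float(st.gates[model.act_idx[k], 0])}
        if model.inact_idx[k] < model.n_gates:
            entry["h"] = float(st.gates[model.inact_idx[k], 0])
        gates[ch.name] = entry
    return MembraneState(
        v=float(st.v[0]), gates=gates, bk=st.bk[:, 0].copy(),
        ca_i=float(st.ca[0]), e_ca=float(st.e_ca[0]), t=st.t,
    )


def init_state(config: Optional[ModelConfig] = None) -> MembraneState:
    """Resting state: V at the configured initial value, gates at their
    steady states, BK at its stationary occupancy, [Ca]i at baseline."""
    config = config or default_config()
    model = CompartmentModel(config)
    return _to_membrane_state(model, model.init_state())


def run_protocol(
    protocol: StimulusProtocol,
    config: Optional[ModelConfig] = None,
    model: Optional[CompartmentModel] = None,
    dt: Optional[float] = None,
    record_every: int = 1,
    record_comps: Optional[Sequence[int]] = None,
    site_labels: Optional[Sequence[str]] = None,
    record_currents: bool = True,
) -> SimulationTrace:
    """Integrate a protocol and return the recorded trace.

    A ``model`` may be passed for multicompartment runs; otherwise a single
    compartment is built from ``config``.
    """
    if model is None:
        config = config or default_config()
        model = CompartmentModel(config)
    else:
        config = model.config
    dt = dt if dt is not None else model.dt
    record_comps = list(record_comps) if record_comps is not None else [0]
    record_currents = record_currents and len(record_comps) == 1

    st = model.init_state(
        protocol.holding if protocol.mode == "voltage_clamp" else None
    )
    use_kernel = HAVE_NUMBA and not config.calcium.dynamic_eca
    if protocol.settle > 0:
        n_settle = int(round(protocol.settle / dt))
        clamp = protocol.holding if protocol.mode == "voltage_clamp" else None
        if use_kernel:
            _kernel_run(model, st, n_settle, dt, clamp_const=clamp)
        else:
            for _ in range(n_settle):
                model.step(st, dt, clamp_v=clamp)
        st.t = 0.0

    n_steps = int(round(protocol.duration / dt))
    n_rec = n_steps // record_every + 1
    n_sites = len(record_comps)
    rec_t = np.empty(n_rec)
    rec_v = np.empty((n_rec, n_sites))
    rec_ca = np.empty((n_rec, n_sites))
    comp = np.asarray(record_comps)

    i_chan0 = model.channel_current_densities(st)
    rec_t[0] = st.t
    rec_v[0] = st.v[comp]
    rec_ca[0] = st.ca[comp]

    if use_kernel:
        rec_i_arr = (
            np.empty((len(model.names), n_rec)) if record_currents else np.empty((0, 0))
        )
        if record_currents:
            rec_i_arr[:, 0] = i_chan0[:, comp[0]]
        k = _kernel_run(
            model, st, n_steps, dt,
            protocol=protocol,
            record_every=record_every,
            rec=(comp, rec_t, rec_v, rec_ca, rec_i_arr, record_currents),
        )
        rec_i = (
            {name: rec_i_arr[row] for row, name in enumerate(model.names)}
            if record_currents
            else {}
        )
    else:
        rec_i = (
            {name: np.empty(n_rec) for name in model.names} if record_currents else {}
        )

        def record(kk, i_chan):
            rec_t[kk] = st.t
            rec_v[kk] = st.v[comp]
            rec_ca[kk] = st.ca[comp]
            if record_currents:
                for row, name in enumerate(model.names):
                    rec_i[name][kk] = i_chan[row, comp[0]]

        if record_currents:
            for row, name in enumerate(model.names):
                rec_i[name][0] = i_chan0[row, comp[0]]
        # precompute the schedule on the same grid the compiled path uses
        times = st.t + dt * np.arange(n_steps)
        stim_amp = np.zeros(n_steps)
        clamp_cmd = np.full(n_steps, np.nan)
        if protocol.mode == "voltage_clamp":
            clamp_cmd[:] = protocol.holding
            for start, seg_dur, amp in protocol.segments:
                clamp_cmd[(times >= start) & (times < start + seg_dur)] = amp
        elif protocol.mode == "current_clamp":
            for start, seg_dur, amp in protocol.segments:
                stim_amp[(times >= start) & (times < start + seg_dur)] = amp
        i_inj = np.zeros(model.n_comp)
        k = 1
        for n in range(n_steps):
            if protocol.mode == "voltage_clamp":
                i_chan = model.step(st, dt, clamp_v=clamp_cmd[n])
            elif protocol.mode == "current_clamp":
                i_inj[:] = 0.0
                i_inj[protocol.compartment] = stim_amp[n]
                i_chan = model.step(st, dt, i_inj_nA=i_inj)
            else:
                i_chan = model.step(st, dt, synapses=protocol.synapses)
            if (n + 1) % record_every == 0:
                record(k, i_chan)
                k += 1

    labels = tuple(site_labels) if site_labels else tuple(
        f"c{c}" for c in record_comps
    ) if n_sites > 1 else ("soma",)
    v = rec_v[:k, 0] if n_sites == 1 else rec_v[:k]
    ca = rec_ca[:k, 0] if n_sites == 1 else rec_ca[:k]
    meta = {
        "mode": protocol.mode,
        "dt_ms": dt,
        "record_every": record_every,
        "celsius": config.temperature,
        "segments": list(protocol.segments),
        "stim_start": protocol.segments[0][0]
        if protocol.segments
        else (protocol.synapses[0].onset if protocol.synapses else None),
    }
    return SimulationTrace(
        time=rec_t[:k], v=v, currents={n: s[:k] for n, s in rec_i.items()},
        ca=ca, sites=labels, metadata=meta,
    )


def _kernel_run(
    model: CompartmentModel,
    st: EngineState,
    n_steps: int,
    dt: float,
    protocol: Optional[StimulusProtocol] = None,
    clamp_const: Optional[float] = None,
    record_every: int = 1,
    rec=None,
) -> int:
    """Drive the compiled integrator; mutates ``st`` and the record arrays."""
    t0 = st.t
    times = t0 + dt * np.arange(n_steps)
    stim_amp = np.zeros(n_steps)
    stim_comp = -1
    clamp_cmd = np.full(n_steps, np.nan)
    syn_specs: Tuple[SynapseSpec, ...] = ()
    if clamp_const is not None:
        clamp_cmd[:] = clamp_const
    elif protocol is not None:
        if protocol.mode == "voltage_clamp":
            clamp_cmd[:] = protocol.holding
            for start, dur, amp in protocol.segments:
                clamp_cmd[(times >= start) & (times < start + dur)] = amp
        elif protocol.mode == "current_clamp":
            stim_comp = protocol.compartment
            for start, dur, amp in protocol.segments:
                stim_amp[(times >= start) & (times < start + dur)] = amp
        else:
            syn_specs = protocol.synapses
    if syn_specs:
        syn_comp = np.array([s.compartment for s in syn_specs], dtype=np.int64)
        syn_g = np.vstack([syn_conductance(times, s) for s in syn_specs])
        syn_e = np.array([s.e_syn for s in syn_specs])
    else:
        syn_comp = np.zeros(0, dtype=np.int64)
        syn_g = np.zeros((0, n_steps))
        syn_e = np.zeros(0)

    if rec is None:
        comp = np.zeros(1, dtype=np.int64)
        rec_t = np.empty(1)
        rec_v = np.empty((1, 1))
        rec_ca = np.empty((1, 1))
        rec_i = np.empty((0, 0))
        record_currents = False
        record_every = n_steps + 1
    else:
        comp, rec_t, rec_v, rec_ca, rec_i, record_currents = rec

    bkspec = model.config.bk
    calc = model.config.calcium
    k_rec, t_end = run_kernel(
        n_steps, dt, record_every,
        model.gate_vhalf[:, 0], model.gate_slope[:, 0],
        model.gate_tau0[:, 0], model.gate_tauamp[:, 0],
        model.gate_tauvmid[:, 0], model.gate_tausigma[:, 0],
        model.gate_ca_kd_full, model.gate_ca_n_full,
        model.gmax[:, 0], model.erev[:, 0],
        model.act_idx, model.act_exp[:, 0].astype(np.int64),
        model.inact_idx, model.inact_exp[:, 0].astype(np.int64),
        model.is_ca_flags,
        model._bk_bind_mult, model._bk_unbind_vals,
        model._bk_alpha_base, model._bk_beta_base,
        model.bk_src.astype(np.int64), model.bk_dst.astype(np.int64),
        bkspec.za, bkspec.zb, bkspec.vslope, bkspec.kc4,
        bkspec.gmax, bkspec.erev, bkspec.include_o0,
        model.temp.tadj,
        model.config.leak_gmax, model.config.leak_erev,
        calc.depth * 1e-4, calc.baseline, calc.tau_removal, calc.floor,
        model.area_cm2, model.c_uf,
        stim_amp, stim_comp, clamp_cmd,
        syn_comp, syn_g, syn_e,
        model.cp_i.astype(np.int64), model.cp_j.astype(np.int64), model.cp_g,
        st.v, st.gates, st.bk, st.ca,
        comp.astype(np.int64), rec_t, rec_v, rec_ca, rec_i,
        record_currents,
    )
    if k_rec < 0:
        raise InstabilityError(
            f"voltage moved more than {5.0} mV in one step near t = {t_end:.3f} ms;"
            " reduce dt"
        )
    st.t = t0 + n_steps * dt
    return int(k_rec)


def run_current_clamp(
    protocol: StimulusProtocol, config: Optional[ModelConfig] = None, **kw
) -> SimulationTrace:
    if protocol.mode != "current_clamp":
        raise ValueError("protocol mode must be current_clamp")
    return run_protocol(protocol, config, **kw)


def run_synaptic(
    protocol: StimulusProtocol, config: Optional[ModelConfig] = None, **kw
) -> SimulationTrace:
    if protocol.mode != "synaptic":
        raise ValueError("protocol mode must be synaptic")
    return run_protocol(protocol, config, **kw)


@dataclass
class VoltageClampResult:
    """A voltage-clamp family: one trace per test potential."""

    test_potentials: np.ndarray
    traces: List[SimulationTrace]
    holding: float

    def step_window(self, i: int) -> Tuple[float, float]:
        seg = self.traces[i].metadata["segments"][0]
        return seg[0], seg[0] + seg[1]


def run_voltage_clamp(
    test_potentials: Sequence[float],
    config: Optional[ModelConfig] = None,
    holding: float = -90.0,
    step_start: float = 20.0,
    step_duration: float = 300.0,
    tail: float = 20.0,
    dt: Optional[float] = None,
    settle: float = 200.0,
) -> VoltageClampResult:
    """Run a family of voltage steps from a holding potential.

    The clamp is ideal (the command is followed exactly and no capacitive
    current flows); each trace records every channel's current density, from
    which I-V curves are built by peak or steady-state extraction.
    """
    config = config or default_config()
    traces = []
    for v_test in test_potentials:
        proto = StimulusProtocol(
            mode="voltage_clamp",
            holding=holding,
            segments=((step_start, step_duration, float(v_test)),),
            duration=step_start + step_duration + tail,
            settle=settle,
        )
        traces.append(run_protocol(proto, config, dt=dt))
    return VoltageClampResult(
        test_potentials=np.asarray(list(test_potentials), dtype=float),
        traces=traces,
        holding=holding,
    )


# ------------------------------------------------------------------ protocols
# The standard stimulation schedules used for model validation.


def standard_pulse_protocol(
    amplitude_nA: float = 0.1, duration_ms: float = 10.0, start: float = 20.0,
    total: float = 400.0, settle: float = 300.0,
) -> StimulusProtocol:
    """Brief rectangular current pulse (0.1 nA for 10 ms by default)."""
    return StimulusProtocol(
        mode="current_clamp",
        segments=((start, duration_ms, amplitude_nA),),
        duration=total,
        settle=settle,
    )


def long_pulse_protocol(
    amplitude_nA: float = 0.1, duration_ms: float = 100.0, start: float = 20.0,
    total: float = 400.0, settle: float = 300.0,
) -> StimulusProtocol:
    """Long rectangular current injection (0.1 nA for 100 ms by default)."""
    return standard_pulse_protocol(amplitude_nA, duration_ms, start, total, settle)


def standard_synaptic_protocol(
    gmax_uS: float = 0.0095, tau_rise: float = 15.0, tau_decay: float = 25.0,
    onset: float = 50.0, total: float = 500.0, e_syn: float = E_SYN,
    settle: float = 300.0,
) -> StimulusProtocol:
    """Biexponential synaptic drive (0.0095 uS, 15/25 ms by default)."""
    syn = SynapseSpec(
        model="biexp", gmax=gmax_uS, onset=onset,
        tau_rise=tau_rise, tau_decay=tau_decay, e_syn=e_syn,
    )
    return StimulusProtocol(
        mode="synaptic", synapses=(syn,), duration=total, settle=settle
    )
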