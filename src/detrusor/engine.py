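"""Vectorized fixed-step integrator for one or many coupled compartments.

The membrane equation per compartment is

    Cm dV/dt = I_inj + I_axial - I_ionic - I_syn

with injected depolarizing current defined positive (so a +0.1 nA pulse
depolarizes the cell).  Ionic current densities are in mA/cm2, absolute
currents in nA, conductances between compartments in uS, voltages in mV and
time in ms; with those units no further conversion constants are needed
beyond the 1e6 between (mA/cm2 * cm2) and nA.

Integration is forward Euler at a fixed dt (0.02 ms by default, matching the
solver the model was built around).  The Markov BK occupancies are advanced
with automatic sub-stepping so that no state's exit probability per substep
exceeds 0.1, which keeps occupancies in [0, 1] and conserves their sum to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bk import N_STATES, bk_stationary_occupancy, bk_transition_edges
from .calcium import FARADAY, ca_reversal
from .channels import TemperatureContext, katp_activation, sk_apamin_scaling
from .config import ModelConfig
from .synapse import SynapseSpec, syn_conductance

__all__ = ["CompartmentModel", "EngineState", "InstabilityError"]

#: abort if a single Euler step moves the voltage by more than this (mV)
MAX_DV_PER_STEP = 5.0


class InstabilityError(RuntimeError):
    """Raised when the fixed-step integration becomes numerically unstable."""


@dataclass
class EngineState:
    """Complete instantaneous state of every compartment."""

    v: np.ndarray  # (n,) mV
    gates: np.ndarray  # (n_gates + 1, n); last row pinned at 1
    bk: np.ndarray  # (10, n)
    ca: np.ndarray  # (n,) mM
    e_ca: np.ndarray  # (n,) mV
    t: float = 0.0

    def copy(self) -> "EngineState":
        return EngineState(
            self.v.copy(), self.gates.copy(), self.bk.copy(), self.ca.copy(),
            self.e_ca.copy(), self.t,
        )


class CompartmentModel:
    """A chain of isopotential compartments with the full channel complement.

    ``coupling`` lists (i, j, g_uS) conductances between compartment pairs;
    axial links and gap junctions are both represented this way.  A single
    cell is the n_comp = 1 special case with no coupling.
    """

    def __init__(
        self,
        config: ModelConfig,
        n_comp: int = 1,
        compartment_length_um: Optional[float] = None,
        coupling: Sequence[Tuple[int, int, float]] = (),
    ) -> None:
        config.validate()
        self.config = config
        self.n_comp = int(n_comp)
        geom = config.geometry
        self.comp_length_um = (
            geom.length if compartment_length_um is None else compartment_length_um
        )
        self.area_cm2 = np.pi * geom.diameter * self.comp_length_um * 1e-8
        self.c_uf = geom.cm * self.area_cm2
        self.temp = TemperatureContext(config.temperature)
        self.dt = config.solver.dt

        self._compile_channels()
        self._compile_coupling(coupling)

    # ------------------------------------------------------------------ setup

    def _compile_channels(self) -> None:
        cfg = self.config
        vh, sl, t0, am, vm, sg = [], [], [], [], [], []
        ca_kd, ca_n = [], []
        self.names: List[str] = []
        act_idx, act_exp, inact_idx, inact_exp = [], [], [], []
        gmax, erev, is_ca = [], [], []

        def add_gate(g):
            vh.append(g.half_potential)
            sl.append(g.slope)
            t0.append(g.tau.tau0)
            am.append(g.tau.amp)
            vm.append(g.tau.vmid)
            sg.append(g.tau.sigma)
            ca_kd.append(np.nan)
            ca_n.append(np.nan)
            return len(vh) - 1

        for ch in cfg.channels:
            self.names.append(ch.name)
            g_eff = ch.gmax
            if ch.ligand_dependence is not None:
                lig = ch.ligand_dependence
                if lig.kind == "atp_inhibition":
                    g_eff *= katp_activation(cfg.atp, ch)
                else:
                    g_eff *= sk_apamin_scaling(cfg.apamin, ch)
            gmax.append(g_eff)
            erev.append(ch.erev)
            is_ca.append(ch.is_calcium_carrier)
            i = add_gate(ch.activation)
            if ch.ca_dependence is not None:
                ca_kd[i] = ch.ca_dependence.kd
                ca_n[i] = ch.ca_dependence.n
            act_idx.append(i)
            act_exp.append(ch.activation.exponent)
            if ch.inactivation is not None:
                j = add_gate(ch.inactivation)
                inact_idx.append(j)
                inact_exp.append(ch.inactivation.exponent)
            else:
                inact_idx.append(-1)  # fixed-one row appended below
                inact_exp.append(0)

        self.n_gates = len(vh)
        self.gate_vhalf = np.asarray(vh)[:, None]
        self.gate_slope = np.asarray(sl)[:, None]
        self.gate_tau0 = np.asarray(t0)[:, None]
        self.gate_tauamp = np.asarray(am)[:, None]
        self.gate_tauvmid = np.asarray(vm)[:, None]
        self.gate_tausigma = np.asarray(sg)[:, None]
        self.gate_ca_kd_full = np.asarray(ca_kd)  # nan where not Ca-dependent
        self.gate_ca_n_full = np.asarray(ca_n)
        self.gate_ca_rows = np.array(
            [i for i, k in enumerate(ca_kd) if np.isfinite(k)], dtype=int
        )
        self.gate_ca_kd = np.asarray([k for k in ca_kd if np.isfinite(k)])[:, None]
        self.gate_ca_n = np.asarray(
            [n for n, k in zip(ca_n, ca_kd) if np.isfinite(k)]
        )[:, None]

        one_row = self.n_gates  # virtual always-one gate
        self.act_idx = np.asarray(act_idx)
        self.act_exp = np.asarray(act_exp)[:, None]
        self.inact_idx = np.asarray([one_row if j < 0 else j for j in inact_idx])
        self.inact_exp = np.asarray(inact_exp)[:, None]
        self.gmax = np.asarray(gmax)[:, None]
        self.erev = np.asarray(erev)[:, None]
        self.ca_rows = np.array([i for i, f in enumerate(is_ca) if f], dtype=int)
        self.is_ca_flags = np.asarray(is_ca, dtype=np.bool_)

        self.bk_src, self.bk_dst = bk_transition_edges()
        self._compile_bk_rate_templates()
        self.names.append("BK")
        self.names.append("Leak")

    def _compile_bk_rate_templates(self) -> None:
        """Constant parts of the 26 BK transition rates, for fast assembly."""
        spec = self.config.bk
        d = spec.allosteric_d
        # edge order (see bk.bk_transition_edges): closed-tier bind/unbind
        # pairs, open-tier bind/unbind pairs, then 5 vertical alpha/beta pairs
        self._bk_bind_rows = np.array([0, 2, 4, 6, 8, 10, 12, 14])
        self._bk_bind_mult = np.array([4.0, 3.0, 2.0, 1.0] * 2) * spec.kon
        self._bk_unbind_rows = np.array([1, 3, 5, 7, 9, 11, 13, 15])
        koff_c = spec.kon * spec.kd_closed
        koff_o = spec.kon * spec.kd_open
        self._bk_unbind_vals = np.concatenate(
            [np.arange(1, 5) * koff_c, np.arange(1, 5) * koff_o]
        )
        allo = spec.l0 * d ** np.arange(5)
        self._bk_alpha_rows = np.array([16, 18, 20, 22, 24])
        self._bk_beta_rows = np.array([17, 19, 21, 23, 25])
        self._bk_alpha_base = spec.a0 * allo**spec.forward_frac
        self._bk_beta_base = spec.a0 * allo ** (spec.forward_frac - 1.0)

    def _compile_coupling(self, coupling) -> None:
        if coupling:
            arr = np.asarray([(i, j, g) for i, j, g in coupling], dtype=float)
            self.cp_i = arr[:, 0].astype(int)
            self.cp_j = arr[:, 1].astype(int)
            self.cp_g = arr[:, 2]
            if np.any(self.cp_g < 0):
                raise ValueError("coupling conductances must be nonnegative")
        else:
            self.cp_i = np.zeros(0, dtype=int)
            self.cp_j = np.zeros(0, dtype=int)
            self.cp_g = np.zeros(0)

    # ------------------------------------------------------------- state init

    def init_state(self, v0: Optional[float] = None) -> EngineState:
        """Steady state at the initial voltage and baseline calcium."""
        cfg = self.config
        v = np.full(self.n_comp, cfg.v_init if v0 is None else v0, dtype=float)
        ca = np.full(self.n_comp, cfg.calcium.baseline)
        gates = np.ones((self.n_gates + 1, self.n_comp))
        gates[: self.n_gates] = self._gate_inf(v, ca)
        try:
            occ = bk_stationary_occupancy(float(v[0]), float(ca[0]), cfg.bk, self.temp)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"stationary BK occupancy solve failed at V={v[0]} mV, "
                f"ca={ca[0]} mM: {exc}"
            ) from exc
        bk = np.repeat(occ.p[:, None], self.n_comp, axis=1)
        e_ca = np.full(self.n_comp, cfg.calcium.e_ca_fixed)
        if cfg.calcium.dynamic_eca:
            e_ca[:] = ca_reversal(ca, cfg.calcium.ca_out, self.temp)
        return EngineState(v=v, gates=gates, bk=bk, ca=ca, e_ca=e_ca)

    # ----------------------------------------------------------- inner pieces

    def _gate_inf(self, v: np.ndarray, ca: np.ndarray) -> np.ndarray:
        minf = 1.0 / (1.0 + np.exp((v[None, :] + self.gate_vhalf) / self.gate_slope))
        if self.gate_ca_rows.size:
            c = ca[None, :]
            f = c**self.gate_ca_n / (c**self.gate_ca_n + self.gate_ca_kd**self.gate_ca_n)
            minf[self.gate_ca_rows] *= f
        return minf

    def _gate_tau(self, v: np.ndarray) -> np.ndarray:
        tau = self.gate_tau0 + self.gate_tauamp / np.cosh(
            (v[None, :] + self.gate_tauvmid) / self.gate_tausigma
        )
        return tau / self.temp.tadj

    def channel_current_densities(self, st: EngineState) -> np.ndarray:
        """Per-channel current densities (n_chan + 2, n) incl. BK and leak."""
        po = st.gates[self.act_idx] ** self.act_exp
        po = po * st.gates[self.inact_idx] ** self.inact_exp
        if self.config.calcium.dynamic_eca and self.ca_rows.size:
            erev = np.broadcast_to(self.erev, (len(self.gmax), self.n_comp)).copy()
            erev[self.ca_rows] = st.e_ca[None, :]
        else:
            erev = self.erev
        i_hh = self.gmax * po * (st.v[None, :] - erev)
        o_idx = [6, 7, 8, 9] + ([5] if self.config.bk.include_o0 else [])
        i_bk = self.config.bk.gmax * st.bk[o_idx].sum(axis=0) * (
            st.v - self.config.bk.erev
        )
        i_leak = self.config.leak_gmax * (st.v - self.config.leak_erev)
        return np.vstack([i_hh, i_bk[None, :], i_leak[None, :]])

    def _bk_rates(self, v: np.ndarray, ca: np.ndarray) -> np.ndarray:
        spec = self.config.bk
        n = v.shape[0]
        rates = np.empty((26, n))
        rates[self._bk_bind_rows] = self._bk_bind_mult[:, None] * ca[None, :]
        rates[self._bk_unbind_rows] = self._bk_unbind_vals[:, None]
        ea = np.exp(spec.za * v / spec.vslope)
        eb = np.exp(-spec.zb * v / spec.vslope)
        rates[self._bk_alpha_rows] = self._bk_alpha_base[:, None] * ea[None, :]
        rates[self._bk_beta_rows] = self._bk_beta_base[:, None] * eb[None, :]
        f4 = 0.5 + 0.5 * ca / (ca + spec.kc4)  # C4<->O4 depends on Ca too
        rates[24] *= f4
        rates[25] *= f4
        if self.temp.tadj != 1.0:
            rates *= self.temp.tadj
        return rates

    def _bk_step(self, st: EngineState, dt: float) -> None:
        rates = self._bk_rates(st.v, st.ca)
        if self.n_comp == 1:
            q = np.zeros((N_STATES, N_STATES))
            q[self.bk_dst, self.bk_src] = rates[:, 0]
            colsum = q.sum(axis=0)
            q[np.arange(N_STATES), np.arange(N_STATES)] = -colsum
            max_exit = float(colsum.max())
            n_sub = max(1, int(np.ceil(max_exit * dt / 0.1)))
            h = dt / n_sub
            p = st.bk[:, 0]
            for _ in range(n_sub):
                p = p + h * (q @ p)
            st.bk[:, 0] = p
            return
        q = np.zeros((N_STATES, N_STATES, self.n_comp))
        q[self.bk_dst, self.bk_src] = rates
        colsum = q.sum(axis=0)
        q[np.arange(N_STATES), np.arange(N_STATES)] = -colsum
        max_exit = float(colsum.max()) if colsum.size else 0.0
        n_sub = max(1, int(np.ceil(max_exit * dt / 0.1)))
        h = dt / n_sub
        p = st.bk
        for _ in range(n_sub):
            p = p + h * np.einsum("ijn,jn->in", q, p)
        st.bk = p

    def step(
        self,
        st: EngineState,
        dt: float,
        i_inj_nA: Optional[np.ndarray] = None,
        synapses: Sequence[SynapseSpec] = (),
        clamp_v: Optional[float] = None,
    ) -> np.ndarray:
        """Advance all states by one step; returns the per-channel densities.

        If ``clamp_v`` is given the membrane voltage follows the command
        (ideal clamp; the capacitive current is excluded by construction)
        while gates, BK occupancies and calcium evolve freely.
        """
        i_chan = self.channel_current_densities(st)

        # gating
        minf = self._gate_inf(st.v, st.ca)
        tau = self._gate_tau(st.v)
        g = st.gates[: self.n_gates]
        np.clip(g + dt * (minf - g) / tau, 0.0, 1.0, out=g)
        self._bk_step(st, dt)

        # calcium shell
        spec_ca = self.config.calcium
        i_ca = i_chan[self.ca_rows].sum(axis=0) if self.ca_rows.size else 0.0
        depth_cm = spec_ca.depth * 1e-4
        dca = -i_ca / (2.0 * FARADAY * depth_cm) - (
            st.ca - spec_ca.baseline
        ) / spec_ca.tau_removal
        st.ca = np.maximum(st.ca + dt * dca, spec_ca.floor)
        if spec_ca.dynamic_eca:
            st.e_ca = ca_reversal(st.ca, spec_ca.ca_out, self.temp)

        # membrane potential
        if clamp_v is not None:
            st.v = np.full(self.n_comp, clamp_v, dtype=float)
        else:
            i_mem_nA = i_chan.sum(axis=0) * self.area_cm2 * 1e6
            i_total = -i_mem_nA
            if i_inj_nA is not None:
                i_total = i_total + i_inj_nA
            for syn in synapses:
                g_syn = syn_conductance(st.t, syn)
                if g_syn > 0.0:
                    i_total[syn.compartment] -= g_syn * (
                        st.v[syn.compartment] - syn.e_syn
                    )
            if self.cp_g.size:
                dv_pair = st.v[self.cp_j] - st.v[self.cp_i]
                flow = self.cp_g * dv_pair
                np.add.at(i_total, self.cp_i, flow)
                np.add.at(i_total, self.cp_j, -flow)
            dv = dt * 1e-3 * i_total / self.c_uf
            if np.max(np.abs(dv)) > MAX_DV_PER_STEP:
                raise InstabilityError(
                    f"|dV| = {np.max(np.abs(dv)):.2f} mV in one step at "
                    f"t = {st.t:.3f} ms; reduce dt"
                )
            st.v = st.v + dv
        st.t += dt
        return i_chan
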