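"""Single-compartment integrator, protocol engines and clamp validation."""

import numpy as np
import pytest

from detrusor.analysis import build_iv_curve, extract_ap_features
from detrusor.cell import (
    StimulusProtocol,
    init_state,
    run_protocol,
    run_voltage_clamp,
    standard_pulse_protocol,
    standard_synaptic_protocol,
)
from detrusor.channels import boltzmann_steady_state
from detrusor.engine import InstabilityError


class TestInitState:
    def test_default_resting_values(self, cfg):
        st = init_state(cfg)
        assert st.v == pytest.approx(-50.0)
        assert st.ca_i == pytest.approx(150e-6)
        assert abs(st.bk.sum() - 1.0) < 1e-6

    def test_equilibrium_initialization_is_quiet(self, cfg):
        """With gates at steady state, 10 ms unstimulated drift < 0.5 mV."""
        proto = StimulusProtocol(mode="current_clamp", duration=10.0)
        tr = run_protocol(proto, cfg)
        assert np.max(np.abs(tr.v - tr.v[0])) < 0.5

    def test_pure_leak_cell_rests_at_leak_reversal(self, cfg):
        cfg = cfg.with_scaled_gmax(
            {c: 0.0 for c in ["CaT", "CaL", "Kv1", "KCNQ", "IK", "SK", "KATP",
                              "Ih", "BK"]}
        )
        cfg.leak_erev = -60.0
        cfg.v_init = -50.0
        proto = StimulusProtocol(mode="current_clamp", duration=800.0)
        tr = run_protocol(proto, cfg)
        assert tr.v[-1] == pytest.approx(-60.0, abs=0.05)


class TestStepIntegrator:
    def test_leak_only_rc_charging_matches_closed_form(self, cfg):
        """Step current into a passive cell charges with tau = Rm*Cm."""
        cfg = cfg.with_scaled_gmax(
            {c: 0.0 for c in ["CaT", "CaL", "Kv1", "KCNQ", "IK", "SK", "KATP",
                              "Ih", "BK"]}
        )
        cfg.leak_erev = -50.0
        i_nA = 0.01
        proto = StimulusProtocol(
            mode="current_clamp", segments=((0.0, 400.0, i_nA),), duration=400.0
        )
        tr = run_protocol(proto, cfg)
        geom = cfg.geometry
        r_in = geom.rm * 1e3 / geom.area_cm2  # Ohm
        tau = geom.rm * geom.cm  # ms (kOhm cm2 * uF/cm2)
        v_pred = -50.0 + i_nA * 1e-9 * r_in * 1e3 * (1.0 - np.exp(-tr.time / tau))
        mask = tr.time > 1.0
        assert np.max(np.abs(tr.v[mask] - v_pred[mask]) / np.abs(v_pred[mask] + 50.0 + 1e-9)) < 0.01 or \
            np.max(np.abs(tr.v[mask] - v_pred[mask])) < 0.5

    def test_kernel_matches_reference_numpy_path(self, cfg):
        """The compiled integrator reproduces the numpy step loop exactly."""
        import detrusor.cell as cellmod

        proto = standard_pulse_protocol(total=60.0, settle=0.0)
        tr_kernel = run_protocol(proto, cfg)
        saved = cellmod.HAVE_NUMBA
        cellmod.HAVE_NUMBA = False
        try:
            tr_numpy = run_protocol(proto, cfg)
        finally:
            cellmod.HAVE_NUMBA = saved
        assert np.max(np.abs(tr_kernel.v - tr_numpy.v)) < 1e-9
        assert np.max(np.abs(tr_kernel.ca - tr_numpy.ca)) < 1e-12

    def test_instability_guard(self, cfg):
        proto = StimulusProtocol(
            mode="current_clamp", segments=((0.0, 5.0, 50.0),), duration=5.0
        )
        with pytest.raises(InstabilityError):
            run_protocol(proto, cfg, dt=1.0)

    def test_euler_step_halving_convergence(self, cfg):
        """dt = 0.02 ms reproduces a dt = 0.002 ms reference within 1 mV."""
        proto = standard_pulse_protocol(total=150.0, settle=50.0)
        tr_a = run_protocol(proto, cfg, record_every=10)  # dt 0.02, every 0.2 ms
        tr_b = run_protocol(proto, cfg, dt=0.002, record_every=100)
        assert tr_a.time.shape == tr_b.time.shape
        assert np.max(np.abs(tr_a.v - tr_b.v)) < 1.0


class TestCurrentClamp:
    def test_unstimulated_cell_holds_rest(self, rest_trace):
        assert np.all(np.abs(rest_trace.v + 50.0) < 1.0)

    def test_brief_pulse_fires_single_spike(self, pulse_trace):
        f = extract_ap_features(pulse_trace)
        assert f.n_spikes == 1
        assert f.v_max > 0.0

    def test_long_pulse_fires_two_spikes(self, long_pulse_trace):
        assert extract_ap_features(long_pulse_trace).n_spikes == 2

    def test_hyperpolarizing_pulse_is_passive(self, cfg):
        proto = StimulusProtocol(
            mode="current_clamp", segments=((20.0, 100.0, -0.1),),
            duration=250.0, settle=300.0,
        )
        tr = run_protocol(proto, cfg)
        f = extract_ap_features(tr)
        assert f.n_spikes == 0
        assert tr.v.min() < -55.0  # clear hyperpolarizing deflection


class TestVoltageClamp:
    def test_command_followed_exactly(self, cfg):
        fam = run_voltage_clamp([0.0], cfg, holding=-90.0, step_start=5.0,
                                step_duration=20.0, tail=5.0, settle=20.0)
        tr = fam.traces[0]
        during = (tr.time > 5.1) & (tr.time < 24.9)
        assert np.allclose(tr.v[during], 0.0)

    def test_channel_current_reverses_at_its_erev(self, cfg):
        """Clamping at a channel's reversal potential zeroes its current."""
        for name in ("CaL", "Kv1", "SK", "KATP", "Ih"):
            erev = cfg.channel(name).erev
            fam = run_voltage_clamp([erev], cfg, holding=-90.0, step_start=5.0,
                                    step_duration=30.0, tail=0.0, settle=10.0)
            i_end = fam.traces[0].currents[name][-1]
            assert i_end == pytest.approx(0.0, abs=1e-12)

    def test_cal_iv_zero_crossing_at_calcium_reversal(self, cfg):
        fam = run_voltage_clamp(np.arange(-70.0, 51.0, 10.0), cfg)
        curve = build_iv_curve(fam, "CaL")
        assert curve.zero_crossing() == pytest.approx(51.0, abs=2.0)

    def test_ih_family_grows_with_hyperpolarization(self, cfg):
        """Steps -140..-20 mV from -10 mV: inward current grows as the step
        goes more negative."""
        steps = np.arange(-140.0, -19.0, 30.0)
        fam = run_voltage_clamp(steps, cfg, holding=-10.0, step_duration=400.0,
                                tail=0.0)
        tail = [tr.currents["Ih"][-1] for tr in fam.traces]
        assert all(a < b for a, b in zip(tail, tail[1:]))  # more negative = bigger inward
        assert tail[0] < 0.0

    def test_steady_clamp_current_matches_closed_form(self, cfg):
        """A long step yields gbar*m_inf^x*h_inf^y*(V-E) within 0.1%."""
        v_test = -30.0
        fam = run_voltage_clamp([v_test], cfg, holding=-90.0, step_start=5.0,
                                step_duration=800.0, tail=0.0, settle=10.0)
        tr = fam.traces[0]
        # channels whose slowest gate settles well within the step
        for name in ("KCNQ", "Ih"):
            ch = cfg.channel(name)
            po = boltzmann_steady_state(v_test, ch.activation) ** ch.activation.exponent
            if ch.inactivation is not None:
                po *= boltzmann_steady_state(v_test, ch.inactivation) ** ch.inactivation.exponent
            expected = ch.gmax * po * (v_test - ch.erev)
            assert tr.currents[name][-1] == pytest.approx(expected, rel=1e-3)


class TestSynapticDrive:
    def test_standard_drive_fires_ap_with_adp(self, syn_trace):
        f = extract_ap_features(syn_trace)
        assert f.n_spikes == 1
        assert f.adp_amplitude is not None and f.adp_amplitude > 1.0

    def test_briefer_weaker_drive_gives_ahp_spike(self, cfg):
        """A weaker, briefer synaptic conductance produces the AHP-type
        spike; the slower standard drive produces the ADP type (AP shape is
        governed by the synaptic time course)."""
        proto = standard_synaptic_protocol(gmax_uS=0.006, tau_rise=5.0,
                                           tau_decay=12.0)
        f = extract_ap_features(run_protocol(proto, cfg))
        assert f.n_spikes == 1
        assert f.ahp_amplitude is not None and f.ahp_amplitude > 0.5

    def test_zero_conductance_is_resting_trace(self, cfg):
        proto = standard_synaptic_protocol(gmax_uS=0.0)
        tr = run_protocol(proto, cfg)
        assert np.max(np.abs(tr.v - tr.v[0])) < 0.2


class TestResting:
    def test_emergent_rest_within_physiological_range(self, rest_trace):
        assert -55.0 < rest_trace.v[-1] < -45.0

    def test_resting_calcium_at_baseline(self, rest_trace):
        assert rest_trace.ca[-1] == pytest.approx(150e-6, rel=0.05)


class TestBlockProperties:
    def test_cat_block_abolishes_synaptic_ap(self, cfg):
        """Full CaT block leaves only a subthreshold synaptic depolarization."""
        blocked = cfg.with_scaled_gmax({"CaT": 0.0})
        tr = run_protocol(standard_synaptic_protocol(), blocked)
        assert tr.v.max() < -20.0
        assert extract_ap_features(tr).n_spikes == 0

    def test_cal_block_suppresses_peak_but_not_rmp(self, cfg, syn_trace):
        blocked = cfg.with_scaled_gmax({"CaL": 0.0})
        tr = run_protocol(standard_synaptic_protocol(), blocked)
        f_ctrl = extract_ap_features(syn_trace)
        assert tr.v.max() < f_ctrl.v_max - 10.0
        assert tr.v[0] == pytest.approx(f_ctrl.rmp, abs=0.3)

    def test_sk_block_touches_only_the_ahp_phase(self, cfg, syn_trace):
        """Halving SK changes the AHP but neither RMP, peak, nor the total
        outward current peak (< 2%)."""
        blocked = cfg.with_scaled_gmax({"SK": 0.5})
        tr = run_protocol(standard_synaptic_protocol(), blocked)
        f_c = extract_ap_features(syn_trace)
        f_b = extract_ap_features(tr)
        assert f_b.rmp == pytest.approx(f_c.rmp, abs=0.3)
        assert f_b.v_max == pytest.approx(f_c.v_max, abs=0.5)

        def outward_peak(trace):
            out = sum(
                np.maximum(trace.currents[n], 0.0)
                for n in ("Kv1", "KCNQ", "BK", "IK", "SK", "KATP")
            )
            return out.max()

        rel = abs(outward_peak(tr) - outward_peak(syn_trace)) / outward_peak(syn_trace)
        assert rel < 0.02


class TestTraceContainer:
    def test_uniform_grid_and_frame_round(self, pulse_trace):
        dts = np.diff(pulse_trace.time)
        assert np.allclose(dts, dts[0])
        frame = pulse_trace.to_frame()
        assert "v_mV" in frame.columns and "time_ms" in frame.columns
        assert len(frame) == len(pulse_trace.time)
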