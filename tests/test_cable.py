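"""1-D cable and gap-junction strand propagation."""

import numpy as np
import pytest

import detrusor as d
from detrusor.analysis import extract_ap_features
from detrusor.cable import (
    CableSpec,
    GapJunction,
    RecordingSite,
    build_cable,
    build_strand,
    cable_diagnostics,
    cable_synaptic_protocol,
    foot_curvature,
    propagate,
)
from detrusor.cell import StimulusProtocol, run_protocol
from detrusor.config import CellGeometry


def passive_config():
    cfg = d.default_config().with_scaled_gmax(
        {c: 0.0 for c in ["CaT", "CaL", "Kv1", "KCNQ", "IK", "SK", "KATP", "Ih", "BK"]}
    )
    geom = CellGeometry(rm=10.0)  # compact lambda (~0.9 mm) and tau (10 ms)
    cfg.geometry = geom
    cfg.leak_gmax = 1.0 / (geom.rm * 1e3)
    cfg.leak_erev = -50.0
    return cfg, geom


@pytest.fixture(scope="module")
def active_cable_traces():
    """One propagating spike on the standard 22.2 mm / 111-compartment cable."""
    cfg = d.default_config()
    model = build_cable(CableSpec(), cfg)
    sites = [RecordingSite("R0", 11.1), RecordingSite("R1", 15.5),
             RecordingSite("R2", 19.9)]
    proto = cable_synaptic_protocol(model)
    return propagate(model, proto, sites)


class TestBuildCable:
    def test_standard_compartmentalization(self):
        spec = CableSpec()
        assert spec.compartment_length_mm == pytest.approx(0.2)
        model = build_cable(spec)
        assert model.n_comp == 111
        assert model.comp_length_um == pytest.approx(200.0)

    def test_too_few_compartments_rejected(self):
        with pytest.raises(ValueError):
            CableSpec(n_compartments=2)

    def test_coarse_discretization_warns(self):
        with pytest.warns(UserWarning):
            build_cable(CableSpec(total_length_mm=22.2, n_compartments=10))

    def test_equal_voltages_mean_zero_axial_current(self):
        cfg, _ = passive_config()
        model = build_cable(CableSpec(total_length_mm=1.0, n_compartments=5,
                                      geometry=cfg.geometry), cfg)
        st = model.init_state(v0=-50.0)
        v_before = st.v.copy()
        model.step(st, 0.02)
        assert np.allclose(st.v, v_before[0], atol=1e-9)

    def test_passive_steady_profile_matches_exponential_decay(self):
        """Steady point current at the midpoint decays as exp(-x/lambda)
        within 2% for x in [lambda, 4*lambda]."""
        cfg, geom = passive_config()
        lam = geom.space_constant_mm
        n = 120
        spec = CableSpec(total_length_mm=12.0, n_compartments=n, geometry=geom)
        model = build_cable(spec, cfg)
        mid = n // 2
        proto = StimulusProtocol(mode="current_clamp",
                                 segments=((0.0, 120.0, 0.05),),
                                 duration=120.0, compartment=mid)
        tr = run_protocol(proto, model=model, record_comps=list(range(n)),
                          record_currents=False)
        profile = tr.v[-1] - (-50.0)
        x = (np.arange(n) + 0.5) * spec.compartment_length_mm
        dist = x - x[mid]
        mask = (dist >= lam) & (dist <= 4 * lam)
        predicted = profile[mid] * np.exp(-dist[mask] / lam)
        rel_err = np.abs(profile[mask] - predicted) / predicted
        assert rel_err.max() < 0.02

    def test_diagnostics_report_both_space_constants(self):
        diag = cable_diagnostics(CableSpec())
        assert diag["lambda_ref_mm"] == pytest.approx(1.8)
        assert diag["lambda_from_geometry_mm"] == pytest.approx(3.36, abs=0.05)


class TestStrand:
    def test_infinite_rj_isolates_cells(self):
        cfg, _ = passive_config()
        model = build_strand(n_cells=2, rj_mohm=float("inf"),
                             per_cell_compartments=5, config=cfg)
        proto = StimulusProtocol(mode="current_clamp",
                                 segments=((0.0, 50.0, 0.05),),
                                 duration=50.0, compartment=0)
        tr = run_protocol(proto, model=model, record_comps=[0, 5],
                          record_currents=False)
        assert tr.v[-1, 0] > -48.5  # stimulated cell depolarized
        assert abs(tr.v[-1, 1] + 50.0) < 1e-6  # neighbour untouched

    def test_gap_junction_conductance(self):
        gj = GapJunction(30.0, ((0, 50), (1, 0)))
        assert gj.conductance_uS == pytest.approx(1.0 / 30.0)
        with pytest.raises(ValueError):
            GapJunction(0.0, ((0, 0), (1, 0)))

    def test_equal_voltages_zero_junctional_current(self):
        cfg, _ = passive_config()
        model = build_strand(n_cells=2, rj_mohm=30.0, per_cell_compartments=4,
                             config=cfg)
        st = model.init_state(v0=-50.0)
        model.step(st, 0.02)
        assert np.allclose(st.v, -50.0, atol=1e-9)

    def test_latency_grows_with_rj_and_propagation_can_fail(self):
        """Raising r_j delays the neighbour's spike; high enough r_j blocks."""
        cfg = d.default_config()

        def neighbour_spike_time(rj):
            model = build_strand(n_cells=2, rj_mohm=rj,
                                 per_cell_compartments=21, config=cfg)
            proto = cable_synaptic_protocol(model, position_mm=2.1,
                                            gmax_uS=0.07, total=500.0)
            tr = run_protocol(proto, model=model, record_comps=[31],
                              record_currents=False, record_every=5)
            above = np.nonzero(tr.v > -25.0)[0]
            return tr.time[above[0]] if above.size else None

        t10 = neighbour_spike_time(10.0)
        t40 = neighbour_spike_time(40.0)
        t80 = neighbour_spike_time(80.0)
        assert t10 is not None and t40 is not None and t80 is not None
        assert t10 < t40 < t80
        assert neighbour_spike_time(200.0) is None


class TestPropagation:
    def test_propagated_peaks_not_below_evoked_peak(self, active_cable_traces):
        tr = active_cable_traces
        assert tr["R1"].v.max() >= tr["R0"].v.max()
        assert tr["R2"].v.max() >= tr["R0"].v.max()

    def test_conduction_delay_increases_with_distance(self, active_cable_traces):
        tr = active_cable_traces
        t_peak = {k: v.time[np.argmax(v.v)] for k, v in tr.items()}
        assert t_peak["R0"] < t_peak["R1"] < t_peak["R2"]

    def test_adp_present_at_stimulus_site_only(self, active_cable_traces):
        tr = active_cable_traces
        f0 = extract_ap_features(tr["R0"])
        f2 = extract_ap_features(tr["R2"])
        assert f0.adp_amplitude is not None and f0.adp_amplitude > 2.0
        assert f2.adp_amplitude is None or f2.adp_amplitude < 0.2 * f0.adp_amplitude

    def test_foot_transforms_from_convex_to_concave(self, active_cable_traces):
        tr = active_cable_traces
        assert foot_curvature(tr["R0"]) < 0.0  # convex-upward at the stimulus
        assert foot_curvature(tr["R2"]) > 0.0  # concave-upward when propagated

    def test_subthreshold_stimulus_spreads_passively(self):
        """A weak stimulus attenuates like exp(-x/lambda) instead of
        propagating."""
        cfg, geom = passive_config()
        lam = geom.space_constant_mm
        n = 120
        spec = CableSpec(total_length_mm=12.0, n_compartments=n, geometry=geom)
        model = build_cable(spec, cfg)
        proto = StimulusProtocol(mode="current_clamp",
                                 segments=((0.0, 120.0, 0.02),),
                                 duration=120.0, compartment=n // 2)
        tr = run_protocol(proto, model=model,
                          record_comps=[n // 2, n // 2 + int(2 * lam / 0.1)],
                          record_currents=False)
        amp0 = tr.v[-1, 0] + 50.0
        amp2 = tr.v[-1, 1] + 50.0
        assert amp2 / amp0 == pytest.approx(np.exp(-2.0), rel=0.1)


class TestChargeConservation:
    def test_node_currents_sum_to_capacitive_current(self):
        """Axial + junctional + membrane + stimulus = Cm dV/dt at a node."""
        cfg = d.default_config()
        model = build_strand(n_cells=2, rj_mohm=30.0, per_cell_compartments=3,
                             config=cfg)
        st = model.init_state()
        st.v += np.linspace(0.0, 5.0, model.n_comp)  # force axial flow
        i_chan = model.channel_current_densities(st)
        v_before = st.v.copy()
        dt = 0.02
        model.step(st, dt)
        dv = st.v - v_before
        # reconstruct the expected update for node 2 (last node of cell 0)
        node = 2
        i_mem = -i_chan[:, node].sum() * model.area_cm2 * 1e6  # nA
        i_ax = 0.0
        for i, j, g in zip(model.cp_i, model.cp_j, model.cp_g):
            if i == node:
                i_ax += g * (v_before[j] - v_before[i])
            elif j == node:
                i_ax += g * (v_before[i] - v_before[j])
        expected_dv = dt * 1e-3 * (i_mem + i_ax) / model.c_uf
        assert dv[node] == pytest.approx(expected_dv, rel=1e-9, abs=1e-12)
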