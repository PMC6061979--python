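"""AP feature extraction, I-V curves, fit scoring, sweeps and blocks."""

import numpy as np
import pytest

from detrusor.analysis import (
    IVCurve,
    block_experiment,
    build_iv_curve,
    conductance_sweep,
    extract_ap_features,
    fit_score,
)
from detrusor.cell import SimulationTrace, run_voltage_clamp


def make_trace(t, v, stim_start=None):
    meta = {"stim_start": stim_start} if stim_start is not None else {}
    return SimulationTrace(time=np.asarray(t, float), v=np.asarray(v, float),
                           metadata=meta)


def triangle_trace(rmp=-50.0, peak=0.0, rise=10.0, fall=10.0, dt=0.01):
    """Triangular spike from rmp to peak: baseline, ramp up, ramp down."""
    t_base = np.arange(0.0, 20.0, dt)
    t_up = np.arange(0.0, rise, dt)
    t_dn = np.arange(0.0, fall, dt)
    t_tail = np.arange(0.0, 30.0, dt)
    v = np.concatenate([
        np.full_like(t_base, rmp),
        rmp + (peak - rmp) * t_up / rise,
        peak - (peak - rmp) * t_dn / fall,
        np.full_like(t_tail, rmp),
    ])
    t = dt * np.arange(len(v))
    return make_trace(t, v, stim_start=20.0)


class TestAPFeatures:
    def test_flat_trace_has_no_spikes(self):
        tr = make_trace(np.arange(0, 100, 0.1), np.full(1000, -50.0))
        f = extract_ap_features(tr)
        assert f.n_spikes == 0
        assert f.rmp == pytest.approx(-50.0)
        assert f.v_max is None

    def test_triangle_geometry(self):
        """50 mV triangle with 10 ms rise and fall: APA 50, APD50 10 ms."""
        f = extract_ap_features(triangle_trace())
        assert f.n_spikes == 1
        assert f.apa == pytest.approx(50.0, abs=0.1)
        assert f.apd50 == pytest.approx(10.0, abs=0.1)
        assert f.width_at_level == pytest.approx(10.0, abs=0.1)  # -25 is half here

    def test_invariant_to_time_shift(self):
        tr = triangle_trace()
        shifted = SimulationTrace(time=tr.time + 123.0, v=tr.v.copy(),
                                  metadata={"stim_start": 143.0})
        f0, f1 = extract_ap_features(tr), extract_ap_features(shifted)
        assert f1.apa == pytest.approx(f0.apa)
        assert f1.apd50 == pytest.approx(f0.apd50, abs=0.02)

    def test_invariant_to_twofold_resampling(self):
        tr = triangle_trace()
        coarse = SimulationTrace(time=tr.time[::2], v=tr.v[::2],
                                 metadata=dict(tr.metadata))
        f0, f1 = extract_ap_features(tr), extract_ap_features(coarse)
        assert f1.apa == pytest.approx(f0.apa, abs=0.1)
        assert f1.apd50 == pytest.approx(f0.apd50, abs=0.1)

    def test_nonuniform_grid_rejected(self):
        t = np.concatenate([np.arange(0, 10, 0.1), np.arange(10, 20, 0.2)])
        with pytest.raises(ValueError):
            extract_ap_features(make_trace(t, np.full_like(t, -50.0)))

    def test_ahp_measured_below_rmp(self):
        dt = 0.02
        t = np.arange(0.0, 120.0, dt)
        v = np.full_like(t, -50.0)
        spike = (t >= 20.0) & (t < 40.0)
        v[spike] = -50.0 + 55.0 * np.sin(np.pi * (t[spike] - 20.0) / 20.0)
        dip = (t >= 40.0) & (t < 70.0)
        v[dip] = -50.0 - 5.0 * np.exp(-(t[dip] - 45.0) ** 2 / 20.0)
        f = extract_ap_features(make_trace(t, v, stim_start=20.0))
        assert f.ahp_amplitude == pytest.approx(5.0, abs=0.2)
        assert f.ahp_duration is not None and 0.0 < f.ahp_duration < 30.0


class TestIVCurve:
    def test_normalization_maps_peak_to_unit(self, cfg_session):
        fam = run_voltage_clamp(np.arange(-70.0, 51.0, 20.0), cfg_session)
        curve = build_iv_curve(fam, "CaL")
        assert np.max(np.abs(curve.normalized)) == pytest.approx(1.0)
        assert np.sum(np.abs(np.abs(curve.normalized) - 1.0) < 1e-12) == 1

    def test_ohmic_conductance_gives_straight_line(self):
        """A synthetic linear conductance produces a line through its E_rev."""
        v = np.arange(-80.0, 41.0, 20.0)
        i = 2e-3 * (v + 30.0)
        curve = IVCurve(voltages=v, currents=i, normalized=i / np.max(np.abs(i)),
                        channel="ohmic", extraction="steady")
        assert curve.zero_crossing() == pytest.approx(-30.0)
        slopes = np.diff(i) / np.diff(v)
        assert np.allclose(slopes, slopes[0])

    def test_requires_three_steps(self, cfg_session):
        fam = run_voltage_clamp([-30.0, 0.0], cfg_session, step_duration=50.0,
                                settle=20.0)
        with pytest.raises(ValueError):
            build_iv_curve(fam, "CaL")


class TestFitScore:
    def test_perfect_fit(self):
        y = np.linspace(0.0, 1.0, 20)
        score = fit_score(y, y)
        assert score.s == 0.0
        assert score.is_good

    def test_constant_offset_algebra(self):
        """With K = 0 a constant offset c yields S = c exactly."""
        y = np.linspace(0.0, 10.0, 25)
        score = fit_score(y + 0.07, y, k=0)
        assert score.s == pytest.approx(0.07, rel=1e-12)

    def test_boundary_of_five_percent_rule_is_strict(self):
        y = np.linspace(0.0, 1.0, 50)
        offset = 0.05 * (y.max() - y.min())
        assert not fit_score(y + offset, y).is_good

    def test_brute_force_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 60)
            k = int(rng.integers(0, n - 1))
            a, b = rng.normal(size=n), rng.normal(size=n)
            expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / (n - k))
            assert fit_score(a, b, k).s == pytest.approx(expected, rel=1e-12)

    def test_n_must_exceed_k(self):
        with pytest.raises(ValueError):
            fit_score([1.0, 2.0], [1.0, 2.0], k=2)


@pytest.fixture(scope="module")
def sweep_table(cfg_session):
    return conductance_sweep(cfg_session, channels=("CaL", "BK"), steps=5)


class TestSweep:

    def test_ap_generated_at_every_grid_point(self, sweep_table):
        assert sweep_table["ap_generated"].all()

    def test_peak_monotone_in_cal(self, sweep_table):
        peaks = sweep_table[sweep_table.channel == "CaL"].sort_values("factor")["v_max"]
        assert (np.diff(peaks.to_numpy()) >= 0).all()

    def test_peak_monotone_in_bk(self, sweep_table):
        peaks = sweep_table[sweep_table.channel == "BK"].sort_values("factor")["v_max"]
        assert (np.diff(peaks.to_numpy()) <= 0).all()

    def test_unperturbed_row_matches_control(self, sweep_table, cfg_session, syn_trace):
        row = sweep_table[(sweep_table.channel == "CaL")
                          & (np.isclose(sweep_table.factor, 1.0))].iloc[0]
        f_ctrl = extract_ap_features(syn_trace)
        assert row["v_max"] == pytest.approx(f_ctrl.v_max, abs=1e-9)

    def test_simultaneous_rows_present(self, sweep_table):
        assert (sweep_table.channel == "all").sum() == 5

    def test_range_guard(self, cfg_session):
        with pytest.raises(ValueError):
            conductance_sweep(cfg_session, rel_range=0.9)


class TestBlockExperiment:
    def test_reports_paired_traces_and_deltas(self, cfg_session):
        res = block_experiment(cfg_session, ("SK",), 0.5)
        assert set(res["deltas"]) == {"d_rmp", "d_v_max", "d_apd50",
                                      "d_ahp_amplitude"}
        assert res["control"]["features"].n_spikes == 1

    def test_fraction_bounds(self, cfg_session):
        with pytest.raises(ValueError):
            block_experiment(cfg_session, ("SK",), 1.5)
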