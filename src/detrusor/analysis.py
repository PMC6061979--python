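"""Action-potential morphology, I-V curves, goodness of fit and sweeps.

Feature definitions
-------------------
RMP        mean voltage over the pre-stimulus baseline window.
threshold  voltage at the maximum of d2V/dt2 on the upstroke; a 10 mV/ms
           dV/dt crossing is reported alongside as a fallback definition.
APA        absolute peak minus RMP.
APD50      duration at 50% repolarization, i.e. width at RMP + APA/2.
width      duration at a stated absolute level (default -25 mV).
AHP        depth of the post-spike minimum below RMP, and the time spent
           below RMP around that minimum.
ADP        amplitude above RMP of an interior local maximum on the late
           repolarization (absent when repolarization is monotonic).

The goodness-of-fit statistic is the standard error of regression

    S = sqrt( sum (y_exp - y_sim)^2 / (N - K) )

with K fitted parameters; a fit is good when S is below 5% of the range of
the experimental data (strict inequality).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cell import (
    SimulationTrace,
    StimulusProtocol,
    VoltageClampResult,
    run_protocol,
    standard_synaptic_protocol,
)
from .config import ModelConfig, default_config

__all__ = [
    "APFeatures",
    "IVCurve",
    "FitScore",
    "extract_ap_features",
    "build_iv_curve",
    "fit_score",
    "conductance_sweep",
    "block_experiment",
    "PEAK_CHANNELS",
]

#: channels whose I-V point is the per-step peak (inactivating currents);
#: all others are read at the end of the step (sustained currents)
PEAK_CHANNELS = ("CaL", "CaT", "Kv1")


@dataclass
class APFeatures:
    """Extracted spike morphology; spike-dependent fields are None when no
    spike is found."""

    rmp: float
    n_spikes: int
    v_max: Optional[float] = None
    apa: Optional[float] = None
    apd50: Optional[float] = None
    width_at_level: Optional[float] = None
    level: float = -25.0
    ahp_amplitude: Optional[float] = None
    ahp_duration: Optional[float] = None
    adp_amplitude: Optional[float] = None
    threshold: Optional[float] = None
    threshold_dvdt: Optional[float] = None
    time_to_peak: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return dataclasses.asdict(self)


def _crossings(t: np.ndarray, v: np.ndarray, level: float) -> Tuple[np.ndarray, np.ndarray]:
    """Interpolated times of upward and downward crossings of ``level``."""
    above = v >= level
    idx_up = np.nonzero(~above[:-1] & above[1:])[0]
    idx_dn = np.nonzero(above[:-1] & ~above[1:])[0]

    def interp(idx):
        frac = (level - v[idx]) / (v[idx + 1] - v[idx])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return interp(idx_up), interp(idx_dn)


def extract_ap_features(
    trace: SimulationTrace,
    detect_level: float = -25.0,
    width_level: float = -25.0,
    baseline_window: Optional[Tuple[float, float]] = None,
) -> APFeatures:
    """Extract spike morphology from a single-site trace.

    Spikes are upward excursions through ``detect_level``; all shape
    features are measured on the first spike.  The trace must be on a
    uniform time grid.
    """
    t = np.asarray(trace.time, dtype=float)
    v = np.asarray(trace.v, dtype=float)
    if v.ndim != 1:
        raise ValueError("feature extraction needs a single-site trace")
    dts = np.diff(t)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be on a uniform time grid")

    stim_start = trace.metadata.get("stim_start")
    if baseline_window is None:
        end = stim_start if stim_start is not None else t[0] + 0.05 * (t[-1] - t[0])
        baseline_window = (t[0], max(end, t[0] + trace.dt))
    mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    rmp = float(np.mean(v[mask])) if mask.any() else float(v[0])

    t_up, t_dn = _crossings(t, v, detect_level)
    n_spikes = int(len(t_up))
    if n_spikes == 0:
        return APFeatures(rmp=rmp, n_spikes=0, level=width_level)

    # window of the first spike: from its upward crossing to the next
    # upward crossing (or the end of the trace)
    t0 = t_up[0]
    t_end = t_up[1] if n_spikes > 1 else t[-1]
    win = (t >= t0) & (t < t_end)
    i_peak = np.nonzero(win)[0][np.argmax(v[win])]
    v_max = float(v[i_peak])
    apa = v_max - rmp

    # threshold: curvature maximum on the upstroke, searched from the point
    # where V has clearly left the baseline (RMP + 3 mV) so that stimulus
    # onset artifacts are excluded, up to the peak
    i_start = np.searchsorted(t, stim_start) if stim_start is not None else 0
    dv = np.gradient(v, t)
    d2v = np.gradient(dv, t)
    threshold = threshold_dvdt = None
    left_base = np.nonzero((np.arange(len(v)) >= i_start) & (v >= rmp + 3.0))[0]
    left_base = left_base[left_base < i_peak]
    if left_base.size:
        i_up0 = left_base[0]
        seg = slice(i_up0, i_peak + 1)
        rising = np.nonzero(dv[seg] > 0)[0]
        if rising.size:
            i_thr = i_up0 + rising[np.argmax(d2v[seg][rising])]
            threshold = float(v[i_thr])
        fast = np.nonzero(dv[seg] >= 10.0)[0]
        if fast.size:
            threshold_dvdt = float(v[i_up0 + fast[0]])

    def width_at(level: float) -> Optional[float]:
        # last upward crossing before the peak, first downward after it
        up, dn = _crossings(t, v, level)
        up_before = up[(up <= t[i_peak])]
        dn_after = dn[(dn >= t[i_peak]) & (dn < t_end)]
        if up_before.size and dn_after.size:
            return float(dn_after[0] - up_before[-1])
        return None

    apd50 = width_at(rmp + apa / 2.0)
    width = width_at(width_level)

    # after-hyperpolarization: depth of the post-spike minimum below RMP and
    # the time spent below RMP.  Because the return to rest is asymptotic,
    # the end of the AHP is read with a resolution band: recovery to within
    # 10% of the AHP depth of the resting potential.
    ahp_amp = ahp_dur = None
    post = np.nonzero(win & (t > t[i_peak]))[0]
    if post.size:
        below = v[post] < rmp
        if below.any():
            i_first = post[np.argmax(below)]
            depth = float(rmp - np.min(v[post]))
            if depth > 1e-3:
                ahp_amp = depth
                band = rmp - 0.1 * depth
                j_min = int(np.argmin(v[post]))
                recovered = np.nonzero(v[post[j_min:]] >= band)[0]
                t_exit = t[post[j_min + recovered[0]]] if recovered.size else t[post[-1]]
                ahp_dur = float(t_exit - t[i_first])

    # after-depolarization: interior local maximum on the late repolarization
    adp = None
    fall_lvl = rmp + 0.25 * apa
    late = np.nonzero(win & (t > t[i_peak]) & (v < fall_lvl) & (v > rmp))[0]
    if late.size > 4:
        seg_v = v[late[0] : late[-1] + 1]
        interior = np.arange(1, len(seg_v) - 1)
        locmax = interior[
            (seg_v[interior] > seg_v[interior - 1])
            & (seg_v[interior] >= seg_v[interior + 1])
        ]
        if locmax.size:
            cand = float(seg_v[locmax].max())
            if cand - seg_v[-1] > 0.25 and cand - rmp > 0.25:
                adp = cand - rmp

    return APFeatures(
        rmp=rmp,
        n_spikes=n_spikes,
        v_max=v_max,
        apa=apa,
        apd50=apd50,
        width_at_level=width,
        level=width_level,
        ahp_amplitude=ahp_amp,
        ahp_duration=ahp_dur,
        adp_amplitude=adp,
        threshold=threshold,
        threshold_dvdt=threshold_dvdt,
        time_to_peak=float(t[i_peak] - (stim_start if stim_start is not None else t0)),
    )


@dataclass
class IVCurve:
    """Current-voltage relation, raw and normalized by peak magnitude."""

    voltages: np.ndarray
    currents: np.ndarray
    normalized: np.ndarray
    channel: str
    extraction: str  # 'peak' or 'steady'

    def zero_crossing(self) -> Optional[float]:
        """Voltage at which the current reverses sign.

        Interpolated within the tested range when the sign changes there;
        otherwise linearly extrapolated from the final segment (the standard
        step families stop at +50 mV, just short of the Ca2+ reversal).
        """
        i = self.currents
        v = self.voltages
        sgn = np.sign(i)
        idx = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
        k = idx[0] if idx.size else len(i) - 2
        if i[k + 1] == i[k]:
            return None
        return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def build_iv_curve(
    result: VoltageClampResult,
    channel: str,
    extraction: Optional[str] = None,
) -> IVCurve:
    """Per-step current of one channel vs test potential, peak-normalized.

    Inactivating channels (CaL, CaT, Kv1) report the within-step extremum;
    sustained channels report the value at the end of the step.
    """
    if len(result.traces) < 3:
        raise ValueError("need at least 3 clamp steps to build an I-V curve")
    extraction = extraction or ("peak" if channel in PEAK_CHANNELS else "steady")
    currents = []
    for k, tr in enumerate(result.traces):
        if channel not in tr.currents:
            raise KeyError(f"trace does not record channel {channel!r}")
        t0, t1 = result.step_window(k)
        m = (tr.time >= t0) & (tr.time <= t1)
        i = tr.currents[channel][m]
        if extraction == "peak":
            currents.append(i[np.argmax(np.abs(i))])
        else:
            currents.append(i[-1])
    currents = np.asarray(currents)
    peak = np.max(np.abs(currents))
    if peak == 0.0:
        raise ValueError("all-zero currents; cannot normalize I-V curve")
    return IVCurve(
        voltages=result.test_potentials,
        currents=currents,
        normalized=currents / peak,
        channel=channel,
        extraction=extraction,
    )


@dataclass
class FitScore:
    """Standard error of regression against a reference signal."""

    s: float
    n: int
    k: int
    threshold: float
    is_good: bool


def fit_score(y_exp: Sequence[float], y_sim: Sequence[float], k: int = 0) -> FitScore:
    """S = sqrt(sum (y_exp - y_sim)^2 / (N - K)); good when S < 5% of the
    experimental range (strict)."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_exp.shape != y_sim.shape or y_exp.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(y_exp)
    if n <= k:
        raise ValueError("need more points than fit parameters (N > K)")
    s = float(np.sqrt(np.sum((y_exp - y_sim) ** 2) / (n - k)))
    thr = 0.05 * float(np.max(y_exp) - np.min(y_exp))
    return FitScore(s=s, n=n, k=k, threshold=thr, is_good=s < thr)


def conductance_sweep(
    config: Optional[ModelConfig] = None,
    channels: Sequence[str] = ("CaL", "BK", "Kv1"),
    rel_range: float = 0.2,
    steps: int = 5,
    protocol: Optional[StimulusProtocol] = None,
    include_simultaneous: bool = True,
    max_range: float = 0.5,
) -> pd.DataFrame:
    """AP features under stepwise +/- perturbation of maximal conductances.

    Each named channel is perturbed alone over ``rel_range`` (fraction of the
    control value) in ``steps`` even steps; optionally all named channels are
    perturbed together.  Rows flag runs in which no spike was generated.
    """
    if rel_range > max_range:
        raise ValueError(f"rel_range exceeds the safety bound {max_range}")
    config = config or default_config()
    protocol = protocol or standard_synaptic_protocol()
    factors = 1.0 + np.linspace(-rel_range, rel_range, steps)
    rows = []
    targets: List[Tuple[str, Sequence[str]]] = [(ch, (ch,)) for ch in channels]
    if include_simultaneous:
        targets.append(("all", tuple(channels)))
    for label, group in targets:
        for f in factors:
            cfg = config.with_scaled_gmax({ch: float(f) for ch in group})
            tr = run_protocol(protocol, cfg)
            feats = extract_ap_features(tr)
            row = {"channel": label, "factor": float(f),
                   "ap_generated": feats.n_spikes > 0}
            row.update(feats.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def block_experiment(
    config: Optional[ModelConfig] = None,
    channels: Sequence[str] = ("CaT",),
    fraction_block: float = 1.0,
    protocol: Optional[StimulusProtocol] = None,
) -> Dict:
    """Paired control/block runs of the standard synaptic protocol.

    ``fraction_block`` scales the named conductances by (1 - fraction);
    returns both traces, both feature sets and the feature deltas
    (block minus control).
    """
    if not (0.0 <= fraction_block <= 1.0):
        raise ValueError("fraction_block must lie in [0, 1]")
    config = config or default_config()
    protocol = protocol or standard_synaptic_protocol()
    cfg_block = config.with_scaled_gmax(
        {ch: 1.0 - fraction_block for ch in channels}
    )
    tr_ctrl = run_protocol(protocol, config)
    tr_block = run_protocol(protocol, cfg_block)
    f_ctrl = extract_ap_features(tr_ctrl)
    f_block = extract_ap_features(tr_block)

    def delta(a, b):
        return None if a is None or b is None else b - a

    deltas = {
        "d_rmp": delta(f_ctrl.rmp, f_block.rmp),
        "d_v_max": delta(f_ctrl.v_max, f_block.v_max),
        "d_apd50": delta(f_ctrl.apd50, f_block.apd50),
        "d_ahp_amplitude": delta(f_ctrl.ahp_amplitude, f_block.ahp_amplitude),
    }
    return {
        "control": {"trace": tr_ctrl, "features": f_ctrl},
        "block": {"trace": tr_block, "features": f_block},
        "deltas": deltas,
        "channels": tuple(channels),
        "fraction_block": fraction_block,
    }
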