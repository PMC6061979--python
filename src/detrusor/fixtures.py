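"""Synthetic reference fixtures for exercising the fit machinery.

Experimental overlays (digitized I-V points, recorded AP and SD traces) are
not redistributable, so tests and examples exercise the goodness-of-fit
scoring against fixtures generated here: the model itself is simulated
under the relevant protocol and Gaussian noise of a stated standard
deviation is added.  With zero noise the fixture equals the clean
simulation; regeneration with the same seed is bit-identical.  The ground
truth is returned alongside so calibration/fit tests can score against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .analysis import build_iv_curve
from .cell import (
    run_protocol,
    run_voltage_clamp,
    standard_pulse_protocol,
    standard_synaptic_protocol,
)
from .config import ModelConfig, default_config

__all__ = ["ReferenceFixture", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("iv_points", "ap_trace", "sd_trace")


@dataclass
class ReferenceFixture:
    """Noisy synthetic 'experimental' data plus its clean ground truth."""

    kind: str
    x: np.ndarray  # voltage (mV) for iv_points, time (ms) for traces
    values: np.ndarray  # noisy observable
    truth: np.ndarray  # noise-free simulation
    noise_sd: float
    seed: int
    params: Dict = field(default_factory=dict)


def generate_fixture(
    kind: str,
    config: Optional[ModelConfig] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    channel: str = "CaL",
    subsample: int = 25,
) -> ReferenceFixture:
    """Simulate a figure protocol and add Gaussian noise of ``noise_sd``.

    kind='iv_points'  normalized I-V of ``channel`` under the standard
                      -90 mV-holding step family (noise_sd in normalized
                      current units).
    kind='ap_trace'   the 0.1 nA / 10 ms current-clamp spike (noise in mV).
    kind='sd_trace'   a subthreshold synaptic depolarization (noise in mV).

    Traces are thinned by ``subsample`` to emulate digitized points.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    config = config or default_config()
    rng = np.random.default_rng(seed)

    if kind == "iv_points":
        fam = run_voltage_clamp(np.arange(-70.0, 51.0, 10.0), config)
        curve = build_iv_curve(fam, channel)
        x, truth = curve.voltages, curve.normalized
        params = {"channel": channel, "holding": fam.holding}
    elif kind == "ap_trace":
        tr = run_protocol(standard_pulse_protocol(), config)
        x, truth = tr.time[::subsample], tr.v[::subsample]
        params = {"protocol": "0.1 nA / 10 ms pulse"}
    else:
        proto = standard_synaptic_protocol(gmax_uS=0.004)
        tr = run_protocol(proto, config)
        x, truth = tr.time[::subsample], tr.v[::subsample]
        params = {"protocol": "subthreshold synaptic drive, 0.004 uS"}

    values = truth + rng.normal(0.0, noise_sd, size=truth.shape)
    return ReferenceFixture(
        kind=kind, x=np.asarray(x), values=values, truth=np.asarray(truth),
        noise_sd=noise_sd, seed=seed, params=params,
    )
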