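"""Shared fixtures: the calibrated cell and its standard protocol traces.

Simulation-heavy traces are session-scoped so the expensive runs happen
once; tests must not mutate them.
"""

import pytest

import detrusor as d
from detrusor.cell import (
    long_pulse_protocol,
    run_protocol,
    standard_pulse_protocol,
    standard_synaptic_protocol,
    StimulusProtocol,
)


@pytest.fixture()
def cfg():
    """A fresh default configuration (mutable; function-scoped)."""
    return d.default_config()


@pytest.fixture(scope="session")
def cfg_session():
    return d.default_config()


@pytest.fixture(scope="session")
def rest_trace(cfg_session):
    """500 ms unstimulated run from the initialized state."""
    proto = StimulusProtocol(mode="current_clamp", duration=500.0)
    return run_protocol(proto, cfg_session)


@pytest.fixture(scope="session")
def pulse_trace(cfg_session):
    """The standard 0.1 nA / 10 ms current-clamp spike."""
    return run_protocol(standard_pulse_protocol(), cfg_session)


@pytest.fixture(scope="session")
def long_pulse_trace(cfg_session):
    """0.1 nA sustained for 100 ms."""
    return run_protocol(long_pulse_protocol(), cfg_session)


@pytest.fixture(scope="session")
def syn_trace(cfg_session):
    """The standard synaptic-drive spike (0.0095 uS, 15/25 ms)."""
    return run_protocol(standard_synaptic_protocol(), cfg_session)


@pytest.fixture(scope="session")
def syn_block_trace(cfg_session):
    """Same synaptic protocol with gBK and gKCNQ at 80%."""
    blocked = cfg_session.with_scaled_gmax({"BK": 0.8, "KCNQ": 0.8})
    return run_protocol(standard_synaptic_protocol(), blocked)
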