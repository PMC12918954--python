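"""Shared fixtures: simulated recordings reused across test modules.

Expensive simulations (especially the fine-grid reference run) are
session-scoped so each is integrated once.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from gliamod import (
    NoiseSpec,
    RampCCProtocol,
    StepVCProtocol,
    build_default_params,
    scale_kv4,
    simulate_current_clamp,
    simulate_voltage_clamp,
)

QUIET = NoiseSpec(current_noise_sd=0.0, voltage_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def control_params():
    return build_default_params("control")


@pytest.fixture(scope="session")
def passive_params(control_params):
    """Cell with every voltage-gated conductance removed (leak only)."""
    return replace(control_params, g_na=0.0, g_kdr=0.0, g_a=0.0)


@pytest.fixture(scope="session")
def na_blocked_params(control_params):
    """Na+ channels blocked, the bath condition for K+ current isolation."""
    return replace(control_params, g_na=0.0)


@pytest.fixture(scope="session")
def a_only_params(control_params):
    """Cell expressing only the A-type conductance."""
    return replace(control_params, g_na=0.0, g_kdr=0.0, g_leak=0.0)


@pytest.fixture(scope="session")
def ramp_protocol():
    return RampCCProtocol()


@pytest.fixture(scope="session")
def cc_quiet_control(control_params, ramp_protocol):
    """Noise-free single-trial ramp recording of the control preset."""
    return simulate_current_clamp(control_params, ramp_protocol, noise=QUIET, n_trials=1)


@pytest.fixture(scope="session")
def cc_fine_control(control_params, ramp_protocol):
    """Fine-grid (dt = 0.001 ms) reference integration of the same run."""
    return simulate_current_clamp(
        control_params, ramp_protocol, dt=0.001, noise=QUIET, n_trials=1
    )


@pytest.fixture(scope="session")
def cc_noisy_pair(control_params, ramp_protocol):
    """Control and Kv4-enhanced recordings with default noise, 5 trials."""
    noise = NoiseSpec(seed=20260923)
    ctl = simulate_current_clamp(control_params, ramp_protocol, noise=noise, n_trials=5)
    kv4 = simulate_current_clamp(
        scale_kv4(control_params, 1.5), ramp_protocol, noise=noise, n_trials=5
    )
    return ctl, kv4


@pytest.fixture(scope="session")
def step_families_na_blocked(na_blocked_params):
    """Trial-averaged I_Total / I_K step families of the Na-blocked cell."""
    from gliamod.kv import StepFamily

    tot = simulate_voltage_clamp(
        na_blocked_params, StepVCProtocol(prepulse_mV=-100.0), noise=QUIET, n_trials=1
    )
    ik = simulate_voltage_clamp(
        na_blocked_params, StepVCProtocol(prepulse_mV=-40.0), noise=QUIET, n_trials=1
    )
    return StepFamily.from_recording(tot, "I_Total"), StepFamily.from_recording(ik, "I_K")


@pytest.fixture(scope="session")
def a_only_family(a_only_params):
    from gliamod.kv import StepFamily

    rec = simulate_voltage_clamp(
        a_only_params, StepVCProtocol(prepulse_mV=-100.0), noise=QUIET, n_trials=1
    )
    return StepFamily.from_recording(rec, "I_A")
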