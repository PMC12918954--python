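"""Stimulation protocols and their command waveforms.

Three protocols cover the recording configurations used for DRG
excitability work: a ramp current injection with hyperpolarizing onset
(current clamp), a prepulse + step family (voltage clamp, for I_Total /
I_K separation), and a slow voltage ramp (voltage clamp, quasi-steady-state
I-V).  Command waveforms are generated deterministically from the protocol
fields and the sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RampCCProtocol", "StepVCProtocol", "RampVCProtocol", "NoiseSpec"]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian recording noise, applied after integration.

    Noise goes on the recorded channel only (voltage in CC, current in VC);
    the command stays exact.  The same seed always yields bit-identical
    output.
    """

    current_noise_sd: float = 2.0
    voltage_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_noise_sd < 0 or self.voltage_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class RampCCProtocol:
    """Ramp current injection with a hyperpolarizing onset.

    The command sits at 0 pA for ``pre_stim_ms``, jumps to the (negative)
    ``onset_current`` and ramps up at ``ramp_rate`` pA/ms until
    ``max_current``, optionally holds the final level for ``hold_ms``
    (with ``ramp_rate = 0`` this gives a plain current step), then
    returns to 0 pA for ``post_stim_ms``.
    """

    onset_current: float = -20.0
    ramp_rate: float = 0.15
    max_current: float = 70.0
    pre_stim_ms: float = 100.0
    post_stim_ms: float = 100.0
    hold_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.ramp_rate < 0:
            raise ValueError("ramp_rate must be non-negative")
        if self.onset_current > 0:
            raise ValueError("onset_current must be hyperpolarizing (<= 0)")
        if self.hold_ms < 0:
            raise ValueError("hold_ms must be non-negative")

    @property
    def ramp_ms(self) -> float:
        if self.ramp_rate == 0:
            return 0.0
        return (self.max_current - self.onset_current) / self.ramp_rate

    @property
    def stim_ms(self) -> float:
        return self.ramp_ms + self.hold_ms

    def current_at(self, t: float) -> float:
        """Injected current (pA) at time ``t`` ms."""
        u = t - self.pre_stim_ms
        if u < 0 or u >= self.stim_ms:
            return 0.0
        if u < self.ramp_ms:
            return self.onset_current + self.ramp_rate * u
        return self.max_current if self.ramp_rate > 0 else self.onset_current

    def command(self, dt: float) -> np.ndarray:
        """Injected-current waveform (pA) sampled at ``dt`` ms."""
        total = self.pre_stim_ms + self.stim_ms + self.post_stim_ms
        n = int(round(total / dt)) + 1
        return np.array([self.current_at(k * dt) for k in range(n)])


@dataclass(frozen=True)
class StepVCProtocol:
    """Prepulse + test-step family for K+ current separation.

    A −100 mV prepulse leaves the A-current available; a −40 mV prepulse
    inactivates it, so the −100/−40 pair isolates I_A by subtraction.
    """

    holding_mV: float = -70.0
    prepulse_mV: float = -100.0
    prepulse_ms: float = 500.0
    test_start_mV: float = -60.0
    test_stop_mV: float = 50.0
    test_step_mV: float = 10.0
    test_ms: float = 500.0
    holding_ms: float = 100.0
    post_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.test_step_mV <= 0:
            raise ValueError("test_step_mV must be positive")
        if self.prepulse_ms <= 0:
            raise ValueError("prepulse_ms must be positive")
        span = self.test_stop_mV - self.test_start_mV
        n = span / self.test_step_mV
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(test_stop - test_start) must be divisible by test_step")

    @property
    def test_potentials(self) -> np.ndarray:
        n = int(round((self.test_stop_mV - self.test_start_mV) / self.test_step_mV))
        return self.test_start_mV + self.test_step_mV * np.arange(n + 1)

    @property
    def test_start_sample_ms(self) -> float:
        return self.holding_ms + self.prepulse_ms

    def command(self, test_mV: float, dt: float) -> np.ndarray:
        """Command-voltage waveform (mV) for one test potential."""
        total = self.holding_ms + self.prepulse_ms + self.test_ms + self.post_ms
        t = np.arange(int(round(total / dt)) + 1) * dt
        v = np.full_like(t, self.holding_mV)
        v[(t >= self.holding_ms) & (t < self.holding_ms + self.prepulse_ms)] = self.prepulse_mV
        in_test = (t >= self.test_start_sample_ms) & (t < self.test_start_sample_ms + self.test_ms)
        v[in_test] = test_mV
        return v


@dataclass(frozen=True)
class RampVCProtocol:
    """Slow voltage ramp after a hyperpolarized prepulse.

    The default −100 → +20 mV ramp at 100 mV/s approximates the
    quasi-steady-state current; currents are later binned at 0.1 mV.
    """

    prepulse_mV: float = -100.0
    prepulse_ms: float = 500.0
    ramp_start_mV: float = -100.0
    ramp_stop_mV: float = 20.0
    ramp_rate_mV_per_s: float = 100.0

    def __post_init__(self) -> None:
        if self.ramp_stop_mV <= self.ramp_start_mV:
            raise ValueError("ramp_stop_mV must exceed ramp_start_mV")
        if self.ramp_rate_mV_per_s <= 0:
            raise ValueError("ramp_rate_mV_per_s must be positive")

    @property
    def ramp_ms(self) -> float:
        return (self.ramp_stop_mV - self.ramp_start_mV) / self.ramp_rate_mV_per_s * 1000.0

    def command(self, dt: float) -> np.ndarray:
        """Command-voltage waveform (mV): prepulse then linear ramp."""
        total = self.prepulse_ms + self.ramp_ms
        t = np.arange(int(round(total / dt)) + 1) * dt
        v = np.full_like(t, self.prepulse_mV)
        in_ramp = t >= self.prepulse_ms
        v[in_ramp] = np.minimum(
            self.ramp_start_mV
            + self.ramp_rate_mV_per_s / 1000.0 * (t[in_ramp] - self.prepulse_ms),
            self.ramp_stop_mV,
        )
        return v
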