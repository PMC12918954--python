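"""Single-compartment conductance model of a small/medium DRG sensory neuron.

The model carries four membrane currents: a fast transient Na+ current
(m^3 h gating), a sustained delayed-rectifier K+ current (n^4), a Kv4-like
transient A-type K+ current (a^3 b, Connor–Stevens-style), and an ohmic
leak.  Gate steady states are Boltzmann functions of voltage with
bell-shaped or sigmoidal time constants — a phenomenological
parameterisation whose A-current inactivation gate is almost fully available at −100 mV and
almost fully inactivated at −40 mV, which is what makes prepulse
subtraction (I_A = I_Total − I_K) a meaningful isolation.

Units: mV, ms, pA, pF, nS throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = ["Gate", "NeuronParams", "build_default_params", "scale_kv4", "CONDITIONS"]


@dataclass(frozen=True)
class Gate:
    """One Hodgkin–Huxley-style gating variable.

    Steady state ``x_inf(V) = 1 / (1 + exp(-(V - v_half) / slope))``; a
    positive ``slope`` gives an activation gate, negative an inactivation
    gate.  The time constant (ms) is either bell-shaped,
    ``tau_min + tau_amp / cosh((V - tau_vhalf) / tau_sigma)``
    (``tau_form="bell"``), or sigmoidal,
    ``tau_min + tau_amp / (1 + exp(-(V - tau_vhalf) / tau_sigma))``
    (``tau_form="sigmoid"``).  The sigmoid form with a positive
    ``tau_sigma`` models Kv4-type inactivation: fast recovery at
    hyperpolarized potentials, slow inactivation once depolarized.
    """

    v_half: float
    slope: float
    tau_min: float
    tau_amp: float
    tau_vhalf: float
    tau_sigma: float
    power: int = 1
    tau_form: str = "bell"

    def __post_init__(self) -> None:
        if self.tau_form not in ("bell", "sigmoid"):
            raise ValueError(f"unknown tau_form {self.tau_form!r}")

    def x_inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) / self.slope))

    def tau(self, v: float) -> float:
        u = (v - self.tau_vhalf) / self.tau_sigma
        if self.tau_form == "bell":
            return self.tau_min + self.tau_amp / math.cosh(u)
        return self.tau_min + self.tau_amp / (1.0 + math.exp(-u))


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of the model cell.

    Conductances are whole-cell maximal conductances in nS; ``c_m`` is the
    whole-cell capacitance in pF; reversal potentials in mV.
    """

    c_m: float
    g_na: float
    g_kdr: float
    g_a: float
    g_leak: float
    e_na: float
    e_k: float
    e_leak: float
    na_act: Gate
    na_inact: Gate
    kdr_act: Gate
    a_act: Gate
    a_inact: Gate

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError(f"c_m must be positive, got {self.c_m}")
        for name in ("g_na", "g_kdr", "g_a", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.e_na > 0 > self.e_k):
            raise ValueError("expected e_na > 0 > e_k")

    # -- membrane current ---------------------------------------------------

    def ionic_current(self, v: float, m: float, h: float, n: float, a: float, b: float) -> float:
        """Total ionic + leak current (pA, outward positive) at state."""
        i_na = self.g_na * m**3 * h * (v - self.e_na)
        i_kdr = self.g_kdr * n**4 * (v - self.e_k)
        i_a = self.g_a * a**3 * b * (v - self.e_k)
        i_leak = self.g_leak * (v - self.e_leak)
        return i_na + i_kdr + i_a + i_leak

    def steady_state_current(self, v: float) -> float:
        """Instantaneous current balance with every gate at its steady state."""
        return self.ionic_current(
            v,
            self.na_act.x_inf(v),
            self.na_inact.x_inf(v),
            self.kdr_act.x_inf(v),
            self.a_act.x_inf(v),
            self.a_inact.x_inf(v),
        )

    def resting_state(self) -> tuple[float, float, float, float, float, float]:
        """Zero-current fixed point ``(V, m, h, n, a, b)``.

        The steady-state I-V relation can be N-shaped (a Na+ window
        region with further zero crossings above threshold), so the
        resting potential is the MOST HYPERPOLARIZED root: scan upward
        from E_K for the first sign change, then refine by root-finding.
        """
        lo = self.e_k + 1e-6
        f_lo = self.steady_state_current(lo)
        v_scan = lo
        while v_scan < self.e_na - 1.0:
            v_next = v_scan + 1.0
            f_next = self.steady_state_current(v_next)
            if f_lo * f_next <= 0:
                break
            v_scan, f_lo = v_next, f_next
        else:
            raise ValueError("no zero-current fixed point between E_K and E_Na")
        v = brentq(self.steady_state_current, v_scan, v_scan + 1.0, xtol=1e-10)
        return (
            v,
            self.na_act.x_inf(v),
            self.na_inact.x_inf(v),
            self.kdr_act.x_inf(v),
            self.a_act.x_inf(v),
            self.a_inact.x_inf(v),
        )

    def gate_state_at(self, v: float) -> tuple[float, float, float, float, float]:
        """All five gates at steady state for a clamped potential."""
        return (
            self.na_act.x_inf(v),
            self.na_inact.x_inf(v),
            self.kdr_act.x_inf(v),
            self.a_act.x_inf(v),
            self.a_inact.x_inf(v),
        )


# Preset tuned once so that, under the default 0.15 pA/ms ramp, the control
# cell rests near −58 mV, fires a train of APs, and the A-current's window
# conductance around threshold gives Kv4 scaling its experimental signature
# (fewer APs, higher rheobase, lower depolarised input resistance).
_CONTROL = NeuronParams(
    c_m=22.0,
    g_na=900.0,
    g_kdr=350.0,
    g_a=220.0,
    g_leak=2.0,
    e_na=70.0,
    e_k=-90.0,
    e_leak=-58.0,
    na_act=Gate(v_half=-32.0, slope=5.5, tau_min=0.05, tau_amp=0.25, tau_vhalf=-32.0, tau_sigma=14.0, power=3),
    na_inact=Gate(v_half=-55.0, slope=-7.0, tau_min=0.6, tau_amp=6.0, tau_vhalf=-55.0, tau_sigma=12.0, power=1),
    kdr_act=Gate(v_half=-15.0, slope=9.0, tau_min=2.2, tau_amp=3.5, tau_vhalf=-15.0, tau_sigma=20.0, power=4),
    a_act=Gate(v_half=-38.0, slope=10.0, tau_min=3.0, tau_amp=1.2, tau_vhalf=-38.0, tau_sigma=20.0, power=3),
    a_inact=Gate(v_half=-65.0, slope=-6.0, tau_min=8.0, tau_amp=40.0, tau_vhalf=-55.0, tau_sigma=5.0, power=1, tau_form="sigmoid"),
)

CONDITIONS = ("control", "high_kv4", "no_kv4")


def build_default_params(condition: str = "control") -> NeuronParams:
    """Return the preset for one of the study conditions.

    ``control`` is the reference cell; ``high_kv4`` models an enhanced Kv4
    conductance (g_A × 1.5, all else identical), the direction of the
    Fibulin-2 effect; ``no_kv4`` has g_A = 0 (complete Kv4 block).
    """
    if condition == "control":
        return _CONTROL
    if condition == "high_kv4":
        return scale_kv4(_CONTROL, 1.5)
    if condition == "no_kv4":
        return scale_kv4(_CONTROL, 0.0)
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def scale_kv4(params: NeuronParams, factor: float) -> NeuronParams:
    """Scale the A-type (Kv4) conductance by ``factor``, all else unchanged.

    ``factor`` < 1 models pharmacological block (Phrixotoxin-1 gives
    factor 0 at saturation); ``factor`` > 1 models conductance enhancement.
    """
    if factor < 0:
        raise ValueError(f"factor must be non-negative, got {factor}")
    return replace(params, g_a=params.g_a * factor)
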