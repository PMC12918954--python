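"""Current-clamp feature extraction.

Implements the quantities used to characterise DRG neuron excitability
from ramp-evoked recordings: AP detection with a 5 mV/ms rise-speed
threshold criterion, first-AP waveform parameters (threshold, amplitude,
half-height duration, maximal rise rate, fast afterhyperpolarization),
rheobase measures referenced to the resting-potential crossing of the
ramp, and state-dependent input resistance from linear fits over defined
voltage windows.  Scalar features are computed per trial and averaged
across trials; crossing times are linearly interpolated between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .io import Recording, Sweep

__all__ = [
    "APCriteria",
    "APEvent",
    "ExcitabilityProfile",
    "resting_potential",
    "detect_aps",
    "ap_waveform_params",
    "rheobase_measures",
    "input_resistance",
    "excitability_profile",
    "FeatureError",
]


class FeatureError(ValueError):
    """Raised when a feature is undefined on the given sweep."""


@dataclass(frozen=True)
class APCriteria:
    """AP acceptance and smoothing criteria.

    An AP is a local voltage maximum exceeding ``peak_min_mV``, preceded
    within ``lookback_ms`` by an upward crossing of ``dvdt_threshold``
    (mV/ms) of the smoothed derivative, with at least ``refractory_ms``
    peak separation.  dV/dt is computed by central differences on a
    Savitzky–Golay smoothed trace.
    """

    dvdt_threshold: float = 5.0
    peak_min_mV: float = -10.0
    lookback_ms: float = 10.0
    refractory_ms: float = 2.0
    smooth_window_ms: float = 0.5
    smooth_order: int = 2


@dataclass
class APEvent:
    """Waveform parameters of a single action potential."""

    threshold_time: float
    threshold_V: float
    peak_time: float
    peak_V: float
    max_rise_rate: float
    amplitude: float
    duration_half: float
    fAHP: float

    def __post_init__(self) -> None:
        if self.peak_time <= self.threshold_time:
            raise FeatureError("AP peak must follow its threshold point")
        if self.amplitude <= 0:
            raise FeatureError("AP amplitude must be positive")
        if self.duration_half <= 0:
            raise FeatureError("AP half-height duration must be positive")


@dataclass
class ExcitabilityProfile:
    """Trial-averaged excitability feature vector for one cell."""

    ap_count: float
    rheobase: float | None
    rheobase_norm: float | None
    charge_transfer: float | None
    rmp: float
    rin_hyper: float | None
    rin_depol: float | None
    capacitance: float
    ap1_ap2_interval: float | None = None
    first_ap: APEvent | None = None

    def as_dict(self) -> dict:
        d = {
            "ap_count": self.ap_count,
            "ap1_ap2_interval": self.ap1_ap2_interval,
            "rheobase": self.rheobase,
            "rheobase_norm": self.rheobase_norm,
            "charge_transfer": self.charge_transfer,
            "rmp": self.rmp,
            "rin_hyper": self.rin_hyper,
            "rin_depol": self.rin_depol,
            "capacitance": self.capacitance,
        }
        if self.first_ap is not None:
            for k in (
                "threshold_V",
                "peak_V",
                "max_rise_rate",
                "amplitude",
                "duration_half",
                "fAHP",
            ):
                d[f"ap_{k}"] = getattr(self.first_ap, k)
        return d


# -- helpers ----------------------------------------------------------------


def _smoothed_dvdt(sweep: Sweep, criteria: APCriteria) -> np.ndarray:
    """Central-difference dV/dt (mV/ms) of the locally smoothed trace."""
    v = sweep.recorded
    win = int(round(criteria.smooth_window_ms / sweep.dt))
    if win % 2 == 0:
        win += 1
    if win > criteria.smooth_order and win <= len(v):
        v = savgol_filter(v, win, criteria.smooth_order)
    return np.gradient(v, sweep.dt)


def _cross_time(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    """Linear interpolation of the crossing time of ``level`` in [t0, t1]."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def resting_potential(sweep: Sweep, window: tuple[float, float]) -> float:
    """Mean recorded voltage (mV) over a stimulus-free window (ms).

    The in-silico surrogate of measuring RMP right after break-in: the
    mean of the pre-stimulus baseline.
    """
    lo, hi = window
    t = sweep.time
    if lo < t[0] or hi > t[-1] or hi <= lo:
        raise FeatureError(f"window {window} outside sweep [0, {t[-1]:.3f}] ms")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 10:
        raise FeatureError(f"window holds {int(mask.sum())} samples; at least 10 required")
    if np.any(sweep.command[mask] != 0):
        raise FeatureError("window overlaps nonzero command current")
    return float(np.mean(sweep.recorded[mask]))


def detect_aps(
    sweep: Sweep, criteria: APCriteria | None = None
) -> list[tuple[float, float, float]]:
    """Detect APs; returns ``(threshold_time, peak_time, peak_V)`` per event.

    Events are ordered and non-overlapping; an empty list is a valid
    result for subthreshold traces.
    """
    if sweep.mode != "CC":
        raise FeatureError("AP detection requires a current-clamp sweep")
    if criteria is None:
        criteria = APCriteria()
    v = sweep.recorded
    t = sweep.time
    dvdt = _smoothed_dvdt(sweep, criteria)

    peaks = np.where((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > criteria.peak_min_mV))[0] + 1
    events: list[tuple[float, float, float]] = []
    last_peak_t = -np.inf
    last_peak_idx = 0
    lookback = int(round(criteria.lookback_ms / sweep.dt))
    for p in peaks:
        if t[p] - last_peak_t < criteria.refractory_ms:
            continue
        lo = max(last_peak_idx, p - lookback, 1)
        seg = dvdt[lo : p + 1]
        up = np.where((seg[1:] >= criteria.dvdt_threshold) & (seg[:-1] < criteria.dvdt_threshold))[0]
        if len(up) == 0:
            if dvdt[lo] >= criteria.dvdt_threshold and lo == 1:
                thr_t = t[lo]  # rise criterion already met at trace start
            else:
                continue
        else:
            i = lo + up[-1]
            thr_t = _cross_time(t[i], t[i + 1], dvdt[i], dvdt[i + 1], criteria.dvdt_threshold)
        events.append((float(thr_t), float(t[p]), float(v[p])))
        last_peak_t = t[p]
        last_peak_idx = p
    return events


def ap_waveform_params(
    sweep: Sweep, event_index: int = 1, criteria: APCriteria | None = None
) -> APEvent:
    """Waveform parameters of the ``event_index``-th AP (1-based).

    Threshold is the last upward 5 mV/ms crossing of the smoothed dV/dt
    before the peak; amplitude is peak minus threshold voltage; duration
    is the width at half amplitude; fAHP is threshold voltage minus the
    voltage minimum within 5 ms after the peak.
    """
    if criteria is None:
        criteria = APCriteria()
    events = detect_aps(sweep, criteria)
    if len(events) < event_index or event_index < 1:
        raise FeatureError(f"no AP at index {event_index}; {len(events)} detected")
    thr_t, peak_t, _ = events[event_index - 1]
    t = sweep.time
    v = sweep.recorded
    dvdt = _smoothed_dvdt(sweep, criteria)
    dt = sweep.dt

    thr_v = float(np.interp(thr_t, t, v))
    p = int(round(peak_t / dt))
    # parabolic refinement of the sampled peak
    if 0 < p < len(v) - 1 and (v[p - 1] - 2 * v[p] + v[p + 1]) < 0:
        denom = v[p - 1] - 2 * v[p] + v[p + 1]
        shift = 0.5 * (v[p - 1] - v[p + 1]) / denom
        peak_t = t[p] + shift * dt
        peak_v = float(v[p] - 0.25 * (v[p - 1] - v[p + 1]) * shift)
    else:
        peak_v = float(v[p])

    i_thr = int(np.searchsorted(t, thr_t))
    max_rise = float(np.max(dvdt[max(i_thr - 1, 0) : p + 1]))
    amplitude = peak_v - thr_v
    if amplitude <= 0:
        raise FeatureError("non-positive AP amplitude")

    half_v = thr_v + amplitude / 2.0
    # rising crossing: last upward crossing of half_v before the peak
    rise_idx = None
    for i in range(p - 1, max(i_thr - 2, 0), -1):
        if v[i] < half_v <= v[i + 1]:
            rise_idx = i
            break
    if rise_idx is None:
        raise FeatureError("half-height rising crossing not found")
    t_rise = _cross_time(t[rise_idx], t[rise_idx + 1], v[rise_idx], v[rise_idx + 1], half_v)
    # falling crossing: first downward crossing after the peak, before the next AP
    limit = len(v) - 1
    if len(events) > event_index:
        limit = min(limit, int(round(events[event_index][1] / dt)))
    fall_idx = None
    for i in range(p, limit):
        if v[i] >= half_v > v[i + 1]:
            fall_idx = i
            break
    if fall_idx is None:
        raise FeatureError("half-height falling crossing not found before next AP")
    t_fall = _cross_time(t[fall_idx], t[fall_idx + 1], v[fall_idx], v[fall_idx + 1], half_v)

    ahp_end = min(len(v), p + int(round(5.0 / dt)) + 1)
    fahp = thr_v - float(np.min(v[p:ahp_end]))

    return APEvent(
        threshold_time=thr_t,
        threshold_V=thr_v,
        peak_time=float(peak_t),
        peak_V=peak_v,
        max_rise_rate=max_rise,
        amplitude=float(amplitude),
        duration_half=float(t_fall - t_rise),
        fAHP=fahp,
    )


def rheobase_measures(
    sweep: Sweep,
    capacitance: float,
    rmp: float | None = None,
    criteria: APCriteria | None = None,
) -> tuple[float, float, float]:
    """Rheobase (pA), capacitance-normalized rheobase (pA/pF), charge (pC).

    Rheobase is the command-current difference between the first-AP
    threshold point and the last rising crossing of the resting membrane
    potential before it; charge transfer is the trapezoidal integral of
    the command current over that interval.
    """
    if capacitance <= 0:
        raise FeatureError("capacitance must be positive")
    events = detect_aps(sweep, criteria)
    if not events:
        raise FeatureError("no AP detected; rheobase undefined")
    thr_t = events[0][0]
    t = sweep.time
    v = sweep.recorded
    i_cmd = sweep.command
    if rmp is None:
        rmp = _baseline_rmp(sweep)

    i_thr = int(np.searchsorted(t, thr_t))
    cross = np.where((v[: i_thr - 1] < rmp) & (v[1:i_thr] >= rmp))[0]
    if len(cross) == 0:
        raise FeatureError("voltage never crosses RMP rising before the first AP threshold")
    c = int(cross[-1])
    t_rmp = _cross_time(t[c], t[c + 1], v[c], v[c + 1], rmp)

    i_at = lambda x: float(np.interp(x, t, i_cmd))  # noqa: E731
    rheobase = i_at(thr_t) - i_at(t_rmp)
    # trapezoidal integral of I over [t_rmp, thr_t], fractional ends included
    ts = np.concatenate(([t_rmp], t[(t > t_rmp) & (t < thr_t)], [thr_t]))
    charge = float(np.trapezoid(np.interp(ts, t, i_cmd), ts)) / 1000.0  # pA·ms -> pC
    return float(rheobase), float(rheobase / capacitance), charge


def _baseline_rmp(sweep: Sweep) -> float:
    """Mean voltage over the initial zero-command segment."""
    nz = np.nonzero(sweep.command)[0]
    end = int(nz[0]) if len(nz) else sweep.n_samples
    if end < 10:
        raise FeatureError("no zero-command baseline to estimate RMP from")
    return float(np.mean(sweep.recorded[:end]))


def input_resistance(
    sweep: Sweep,
    state: str,
    rmp: float,
    criteria: APCriteria | None = None,
) -> float:
    """State-dependent input resistance (GΩ) from a ramp-evoked sweep.

    OLS slope of voltage against command current over samples whose
    voltage lies 2–12 mV below RMP (``state="hyper"``) or 5–15 mV above
    RMP (``state="depol"``), restricted to the rising phase before the
    first AP threshold.
    """
    if state == "hyper":
        v_lo, v_hi = rmp - 12.0, rmp - 2.0
    elif state == "depol":
        v_lo, v_hi = rmp + 5.0, rmp + 15.0
    else:
        raise FeatureError(f"state must be 'hyper' or 'depol', got {state!r}")
    t = sweep.time
    v = sweep.recorded
    events = detect_aps(sweep, criteria)
    # rising phase ends at the first AP threshold, or at the voltage
    # maximum for subthreshold sweeps (excludes the post-stimulus decay)
    i_end = int(np.searchsorted(t, events[0][0])) if events else int(np.argmax(v)) + 1
    # rising phase: from the voltage minimum within the pre-threshold segment
    i_min = int(np.argmin(v[:i_end])) if i_end > 0 else 0
    seg = slice(i_min, i_end)
    v_seg = v[seg]
    mask = (v_seg >= v_lo) & (v_seg <= v_hi)
    # Samples just above the segment minimum still carry the membrane's
    # capacitive settling transient (the trace is momentarily stationary
    # while the command keeps ramping); skip the lowest 10% of the window
    # span above the minimum, where that transient is concentrated.
    settle = v_seg.min() + 0.1 * (v_hi - v_lo)
    relaxed = mask & (v_seg >= settle)
    if relaxed.sum() >= 10:
        mask = relaxed
    x = sweep.command[seg][mask]
    y = v_seg[mask]
    if len(x) < 10:
        raise FeatureError(
            f"only {len(x)} samples in the {state} voltage window; at least 10 required"
        )
    if np.ptp(x) == 0:
        raise FeatureError("degenerate (constant) command current in the fit window")
    return float(linregress(x, y).slope)


def excitability_profile(
    rec: Recording, criteria: APCriteria | None = None
) -> ExcitabilityProfile:
    """Trial-averaged excitability profile of one simulated/recorded cell.

    Every scalar feature is computed per trial and arithmetic-averaged
    across trials; features undefined on a trial (e.g. no second AP) are
    excluded from that feature's mean.
    """
    if rec.mode != "CC":
        raise FeatureError("excitability profile requires a current-clamp recording")
    per_trial: dict[str, list[float]] = {}

    def push(key: str, value: float | None) -> None:
        if value is not None and np.isfinite(value):
            per_trial.setdefault(key, []).append(float(value))

    ap_fields = ("threshold_V", "peak_V", "max_rise_rate", "amplitude", "duration_half", "fAHP")
    for trial in rec.trials:
        sweep = trial[0]
        rmp = _baseline_rmp(sweep)
        push("rmp", rmp)
        events = detect_aps(sweep, criteria)
        push("ap_count", float(len(events)))
        if len(events) >= 2:
            push("ap1_ap2_interval", events[1][1] - events[0][1])
        if events:
            try:
                rheo, rheo_norm, charge = rheobase_measures(
                    sweep, rec.capacitance, rmp=rmp, criteria=criteria
                )
                push("rheobase", rheo)
                push("rheobase_norm", rheo_norm)
                push("charge_transfer", charge)
            except FeatureError:
                pass
            try:
                ev = ap_waveform_params(sweep, 1, criteria)
                for f in ap_fields:
                    push(f"ap_{f}", getattr(ev, f))
                push("ap_threshold_time", ev.threshold_time)
                push("ap_peak_time", ev.peak_time)
            except FeatureError:
                pass
        for state, key in (("hyper", "rin_hyper"), ("depol", "rin_depol")):
            try:
                push(key, input_resistance(sweep, state, rmp, criteria))
            except FeatureError:
                pass

    mean = lambda k: float(np.mean(per_trial[k])) if k in per_trial else None  # noqa: E731
    first_ap = None
    if "ap_amplitude" in per_trial:
        first_ap = APEvent(
            threshold_time=mean("ap_threshold_time"),
            threshold_V=mean("ap_threshold_V"),
            peak_time=mean("ap_peak_time"),
            peak_V=mean("ap_peak_V"),
            max_rise_rate=mean("ap_max_rise_rate"),
            amplitude=mean("ap_amplitude"),
            duration_half=mean("ap_duration_half"),
            fAHP=mean("ap_fAHP"),
        )
    return ExcitabilityProfile(
        ap_count=mean("ap_count") if mean("ap_count") is not None else 0.0,
        ap1_ap2_interval=mean("ap1_ap2_interval"),
        rheobase=mean("rheobase"),
        rheobase_norm=mean("rheobase_norm"),
        charge_transfer=mean("charge_transfer"),
        rmp=mean("rmp"),
        rin_hyper=mean("rin_hyper"),
        rin_depol=mean("rin_depol"),
        capacitance=rec.capacitance,
        first_ap=first_ap,
    )
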