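"""Voltage-clamp K+ current analysis.

The A-type current cannot be recorded in isolation; it is obtained by
arithmetic on recordings: P/5 leak subtraction removes the linear leak,
the −100/−40 mV prepulse pair separates the transient (I_A) from the
sustained (I_K) component (I_A = I_Total − I_K), and the
toxin-sensitive component is the before/during difference of ramp
recordings.  Current–voltage summaries are normalized to the cell
capacitance (pA/pF); ramp currents are binned at 0.1 mV on the command
voltage to approximate the quasi-steady-state I-V relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording, Sweep

__all__ = [
    "StepFamily",
    "IVCurve",
    "RampIV",
    "leak_subtract_p_over_n",
    "isolate_ia",
    "step_iv",
    "ramp_iv",
    "toxin_sensitive",
    "ia_fraction_at",
    "KvAnalysisError",
]

RAMP_BIN_MV = 0.1
BASELINE_MS = 50.0  # holding-current window right before the test step
SUSTAINED_MS = 50.0  # averaging window at the end of the test pulse


class KvAnalysisError(ValueError):
    """Raised on protocol mismatches or malformed clamp data."""


@dataclass
class StepFamily:
    """Trial-averaged current traces of a prepulse + step protocol.

    ``currents`` has one row per test potential (pA); ``test_mV`` is the
    strictly increasing, uniformly spaced list of test potentials.
    ``pulse_start_ms`` / ``pulse_ms`` locate the test pulse within each
    sweep; ``label`` names the component (I_Total, I_K, I_A).
    """

    test_mV: np.ndarray
    currents: np.ndarray
    prepulse_mV: float
    capacitance: float
    dt: float
    pulse_start_ms: float
    pulse_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        self.test_mV = np.asarray(self.test_mV, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.shape[0] != len(self.test_mV):
            raise KvAnalysisError("one current trace per test potential required")
        d = np.diff(self.test_mV)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise KvAnalysisError("test potentials must be strictly increasing, uniformly spaced")
        if self.capacitance <= 0:
            raise KvAnalysisError("capacitance must be positive")

    @classmethod
    def from_recording(cls, rec: Recording, label: str = "") -> "StepFamily":
        """Build a family from a step-protocol recording, averaging trials."""
        meta = rec.metadata
        if meta.get("protocol") != "step_vc":
            raise KvAnalysisError("recording does not hold a step voltage-clamp protocol")
        sweeps = rec.trial_mean()
        return cls(
            test_mV=np.asarray(meta["test_potentials"], dtype=float),
            currents=np.stack([s.recorded for s in sweeps]),
            prepulse_mV=float(meta["prepulse_mV"]),
            capacitance=rec.capacitance,
            dt=rec.dt,
            pulse_start_ms=float(meta["test_start_ms"]),
            pulse_ms=float(meta["test_ms"]),
            label=label,
        )


@dataclass
class IVCurve:
    """Capacitance-normalized current–voltage summary of a step family."""

    voltages: np.ndarray
    density: np.ndarray
    summary_mode: str
    label: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.voltages) != len(self.density):
            raise KvAnalysisError("voltages and density must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            raise KvAnalysisError("voltages must be sorted ascending")
        if self.summary_mode not in ("peak", "sustained"):
            raise KvAnalysisError("summary_mode must be 'peak' or 'sustained'")

    def at(self, v: float) -> float:
        """Density at grid point ``v`` (must be on the grid)."""
        hit = np.isclose(self.voltages, v)
        if not hit.any():
            raise KvAnalysisError(f"{v} mV is not on the voltage grid")
        return float(self.density[hit][0])


@dataclass
class RampIV:
    """Ramp-evoked quasi-steady-state I-V, binned at 0.1 mV."""

    bin_centers: np.ndarray
    density: np.ndarray
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.bin_centers) != len(self.density):
            raise KvAnalysisError("bin_centers and density must have equal length")


def leak_subtract_p_over_n(test: Sweep, subsweeps: list[Sweep], n: int = 5) -> Sweep:
    """P/N leak subtraction (P/5 by default).

    Each subsweep carries 1/n of the test command amplitude; the corrected
    trace is the baseline-referenced test current minus n times the
    baseline-referenced mean subsweep current, which cancels any linear
    (ohmic) component exactly.
    """
    if len(subsweeps) != n:
        raise KvAnalysisError(f"expected {n} subsweeps, got {len(subsweeps)}")
    for s in subsweeps:
        if s.n_samples != test.n_samples:
            raise KvAnalysisError("subsweep length differs from test sweep")
    test_amp = np.max(np.abs(test.command - test.command[0]))
    for s in subsweeps:
        amp = np.max(np.abs(s.command - s.command[0]))
        if test_amp > 0 and abs(amp - test_amp / n) > 0.01 * test_amp / n:
            raise KvAnalysisError(
                f"subsweep amplitude {amp:.4g} differs from test amplitude / {n} "
                f"= {test_amp / n:.4g} by more than 1%"
            )
    base_idx = np.flatnonzero(test.command != test.command[0])
    n_base = int(base_idx[0]) if len(base_idx) else test.n_samples
    test_base = float(np.mean(test.recorded[:n_base])) if n_base else 0.0
    sub_mean = np.mean([s.recorded for s in subsweeps], axis=0)
    sub_base = float(np.mean(sub_mean[:n_base])) if n_base else 0.0
    corrected = (test.recorded - test_base) - n * (sub_mean - sub_base)
    return Sweep(test.dt, test.command.copy(), corrected, test.mode, test.label)


def isolate_ia(total: StepFamily, ik: StepFamily) -> StepFamily:
    """Isolate the A-type current: I_A = I_Total − I_K, trace by trace.

    ``total`` must come from the hyperpolarized (−100 mV) prepulse that
    leaves I_A available, ``ik`` from the depolarized (−40 mV) prepulse
    that inactivates it.
    """
    if not np.array_equal(total.test_mV, ik.test_mV):
        raise KvAnalysisError("step families have different test potentials")
    if total.currents.shape != ik.currents.shape or total.dt != ik.dt:
        raise KvAnalysisError("step families have different shapes or sampling")
    if not (total.prepulse_mV < ik.prepulse_mV):
        raise KvAnalysisError(
            f"expected total prepulse below ik prepulse, got "
            f"{total.prepulse_mV} vs {ik.prepulse_mV} mV (swapped families?)"
        )
    return StepFamily(
        test_mV=total.test_mV.copy(),
        currents=total.currents - ik.currents,
        prepulse_mV=total.prepulse_mV,
        capacitance=total.capacitance,
        dt=total.dt,
        pulse_start_ms=total.pulse_start_ms,
        pulse_ms=total.pulse_ms,
        label="I_A",
    )


def step_iv(family: StepFamily, summary_mode: str = "peak") -> IVCurve:
    """Summarise a step family into a capacitance-normalized I-V curve.

    The holding current (mean over the 50 ms before the test step) is
    subtracted per trace; ``peak`` takes the maximum over the test pulse,
    ``sustained`` the mean over the last 50 ms of the pulse.
    """
    dt = family.dt
    i0 = int(round(family.pulse_start_ms / dt))
    i1 = int(round((family.pulse_start_ms + family.pulse_ms) / dt))
    if i1 > family.currents.shape[1]:
        raise KvAnalysisError("summary window exceeds sweep length")
    b0 = max(0, i0 - int(round(BASELINE_MS / dt)))
    baseline = family.currents[:, b0:i0].mean(axis=1) if i0 > b0 else 0.0
    seg = family.currents[:, i0:i1] - np.atleast_1d(baseline)[:, None]
    if summary_mode == "peak":
        summary = seg.max(axis=1)
    elif summary_mode == "sustained":
        n_sus = int(round(SUSTAINED_MS / dt))
        if n_sus > seg.shape[1]:
            raise KvAnalysisError("sustained window exceeds the test pulse")
        summary = seg[:, -n_sus:].mean(axis=1)
    else:
        raise KvAnalysisError("summary_mode must be 'peak' or 'sustained'")
    return IVCurve(
        voltages=family.test_mV.copy(),
        density=summary / family.capacitance,
        summary_mode=summary_mode,
        label=family.label,
    )


def ramp_iv(rec: Recording) -> RampIV:
    """Bin a ramp voltage-clamp recording into a 0.1-mV I-V curve.

    Trials are averaged pointwise first; samples on the ramp segment are
    assigned to half-open 0.1-mV bins on the command voltage and averaged
    within bins; density is mean current over capacitance.
    """
    if rec.mode != "VC":
        raise KvAnalysisError("ramp I-V requires a voltage-clamp recording")
    sweep = rec.trial_mean()[0]
    cmd = sweep.command
    # ramp segment: the strictly increasing run of the command
    dv = np.diff(cmd)
    rising = np.flatnonzero(dv > 0)
    if len(rising) == 0:
        raise KvAnalysisError("command holds no rising ramp segment")
    start, stop = rising[0], rising[-1] + 1
    if np.any(dv[start:stop] < 0):
        raise KvAnalysisError("command is not monotone over the ramp segment")
    v = cmd[start : stop + 1]
    i = sweep.recorded[start : stop + 1]
    v_lo, v_hi = v[0], v[-1]
    n_bins = int(round((v_hi - v_lo) / RAMP_BIN_MV))
    edges = v_lo + RAMP_BIN_MV * np.arange(n_bins + 1)
    idx = np.digitize(v, edges) - 1  # half-open [edge, edge + 0.1)
    valid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    if np.any(counts == 0):
        raise KvAnalysisError(
            "empty ramp bins; sampling too coarse relative to the ramp rate"
        )
    sums = np.bincount(idx[valid], weights=i[valid], minlength=n_bins)
    density = sums / counts / rec.capacitance
    centers = edges[:-1] + RAMP_BIN_MV / 2.0
    return RampIV(bin_centers=centers, density=density, n_trials_averaged=rec.n_trials)


def toxin_sensitive(before: Recording, during: Recording) -> RampIV:
    """Toxin-sensitive ramp current: ramp_iv(before) − ramp_iv(during).

    Models Phrixotoxin-1 isolation of the Kv4 component; both recordings
    must share the protocol and capacitance.
    """
    if before.capacitance != during.capacitance:
        raise KvAnalysisError("capacitance differs between recordings")
    cmd_b = before.trials[0][0].command
    cmd_d = during.trials[0][0].command
    if not np.array_equal(cmd_b, cmd_d):
        raise KvAnalysisError("command protocols differ between recordings")
    iv_b = ramp_iv(before)
    iv_d = ramp_iv(during)
    return RampIV(
        bin_centers=iv_b.bin_centers,
        density=iv_b.density - iv_d.density,
        n_trials_averaged=min(iv_b.n_trials_averaged, iv_d.n_trials_averaged),
    )


def ia_fraction_at(
    control: tuple[IVCurve, IVCurve],
    treated: tuple[IVCurve, IVCurve],
    v: float = -10.0,
) -> float:
    """Fraction of the total K+ current increase carried by I_A at ``v``.

    ``control`` and ``treated`` are (I_Total, I_A) curve pairs on matching
    grids; returns ΔI_A(v) / ΔI_Total(v) with Δ = treated − control.  The
    potential defaults to −10 mV, near the AP threshold where the active
    K+ currents gate AP initiation.
    """
    ctl_total, ctl_ia = control
    trt_total, trt_ia = treated
    d_total = trt_total.at(v) - ctl_total.at(v)
    d_ia = trt_ia.at(v) - ctl_ia.at(v)
    if d_total == 0:
        raise KvAnalysisError(f"total-current change at {v} mV is zero; fraction undefined")
    return d_ia / d_total
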