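"""P/N leak subtraction, I_A isolation, I-V summaries and ramp binning."""

from dataclasses import replace

import numpy as np
import pytest

from gliamod import (
    NoiseSpec,
    RampVCProtocol,
    StepVCProtocol,
    scale_kv4,
    simulate_voltage_clamp,
)
from gliamod.io import Recording, Sweep
from gliamod.kv import (
    IVCurve,
    KvAnalysisError,
    StepFamily,
    ia_fraction_at,
    isolate_ia,
    leak_subtract_p_over_n,
    ramp_iv,
    step_iv,
    toxin_sensitive,
)

QUIET = NoiseSpec(0.0, 0.0, 0)
DT = 0.025


def step_sweep(amplitude, recorded, dt=DT, pre=50.0):
    n_pre = int(pre / dt)
    cmd = np.concatenate([np.zeros(n_pre), np.full(len(recorded) - n_pre, amplitude)])
    return Sweep(dt, cmd, np.asarray(recorded, dtype=float), "VC")


class TestLeakSubtraction:
    def _ohmic(self, amplitude, g=2.0, n=4000):
        rec = np.zeros(n)
        rec[int(50.0 / DT) :] = g * amplitude
        return step_sweep(amplitude, rec)

    def test_ohmic_cell_cancels_exactly(self):
        test = self._ohmic(100.0)
        subs = [self._ohmic(20.0) for _ in range(5)]
        out = leak_subtract_p_over_n(test, subs)
        assert np.max(np.abs(out.recorded)) < 1e-9

    def test_zero_subsweeps_leave_test_unchanged(self):
        test = self._ohmic(100.0)
        subs = [step_sweep(20.0, np.zeros(4000)) for _ in range(5)]
        out = leak_subtract_p_over_n(test, subs)
        np.testing.assert_allclose(out.recorded, test.recorded, atol=1e-12)

    def test_wrong_subsweep_count_rejected(self):
        test = self._ohmic(100.0)
        with pytest.raises(KvAnalysisError, match="expected 5"):
            leak_subtract_p_over_n(test, [self._ohmic(20.0)] * 4)

    def test_amplitude_mismatch_rejected(self):
        test = self._ohmic(100.0)
        subs = [self._ohmic(22.0) for _ in range(5)]  # 10% off 1/5 amplitude
        with pytest.raises(KvAnalysisError, match="amplitude"):
            leak_subtract_p_over_n(test, subs)

    def test_recovers_a_current_from_leaky_cell(self, a_only_params):
        """P/5 on a leak + A cell matches the leak-free A-only simulation."""
        leaky = replace(a_only_params, g_leak=2.0)
        kw = dict(noise=QUIET, n_trials=1)
        # subpulses step from the -100 mV prepulse level with 1/5 amplitude
        def sweep_for(params, v_test):
            proto = StepVCProtocol(holding_mV=-100.0, prepulse_mV=-100.0,
                                   test_start_mV=v_test, test_stop_mV=v_test)
            return simulate_voltage_clamp(params, proto, **kw).trials[0][0]

        test = sweep_for(leaky, 50.0)  # amplitude 150 mV from -100
        subs = [sweep_for(leaky, -70.0)] * 5  # amplitude 30 mV = 150 / 5
        corrected = leak_subtract_p_over_n(test, subs)
        oracle = sweep_for(a_only_params, 50.0)
        in_test = test.command == 50.0
        peak = np.max(corrected.recorded[in_test])
        peak_oracle = np.max(oracle.recorded[in_test])
        assert peak == pytest.approx(peak_oracle, rel=0.02)


class TestIsolateIA:
    def test_identical_families_give_zero(self, step_families_na_blocked):
        tot, _ = step_families_na_blocked
        ia = isolate_ia(tot, replace_prepulse(tot, -40.0))
        assert np.max(np.abs(ia.currents)) == 0.0

    def test_swapped_prepulse_labels_rejected(self, step_families_na_blocked):
        tot, ik = step_families_na_blocked
        with pytest.raises(KvAnalysisError, match="prepulse"):
            isolate_ia(ik, replace_prepulse(tot, -100.0))

    def test_isolated_peak_matches_a_only_simulation(
        self, step_families_na_blocked, a_only_family
    ):
        """Na-blocked cell: the isolated I_A at +50 mV is within 5% of the
        simulation expressing only g_A."""
        tot, ik = step_families_na_blocked
        ia = isolate_ia(tot, ik)
        got = step_iv(ia, "peak").at(50.0)
        want = step_iv(a_only_family, "peak").at(50.0)
        assert got == pytest.approx(want, rel=0.05)

    def test_linearity_in_scaled_inputs(self, step_families_na_blocked):
        tot, ik = step_families_na_blocked
        ia = isolate_ia(tot, ik)
        tot2 = replace_currents(tot, tot.currents * 3.0)
        ik2 = replace_currents(ik, ik.currents * 3.0)
        np.testing.assert_allclose(
            isolate_ia(tot2, ik2).currents, 3.0 * ia.currents, atol=1e-9
        )


def replace_prepulse(fam: StepFamily, prepulse):
    return StepFamily(fam.test_mV, fam.currents.copy(), prepulse, fam.capacitance,
                      fam.dt, fam.pulse_start_ms, fam.pulse_ms, fam.label)


def replace_currents(fam: StepFamily, currents):
    return StepFamily(fam.test_mV, currents, fam.prepulse_mV, fam.capacitance,
                      fam.dt, fam.pulse_start_ms, fam.pulse_ms, fam.label)


class TestStepIV:
    def _const_family(self, level=400.0, cap=20.0):
        n = int(650.0 / DT) + 1
        currents = np.zeros((1, n))
        i0 = int(600.0 / DT)  # pulse start at 600 ms
        currents[0, i0:] = level
        return StepFamily(np.array([0.0]), currents, -100.0, cap, DT,
                          pulse_start_ms=600.0, pulse_ms=50.0)

    def test_constant_pulse_density_under_both_modes(self):
        fam = self._const_family()
        assert step_iv(fam, "peak").density[0] == pytest.approx(20.0)
        assert step_iv(fam, "sustained").density[0] == pytest.approx(20.0)

    def test_doubling_capacitance_halves_density(self, a_only_family):
        doubled = StepFamily(a_only_family.test_mV, a_only_family.currents.copy(),
                             a_only_family.prepulse_mV, 2 * a_only_family.capacitance,
                             a_only_family.dt, a_only_family.pulse_start_ms,
                             a_only_family.pulse_ms)
        np.testing.assert_allclose(
            step_iv(doubled, "peak").density, step_iv(a_only_family, "peak").density / 2.0
        )

    def test_peak_density_matches_fine_grid_gate_maximum(self, a_only_params):
        """Peak A-current density at -10 mV equals g_A a^3 b (V - E_K) / C
        at the gate maximum of a dt = 0.001 ms integration."""
        # holding == prepulse, so a short prepulse suffices (gates start
        # at the -100 mV steady state); the transient peaks within 60 ms
        proto = StepVCProtocol(holding_mV=-100.0, prepulse_mV=-100.0,
                               holding_ms=1.0, prepulse_ms=1.0,
                               test_start_mV=-10.0, test_stop_mV=-10.0,
                               test_ms=60.0, post_ms=0.0)
        fine = simulate_voltage_clamp(a_only_params, proto, dt=0.001,
                                      noise=QUIET, n_trials=1)
        want = step_iv(StepFamily.from_recording(fine), "peak").at(-10.0)
        coarse = simulate_voltage_clamp(a_only_params, proto, noise=QUIET, n_trials=1)
        got = step_iv(StepFamily.from_recording(coarse), "peak").at(-10.0)
        assert got == pytest.approx(want, rel=0.05)

    def test_conservation_total_equals_ik_plus_ia_sustained(self, step_families_na_blocked):
        """Sustained-mode I-V of I_Total equals I_K plus isolated I_A
        exactly, by linearity of the mean."""
        tot, ik = step_families_na_blocked
        ia = isolate_ia(tot, ik)
        d_tot = step_iv(tot, "sustained").density
        d_sum = step_iv(ik, "sustained").density + step_iv(ia, "sustained").density
        np.testing.assert_allclose(d_tot, d_sum, atol=1e-9)

    def test_ia_peak_proportional_to_ga(self, a_only_params):
        """Peak isolated-I_A density at +50 mV scales linearly in g_A."""
        base = step_iv(
            StepFamily.from_recording(
                simulate_voltage_clamp(a_only_params, StepVCProtocol(), noise=QUIET,
                                       n_trials=1)
            ),
            "peak",
        ).at(50.0)
        for f in (2.0, 4.0):
            fam = StepFamily.from_recording(
                simulate_voltage_clamp(scale_kv4(a_only_params, f), StepVCProtocol(),
                                       noise=QUIET, n_trials=1)
            )
            assert step_iv(fam, "peak").at(50.0) == pytest.approx(f * base, rel=0.05)

    def test_window_exceeding_sweep_rejected(self):
        fam = self._const_family()
        bad = StepFamily(fam.test_mV, fam.currents, fam.prepulse_mV, fam.capacitance,
                         fam.dt, pulse_start_ms=600.0, pulse_ms=500.0)
        with pytest.raises(KvAnalysisError, match="window"):
            step_iv(bad, "peak")


def ramp_recording(currents, dt=DT, cap=20.0):
    cmd = RampVCProtocol().command(dt)
    sweep = Sweep(dt, cmd, np.asarray(currents, dtype=float), "VC", label="ramp")
    return Recording(trials=[[sweep]], capacitance=cap, metadata={"protocol": "ramp_vc"})


class TestRampIV:
    def test_constant_current_fills_1200_bins(self):
        proto = RampVCProtocol()
        n = len(proto.command(DT))
        rec = ramp_recording(np.full(n, 100.0))
        iv = ramp_iv(rec)
        assert len(iv.bin_centers) == 1200
        np.testing.assert_allclose(iv.density, 5.0)

    def test_linear_conductance_closed_form(self):
        """g = 2 nS, E = -90 mV: bin densities track g (V - E) / C."""
        proto = RampVCProtocol()
        cmd = proto.command(DT)
        rec = ramp_recording(2.0 * (cmd + 90.0))
        iv = ramp_iv(rec)
        expected = 2.0 * (iv.bin_centers + 90.0) / 20.0
        # half a bin's analytic variation: g * 0.05 mV / C
        assert np.max(np.abs(iv.density - expected)) <= 2.0 * 0.05 / 20.0 + 1e-12

    def test_binning_invariant_to_sampling_rate(self, na_blocked_params):
        """Doubling the sampling rate changes no bin by more than 0.5%."""
        proto = RampVCProtocol()
        iv1 = ramp_iv(simulate_voltage_clamp(na_blocked_params, proto, dt=0.025,
                                             noise=QUIET, n_trials=1))
        iv2 = ramp_iv(simulate_voltage_clamp(na_blocked_params, proto, dt=0.0125,
                                             noise=QUIET, n_trials=1))
        scale = np.max(np.abs(iv1.density))
        assert np.max(np.abs(iv1.density - iv2.density)) / scale < 0.005

    def test_non_monotone_command_rejected(self):
        # rise-fall-rise command: the falling stretch sits between two
        # rising runs, so no single monotone ramp segment exists
        cmd0 = RampVCProtocol().command(DT)
        cmd = np.concatenate([cmd0, cmd0[1:]])
        sweep = Sweep(DT, cmd, np.zeros_like(cmd), "VC")
        rec = Recording(trials=[[sweep]], capacitance=20.0)
        with pytest.raises(KvAnalysisError, match="monotone"):
            ramp_iv(rec)

    def test_empty_bins_rejected(self):
        # 1-ms sampling at 0.1 mV/ms ramp -> exactly one sample per bin;
        # 2-ms sampling leaves every other bin empty
        proto = RampVCProtocol()
        cmd = proto.command(2.0)
        rec = Recording(trials=[[Sweep(2.0, cmd, np.zeros_like(cmd), "VC")]],
                        capacitance=20.0)
        with pytest.raises(KvAnalysisError, match="empty"):
            ramp_iv(rec)


class TestToxinSensitive:
    def test_before_equals_during_gives_zero(self, na_blocked_params):
        rec = simulate_voltage_clamp(na_blocked_params, RampVCProtocol(), noise=QUIET,
                                     n_trials=1)
        diff = toxin_sensitive(rec, rec)
        assert np.max(np.abs(diff.density)) == 0.0

    def test_full_block_recovers_a_only_curve(self, na_blocked_params, a_only_params):
        proto = RampVCProtocol()
        before = simulate_voltage_clamp(na_blocked_params, proto, noise=QUIET, n_trials=1)
        during = simulate_voltage_clamp(scale_kv4(na_blocked_params, 0.0), proto,
                                        noise=QUIET, n_trials=1)
        diff = toxin_sensitive(before, during)
        ref = ramp_iv(simulate_voltage_clamp(a_only_params, proto, noise=QUIET, n_trials=1))
        mask = np.abs(ref.density) > 0.5
        assert np.max(
            np.abs(diff.density[mask] - ref.density[mask]) / np.abs(ref.density[mask])
        ) < 0.05

    def test_half_block_recovers_half_curve(self, na_blocked_params, a_only_params):
        proto = RampVCProtocol()
        before = simulate_voltage_clamp(na_blocked_params, proto, noise=QUIET, n_trials=1)
        during = simulate_voltage_clamp(scale_kv4(na_blocked_params, 0.5), proto,
                                        noise=QUIET, n_trials=1)
        diff = toxin_sensitive(before, during)
        ref = ramp_iv(simulate_voltage_clamp(a_only_params, proto, noise=QUIET, n_trials=1))
        mask = np.abs(ref.density) > 0.5
        assert np.max(
            np.abs(diff.density[mask] - 0.5 * ref.density[mask])
            / np.abs(0.5 * ref.density[mask])
        ) < 0.05

    def test_protocol_mismatch_rejected(self, na_blocked_params):
        r1 = simulate_voltage_clamp(na_blocked_params, RampVCProtocol(), noise=QUIET,
                                    n_trials=1)
        r2 = simulate_voltage_clamp(na_blocked_params,
                                    RampVCProtocol(ramp_stop_mV=10.0),
                                    noise=QUIET, n_trials=1)
        with pytest.raises(KvAnalysisError, match="protocol"):
            toxin_sensitive(r1, r2)


class TestIAFraction:
    def _curve(self, density_at_minus10, mode="peak"):
        return IVCurve(np.array([-20.0, -10.0, 0.0]),
                       np.array([0.0, density_at_minus10, 0.0]), mode)

    def test_arithmetic(self):
        ctl = (self._curve(10.0), self._curve(2.0))
        trt = (self._curve(20.0), self._curve(9.6))
        assert ia_fraction_at(ctl, trt, -10.0) == pytest.approx(0.76)

    def test_zero_denominator_signalled(self):
        ctl = (self._curve(10.0), self._curve(2.0))
        with pytest.raises(KvAnalysisError, match="zero"):
            ia_fraction_at(ctl, ctl, -10.0)

    def test_off_grid_voltage_rejected(self):
        ctl = (self._curve(10.0), self._curve(2.0))
        trt = (self._curve(20.0), self._curve(9.6))
        with pytest.raises(KvAnalysisError, match="grid"):
            ia_fraction_at(ctl, trt, -15.0)

    def test_kv4_scaling_fraction_matches_component_oracle(
        self, na_blocked_params, a_only_params
    ):
        """With only g_A scaled, the isolated-I_A route agrees with direct
        single-conductance simulations within 2%."""
        def family(params, prepulse):
            # single-potential family at -10 mV, the only point needed
            proto = StepVCProtocol(prepulse_mV=prepulse, test_start_mV=-10.0,
                                   test_stop_mV=-10.0)
            return StepFamily.from_recording(
                simulate_voltage_clamp(params, proto, noise=QUIET, n_trials=1))

        def pair(params):
            tot = family(params, -100.0)
            ik = family(params, -40.0)
            return step_iv(tot, "peak"), step_iv(isolate_ia(tot, ik), "peak")

        frac = ia_fraction_at(pair(na_blocked_params),
                              pair(scale_kv4(na_blocked_params, 1.5)), -10.0)

        def peak(params):
            return step_iv(family(params, -100.0), "peak").at(-10.0)

        d_ia = peak(scale_kv4(a_only_params, 1.5)) - peak(a_only_params)
        d_tot = peak(scale_kv4(na_blocked_params, 1.5)) - peak(na_blocked_params)
        assert frac == pytest.approx(d_ia / d_tot, rel=0.02)
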