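# gliamod

Simulation and analysis toolkit for studying how satellite glial cells
(SGCs) tune the excitability of dorsal-root-ganglion (DRG) sensory
neurons. It is aimed at electrophysiologists and neuro-omics analysts
who want a tested, scriptable version of the standard analysis chain:

* **Secretome screening** — filter conditioned-media mass-spectrometry
  tables to high-confidence secreted proteins (Welch test on log
  intensities, fold-change and negative-control criteria), classify
  them against the matrisome, and run hypergeometric/BH enrichment.
* **Cell-type integration** — pseudobulk aggregation of single-cell
  counts by DRG cell class, joint TMM/log-CPM normalization with bulk
  RNA-seq, shared-HVG Spearman similarity, and ranking of candidates by
  SGC expression and SGC specificity.
* **Electrophysiology** — a conductance-based model of a small/medium
  DRG neuron with a Kv4-like A-type K⁺ current, driven by the standard
  protocols (0.15 pA/ms ramp with hyperpolarizing onset; −100/−40 mV
  prepulse step families; 100 mV/s voltage ramps), plus the matching
  analyses: AP detection with a 5 mV/ms threshold criterion, rheobase
  and charge transfer referenced to the RMP crossing, state-dependent
  input resistance, P/5 leak subtraction, I_A = I_Total − I_K prepulse
  isolation, capacitance-normalized I-V curves and 0.1-mV ramp binning.
* **Behaviour** — Dixon up-down 50% paw-withdrawal thresholds from von
  Frey staircases, and plate-test latency censoring.

The membrane model is

```
C dV/dt = I_inj − g_Na m³h (V−E_Na) − g_Kdr n⁴ (V−E_K) − g_A a³b (V−E_K) − g_leak (V−E_leak)
```

with Boltzmann gate steady states and voltage-dependent time constants;
the A-current inactivation gate is available (b ≈ 1) at −100 mV and
inactivated (b ≈ 0) at −40 mV, which is what makes the prepulse
subtraction meaningful. The up-down threshold is `10^(X_f + k·δ)` with
`k` the Dixon coefficient of the terminal response pattern. See
`docs/methods.md` for the full model, parameter tables and assumptions.

## Worked example

Compare the control cell with one whose Kv4 conductance is enhanced
1.5× (the signature of SGC-derived Fibulin-2 exposure):

```python
from gliamod import (NoiseSpec, RampCCProtocol, build_default_params,
                     simulate_current_clamp)
from gliamod.features import excitability_profile

for cond in ("control", "high_kv4"):
    rec = simulate_current_clamp(build_default_params(cond), RampCCProtocol(),
                                 noise=NoiseSpec(seed=1), n_trials=5)
    prof = excitability_profile(rec)
    print(f"{cond}: APs={prof.ap_count:.1f}  rheobase={prof.rheobase:.1f} pA  "
          f"AP1-AP2={prof.ap1_ap2_interval:.1f} ms  "
          f"Rin(depol)={prof.rin_depol:.3f} GOhm  RMP={prof.rmp:.1f} mV")
```

prints

```
control: APs=7.0  rheobase=35.0 pA  AP1-AP2=61.2 ms  Rin(depol)=0.404 GOhm  RMP=-59.1 mV
high_kv4: APs=4.0  rheobase=42.6 pA  AP1-AP2=78.3 ms  Rin(depol)=0.333 GOhm  RMP=-59.6 mV
```

Enhancing the A-type conductance halves the ramp-evoked spike count,
raises the current threshold by ~8 pA, prolongs the first inter-spike
interval and lowers the depolarized-state input resistance, while the
resting potential barely moves — the hypoexcitability phenotype, with
the passive properties as negative controls.

The same operations are available from the shell:

```
gliamod simulate-ephys --condition control --seed 7 --out rec.csv
gliamod features --recording rec.csv --out profile.tsv
gliamod make-synth --kind secretome --seed 2 --out synth/
gliamod rank-secretome --table synth/secretome.tsv --out candidates.tsv
gliamod pwt --sessions sessions.csv --out pwt.tsv
```

Every command takes `--config FILE` (TOML; flags override) and logs its
parameters and seed; exit codes are 0 (ok), 1 (usage), 2 (data error).

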