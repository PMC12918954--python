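# Methods

`gliamod` models and analyses the chain of observations linking a
satellite-glial-cell (SGC) secreted factor to the excitability of small
and medium dorsal-root-ganglion (DRG) sensory neurons: secreted-protein
candidates are filtered from conditioned-media proteomics and ranked by
glial expression specificity; the candidate's electrophysiological
signature — an enhanced A-type (Kv4) K⁺ conductance — is explored in a
conductance-based neuron model; the patch-clamp analyses that would
detect that signature in real recordings are implemented exactly as an
experimenter would run them; and mechanical sensitivity is summarised by
the Dixon up-down 50% withdrawal threshold. Every stage runs on synthetic
data with known ground truth, so the pipeline's statistical behaviour is
testable end to end.

## 1. The model neuron

A single isopotential compartment with capacitance `C_m` and four
currents (units: mV, ms, pA, pF, nS):

    C_m dV/dt = I_inj − I_Na − I_Kdr − I_A − I_leak
    I_Na  = g_Na  · m³h · (V − E_Na)
    I_Kdr = g_Kdr · n⁴  · (V − E_K)
    I_A   = g_A   · a³b · (V − E_K)
    I_leak = g_leak · (V − E_leak)

Each gate `x` relaxes as `dx/dt = (x∞(V) − x)/τ_x(V)` with a Boltzmann
steady state `x∞(V) = 1/(1 + exp(−(V − V½)/k))` and a time constant that
is either bell-shaped (`τ_min + τ_amp / cosh((V − V_τ)/σ_τ)`) or
sigmoidal (`τ_min + τ_amp · logistic((V − V_τ)/σ_τ)`). The sigmoidal
form expresses Kv4-type inactivation kinetics: recovery from
inactivation is fast at hyperpolarized potentials and inactivation is
slow once depolarized. The A-current uses the Connor–Stevens gating
structure (cubed activation times one inactivation gate).

Control preset (frozen after one tuning pass against the behavioural
post-conditions below; never revisited):

| parameter | value | role |
|---|---|---|
| C_m | 22 pF | small/medium DRG soma |
| g_Na, E_Na | 900 nS, +70 mV | spike generation |
| g_Kdr, E_K | 350 nS, −90 mV | repolarization, fAHP |
| g_A | 220 nS | Kv4-like transient current |
| g_leak, E_leak | 2 nS, −58 mV | R_in ≈ 0.5 GΩ, RMP ≈ −59 mV |
| m: V½, k | −32, 5.5 mV | τ 0.05–0.3 ms (bell) |
| h: V½, k | −55, −7 mV | τ 0.6–6.6 ms (bell) |
| n: V½, k | −15, 9 mV | τ 2.2–5.7 ms (bell) |
| a: V½, k | −38, 10 mV | τ 3.0–4.2 ms (bell) |
| b: V½, k | −65, −6 mV | τ 8–48 ms (sigmoid, recovery fast below −60 mV) |

Two properties of the A-current carry the science:

* **Availability.** `b∞(−100) ≈ 0.997` and `b∞(−40) ≈ 0.015`, so a
  −100 mV prepulse leaves the current available while a −40 mV prepulse
  removes it — the premise of isolating I_A by prepulse subtraction.
* **Window/delay conductance.** Between −55 and −40 mV the product
  `a³(V)·b(V)` is small but non-zero, and `b` recovers during each
  afterhyperpolarization faster than it re-inactivates during the
  inter-spike climb. Scaling `g_A` therefore raises rheobase, lowers
  depolarized-state input resistance, delays the second spike and thins
  the spike train, while leaving resting potential and the spike
  waveform (threshold, amplitude, rise rate, width, fAHP) essentially
  unchanged (<5% for a 1.5× change in `g_A`). This is the experimental
  contrast the presets encode: `high_kv4` is the control with `g_A`
  ×1.5, `no_kv4` has `g_A` = 0 (saturating Phrixotoxin-1 block).

Whether an enhanced Kv4 current reflects conductance density or altered
kinetics is not resolved by the recordings being modelled; conductance
scaling is adopted as the single-parameter assumption and all contrasts
are expressed through it.

Temperature is not modelled explicitly; rate constants are understood as
effective values near 33–34 °C. There is no series resistance, no
channel stochasticity and no morphology (see Limitations).

### Protocols

* **Ramp current clamp** (excitability): 100 ms baseline at 0 pA, jump
  to −20 pA, ramp at 0.15 pA/ms to +70 pA (600 ms), 100 ms at 0 pA.
  The hyperpolarizing onset makes the trace cross the resting potential
  on its way up, which anchors the rheobase measurement. The default
  endpoint (70 pA) keeps every segment an integer number of samples at
  the default step and its halvings.
* **Step voltage clamp** (K⁺ current separation): holding −70 mV,
  500 ms prepulse at −100 or −40 mV, 500 ms test steps from −60 to
  +50 mV in 10 mV increments.
* **Ramp voltage clamp** (quasi-steady-state I-V): 500 ms at −100 mV,
  then −100 → +20 mV at 100 mV/s.

### Numerics

Current clamp integrates the full state with fixed-step explicit RK4,
default `dt` = 0.025 ms. Convergence is a tested invariant: halving
`dt` moves no voltage sample by more than 0.5 mV for any preset
(measured ≈ 0.007 mV). Voltage clamp is ideal (V equals the command), so
the gate equations are linear with piecewise-constant coefficients and
are advanced by their exact exponential solution segment by segment; on
ramp commands the same update is applied per sample. A simulation
aborts with an error if the state leaves the representable range
(diagnosing unstable parameter/step combinations).

Recording noise is additive Gaussian on the recorded channel only
(defaults 0.2 mV in current clamp, 2 pA in voltage clamp), drawn from a
seeded generator after deterministic integration; identical inputs give
bit-identical recordings. Five trials per cell are simulated by default
and analyses average across trials, matching standard practice.

## 2. Patch-clamp feature extraction

Definitions follow the conventions used for ramp-evoked DRG recordings:

* **AP detection** — a local maximum above −10 mV preceded within 10 ms
  by an upward crossing of 5 mV/ms in dV/dt, with ≥2 ms separation.
  dV/dt is taken on a Savitzky–Golay-smoothed trace (window 0.5 ms,
  order 2) because the 5 mV/ms criterion is noise-sensitive. All
  criteria are configurable.
* **Threshold** — the last upward 5 mV/ms crossing before the peak
  (first AP only); crossing times are linearly interpolated between
  samples and the peak is refined parabolically.
* **Amplitude** — peak minus threshold voltage. **Duration** — width at
  half amplitude. **fAHP** — threshold voltage minus the minimum within
  5 ms after the peak (window anchored at the peak). **Max rise rate**
  — maximum smoothed dV/dt between threshold and peak.
* **Rheobase** — injected current at the first-AP threshold minus the
  current at the last rising crossing of the resting potential before
  it; **charge transfer** is the trapezoidal integral of the command
  over that interval (pC); **normalized rheobase** divides by the cell
  capacitance. The resting-potential crossing (not zero current) is the
  baseline; this reading of "current amplitude difference from resting
  membrane potential to threshold point" is one of two defensible
  parses and is flagged as a choice.
* **Input resistance** — OLS slope of voltage on command current over
  samples whose voltage lies 2–12 mV below (hyperpolarized state) or
  5–15 mV above (depolarized state) the resting potential, restricted
  to the rising phase before the first AP threshold (or before the
  voltage maximum when no AP fires). Samples in the lowest 10% of the
  window span above the trace minimum are excluded: immediately after
  the hyperpolarizing onset the trace is momentarily stationary while
  the command keeps ramping (capacitive settling), and including those
  samples biases the passive-cell recovery from <5% error to ~7%. No
  capacitive-current correction is applied; the residual bias is
  bounded by the passive-recovery test.

Scalar features are computed per trial and arithmetic-averaged across
trials; a feature undefined on a trial (no second AP, say) is excluded
from that feature's mean. All extractors agree within 2% with a
`dt` = 0.001 ms reference integration (tested).

## 3. K⁺ current separation

* **P/5 leak subtraction**: five subsweeps at 1/5 command amplitude,
  same polarity, from the −100 mV prepulse level; corrected =
  baseline-referenced test minus 5× the baseline-referenced mean
  subsweep. Exact for ohmic leak (tested to machine precision).
* **I_A isolation**: I_A = I_Total(−100 prepulse) − I_K(−40 prepulse),
  pointwise per test potential. With Na⁺ currents blocked the isolated
  peak matches an A-only simulation within 5%; the residual comes from
  the delayed rectifier's slightly different starting activation after
  the two prepulses — the same contamination the experimental protocol
  accepts.
* **I-V summaries**: holding current (mean over the 50 ms before the
  step) is subtracted; `peak` takes the maximum over the pulse,
  `sustained` the mean over its last 50 ms; densities divide by the
  cell capacitance. Peak is the default for I_Total and I_A, sustained
  for I_K — the summary statistic behind published I-V plots is rarely
  stated, so both are available.
* **Ramp I-V**: trials averaged pointwise, samples assigned to
  half-open 0.1 mV bins on the command voltage over [−100, +20) — 1200
  bins — and averaged within bins. The toxin-sensitive (Kv4) component
  is the binwise before-minus-during difference, an exactly linear
  operation.
* **I_A share of a K⁺ current increase** at a grid potential v
  (default −10 mV, near AP threshold): ΔI_A(v)/ΔI_Total(v) between two
  conditions. In the packaged treated scenario (g_A ×1.5 with a 1.2×
  delayed-rectifier change) the share evaluates to ≈ 88%; with only g_A
  changed it is 100% by construction.

## 4. Secretome filtering and ranking

The generator emulates a conditioned-media (CM) vs media-control vs
cell-pellet label-free MS experiment: per-protein base abundance
`log2 I ~ N(16, 2)`, replicate noise sd 0.5 (log2), 3 replicates per
group, 740 proteins of which 73 are truly secreted — elevated in CM by
3 log2 units and absent from media controls. Background proteins appear
identically in CM and control (media-derived), so the CM-specific
detection rule recovers the truth set exactly in the noise-free-control
regime; recovery with statistical filters is the tested quantity.

Filters (all configurable, defaults deliberately strict): Welch t-test
on `log2(I+1)` CM vs control with p < 0.05; fold change
`(mean_CM+1)/(mean_ctl+1) ≥ 2` (the boundary is inclusive); negative
controls must show ≤0 detected replicates and a control/CM mean ratio
≤0.1. The underlying test statistic for MS intensities is not
standardised in the field; Welch-on-logs is the simplest defensible
default. Relaxing any threshold provably yields a superset (tested).
Matrisome classification is an exact case-insensitive symbol lookup in
a user-supplied two-column map (six categories plus non-matrisome).
Term enrichment uses the hypergeometric upper tail against a supplied
annotation, BH-adjusted; p-values equal exhaustive enumeration for
universes ≤ 12 (tested).

## 5. Cell-type integration

Pseudobulk profiles sum single-cell counts per major DRG class (glia,
neurons, immune, endothelial, erythrocytes, fibroblasts, mural) and
normalize to CPM. Bulk and pseudobulk count matrices are jointly
TMM-normalized: M-values against a reference (the sample whose
upper-quartile is closest to the mean upper-quartile) are double-trimmed
(30% on M, 5% on A) and precision-weighted; factors are scaled to unit
geometric mean; log-CPM uses effective library sizes and prior count
0.5. The implementation matches Bioconductor edgeR within ~0.2%
(tested via Rscript) and an independent re-implementation within 2%.

Shared highly variable genes: genes are ranked by log-CPM variance
within each platform and combined by the better (minimum) of the two
ranks, ties broken by symbol — a symmetric, deterministic reading of
"top shared HVGs"; the top 5000 (or all available) enter a Spearman
correlation between the mean bulk profile and each class column.

Candidate ranking: per gene, SGC (glia) CPM, the maximum non-SGC CPM,
and their ratio with a 0.01-CPM pseudocount; genes are ranked
descending by SGC expression and by specificity ratio, and the two
ranks are combined by their mean (ties by ratio, then symbol). The
combination rule is an assumption — the source procedure says only
"ranked by both" — and is isolated in one function.

The expression generator draws negative-binomial counts (dispersion
0.3) around class profiles with 20 planted markers per class (8-fold
elevated), 40 cells per class, 2000 genes; the bulk sample mixes its
source class with 10% of a second class (fibroblasts by default),
mirroring the partial fibroblast/mural character of cultured glia.
What it does not emulate: ambient RNA, doublets, batch effects,
zero-inflation beyond NB sampling, gene–gene correlation.

qPCR fold changes use the ΔCT method: ΔCT = Ct_gene − Ct_housekeeping
per sample, relative expression 2^(−ΔCT), and condition fold change as
the ratio of condition means.

## 6. Up-down withdrawal threshold

Filaments default to the Stoelting set (0.02–1.4 g, approximately
log-spaced). Sessions start mid-set, move down after a withdrawal and
up after none, and end four trials after the first reversal; a staircase
that pins at either end without reversing ends there, and all-negative
(all-positive) sessions are assigned the ceiling (floor) force. The 50%
threshold is `10^(X_f + k·δ)` with `X_f` the log10 force of the final
filament and `δ` the mean log10 spacing. The coefficient `k` for each
terminal response pattern is the value that maximises the likelihood of
the pattern under a cumulative-normal psychometric function with spread
equal to one step — the definition the classical tabulated coefficients
approximate — computed once over all patterns up to length 6 and frozen
in `data/dixon_k.json` (`k(OX) = −0.5`, `k(XO) = +0.5`, symmetric
patterns mirror exactly). If the staircase was clamped at a bound during
the terminal pattern, the same likelihood rule is applied to the actual
levels instead. The simulated responder is logistic in log10 force
(slope 10 per decade by default; infinite slope gives a step). Across
200 seeded sessions the median estimate lies within one filament step of
the true threshold at 0.07, 0.16, 0.4 and 1.0 g (tested), and the median
is monotone in the true threshold.

Plate-test latencies are clamped at the apparatus cutoff (40 s hot,
20 s cold) and flagged as censored at the cutoff.

## 7. Problem sizes and determinism

The test suite and the acceptance script run everything at the sizes
above: 5-trial ramp recordings (~24 k samples per trial at 0.025 ms),
12-step voltage-clamp families, one `dt` = 0.001 ms reference
integration, 740-protein secretome tables, 2000 × 280 single-cell
matrices, 100–200 up-down sessions per condition. Every stochastic
component takes an explicit seed and is bit-reproducible; the
acceptance script derives all of its streams from a single `--seed`.

## 8. Limitations

* The neuron model is a phenomenological point cell tuned to reproduce
  effect *directions* and analysis-pipeline behaviour; its absolute
  currents, spike counts and thresholds are not fitted to any recorded
  cell, and conclusions about real DRG neurons should rest on the
  analysis code, not the preset values.
* Ideal clamp omits series-resistance and space-clamp artifacts, and
  the capacitive transient is off by default; P/5 correction is
  therefore exact in simulation in a way it never is at the rig.
* Synthetic omics tables are far cleaner than real MS or scRNA data
  (no missing-value structure, no batch effects, no peptide-level
  inference); passing recovery tests demonstrates correctness of the
  filtering arithmetic, not robustness to those artifacts.
* The Dixon coefficients derive from the likelihood definition rather
  than the historical printed table; values agree at the patterns with
  well-known entries, but the table is the package's own derivation.
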