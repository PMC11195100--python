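# Methods

## Model

A single-compartment Hodgkin–Huxley neuron with twelve currents: transient
and persistent Na⁺ (NaT, NaP), a fast-activating slowly-inactivating K⁺
current (A), large- and small-conductance Ca²⁺-activated K⁺ (BK, SK), the
KCNQ M-current, the HCN h-current, low-threshold T-type Ca²⁺, a lumped
high-voltage-activated Ca²⁺ current (Ca; L/N/P-Q/R collapsed into one
conductance), the NKB-driven TRPC5 current, the Dyn-driven GIRK current and
a passive leak.  `Cm dVm/dt = I_inj − ΣI_ionic`; every gate relaxes
first-order to a Boltzmann steady state with a constant or bell-shaped
voltage-dependent time constant.  Units are mV, ms, nS, pA, pF, µM
(`nS·mV = pA`, `pA/pF = mV/ms`).

The gating scheme — midpoints, slopes, exponents, time constants, the
calcium-handling and receptor-drive parameters — is authored by this
package.  It is pinned to the published constraints where those exist
(whole-cell Ca²⁺ activation midpoint near −32 mV and inactivation near
−49 mV; SK half-maximal at 0.3 µM Ca²⁺; ḡ_SK = 28.1 nS ↔ 60.2 pA/pF
apamin-sensitive density; ḡ_BK = 20.0 nS ↔ 90.0 pA/pF ibTx-sensitive
density; ḡ_Ca = 2.1/2.8 nS and ḡ_T = 0.66/5 nS in the OVX / OVX+E2 states)
and otherwise uses standard first-order forms for this cell class.  All
constants are human-editable YAML (`src/kndysim/presets/`): `common.yaml`
holds the shared kinetics, `ovx.yaml` and `ovx_e2.yaml` only the maximal
conductances.

Choices that shape the dynamics:

* **Cm = 25 pF.**  Bounded above by the BK calibration (20 nS must deliver
  90 pA/pF at +40 mV, so `Cm ≤ ḡ_BK·DF·b∞/90`) and below by realistic
  soma sizes; 25 pF sits in the whole-cell range for these neurons.
* **Calcium pool.**  One bulk pool, fed by the HVA Ca²⁺ current only
  (`dCa/dt = −k·I_Ca − (Ca−Ca₀)/τ`, k = 7.5·10⁻⁵ µM/(pA·ms), τ = 220 ms,
  Ca₀ = 0.05 µM).  SK/BK couple tightly to HVA channels in these cells,
  which motivates excluding the T-type flux; doing so also keeps the large
  T-type burst current from saturating SK and truncating bursts.  TRPC5
  flux is likewise excluded so that voltage-clamp calibration currents are
  independent of TRPC5.  The influx gain is solved numerically so that
  ḡ_SK = 28.1 nS reproduces the OVX apamin-sensitive 60.2 pA/pF at +40 mV
  under the 500-ms K⁺ protocol; the BK calcium half-activation is then
  solved so ḡ_BK = 20 nS gives the OVX+E2 ibTx-sensitive 90.0 pA/pF.
* **HVA inactivation is partial** (non-inactivating floor 0.35, τ = 60 ms):
  the sustained fraction supplies the calcium that keeps SK/BK active at
  the end of 500-ms steps, as the drug-sensitive density measurements
  require.
* **TRPC5 gating** `c∞ = w·a_NKB + (1 − w·a_NKB)·hill(Ca)` with NKB
  efficacy w = 0.6 and a Ca²⁺ Hill term (half 0.35 µM, n = 2).  Receptor
  drive alone opens the channel part-way; calcium entry through
  voltage-gated channels potentiates it to full opening, giving the
  self-sustaining plateau loop (depolarization → HVA influx → more TRPC5).
  With no drive, resting calcium keeps a small TRPC5 conductance open,
  which is why reducing ḡ_TRPC5 hyperpolarizes the cell and raises
  rheobase.
* **Receptor drives** are first-order occupancies: NKB rises at
  0.03 ms⁻¹ during ligand pulses and decays with τ = 15 s (the slow-EPSP
  persistence), Dyn likewise with τ = 3 s, so GIRK shuts off sooner than
  TRPC5 after a train.  "Saturating" protocols hold both occupancies at 1.
* **Presets.**  OVX and OVX+E2 share all kinetics and differ in
  {Ca, T, h, TRPC5, GIRK, BK, M, SK} maximal conductances.  ḡ_SK differs
  because the published calibrations pin the OVX value (28.1 nS) and the
  E2-state density (~50 pA/pF) separately, and with common Ca-dependent
  gating one value cannot satisfy both.  TRPC5/GIRK values (OVX 2.8/1.0 nS,
  E2 0.7/0.5 nS) are not published; they were fixed once so the OVX state
  is silent at rest yet fires under saturating drive, with both values
  lower in the E2 state per the mRNA downregulation.

## Numerics

An adaptive Dormand–Prince RK5(4) integrator (rtol 10⁻⁶, atol 10⁻⁹, max
step 1 ms) is compiled together with the right-hand side via numba; a
20-s spiking simulation takes well under a second.  The integrator is
cross-checked in the test suite against `scipy.integrate.solve_ivp` on the
same right-hand side and against a tolerance-refinement criterion
(max |ΔVm| < 0.5 mV).  Voltage clamp is ideal: Vm is set to the command and
the clamp current equals the total ionic current.  Traces are sampled at
0.25 ms; gates are clipped to [0, 1] against roundoff.  Current-clamp runs
start from a 5-s settle at zero input from −70 mV; voltage-clamp sweeps
start from the closed-form steady state at the holding potential, standing
in for the 5-s inter-sweep pacing of the recordings.

Analysis constants (documented, configurable): spikes are upward crossings
of −20 mV with a 2-ms refractory; bursts need ≥2 spikes with intra-burst
ISI ≤ 80 ms and ≥300 ms flanking quiescence; phasic bursting additionally
requires a bimodal subthreshold Vm distribution (two-means separation
≥10 mV); tonic vs irregular splits at ISI CV = 0.5; the slow-EPSP uses a
2-Hz zero-phase 4th-order Butterworth low-pass, a 5-s pre-train baseline
and a 10-s post-train peak window; I–V baselines are the mean holding
current over the 50 ms before each step; "peak" means the extremum by
absolute value (inward negative).

Calibration exploits the exact linearity of a channel's drug-sensitive
clamp density in its maximal conductance: one unit-conductance simulation
gives the density template, and the least-squares gbar is closed-form.  A
flat objective (channel closed at every target potential) raises an error;
negative extrapolations clamp to zero with a warning.

## Synthetic data

The voltage-clamp generator emulates the *statistical structure* of the
recorded cohorts — a smooth group-mean I–V density curve, Gaussian
between-cell scaling (SD set from the printed SEM·√n) and additive
within-trace noise — not raw patch-clamp artifacts (no capacitive
transients, series-resistance or seal errors).  Spike-train fixtures place
stereotyped spike waveforms on a flat or two-level baseline with gamma ISI
statistics, so the classifier's ground truth is known by construction.
qPCR pools inject a chosen fold change as a CT shift of −log₂F with
Gaussian cycle noise (4–6 animals, 3–6 ten-cell pools each).  Every
generator is a pure function of (specification, seed).  Passing tests on
these fixtures shows the pipeline recovers what it was given under the
declared noise model; it does not validate the noise model against real
recordings.

qPCR efficiency is reported as an integer percentage capped at 100:
standard-curve slopes steeper than −1/log₁₀2 arise from fitting noise and
tabulated efficiencies round them down to 100, which the cap reproduces.
The two-group test is the pooled-variance Student's t (df = n₁+n₂−2)
reconstructed from means, SEMs and group sizes; a Welch variant is
available behind a flag.  ΔΔCT uses per-animal means of per-pool relative
quantities as the unit of analysis.

## Known limitations

* A bulk-calcium, single-compartment model cannot reproduce every
  pharmacological direction: blocking *all* voltage-gated Ca²⁺ entry (Cd²⁺)
  in current clamp removes the SK/BK brakes more strongly than the TRPC5
  potentiation, so the net effect of full Ca²⁺ block on the slow EPSP is
  depolarizing here, unlike the recorded attenuation (which involves
  presynaptic effects and Ca²⁺ microdomains the model lumps together).
  The underlying coupling — Ca²⁺ entry potentiates the NKB-evoked TRPC5
  current — holds and is tested under voltage clamp.
* With ḡ_T = 5 nS the E2-state whole-cell Ca²⁺ I–V peaks near −40 mV
  (T-dominated) rather than −10 mV; the OVX state peaks at −10 mV as
  recorded.
* Bursts are compact (3 spikes over ~100 ms every ~0.4 s); recorded phasic
  bursts ride longer up-states with more spikes.  The classifier criteria
  (burst structure, up/down bimodality) are met, but the time scales are
  shorter than ex vivo.
* Firing rates under saturating drive (~5 Hz sustained) sit at the low end
  of "high-frequency" synchronized firing.
* The M-current amplitude ratio between states equals the conductance
  ratio exactly (shared kinetics); it is a calibration identity, not an
  independent prediction.
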