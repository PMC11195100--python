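# kndysim

Conductance-based modelling and in-silico electrophysiology of arcuate
kisspeptin (KNDy) neurons — the hypothalamic cells that co-express
kisspeptin, neurokinin B (NKB) and dynorphin (Dyn) and drive pulsatile GnRH
release.  The package is for computational neuroendocrinologists and
electrophysiologists who want to reproduce, probe or extend the
estradiol-dependent switch of these neurons between two firing modes:

* **OVX (low-estradiol) state** — silent at rest, but responding to
  NKB-receptor drive with sustained high-frequency firing carried by TRPC5
  channels and terminated by Dyn-activated GIRK channels (the slow
  EPSP / plateau-potential mode that synchronizes the KNDy network);
* **OVX+E2 (high-estradiol) state** — spontaneous phasic burst firing with
  up/down membrane-potential states, supported by up-regulated T-type and
  high-voltage-activated (HVA) Ca²⁺ currents, h-current, BK and M currents.

## The model

The membrane follows a Hodgkin–Huxley single-compartment equation

```
Cm dVm/dt = I_inj − (I_NaT + I_NaP + I_A + I_BK + I_h + I_SK + I_M
                     + I_T + I_Ca + I_TRPC5 + I_GIRK + I_leak)
```

with each current `I_x = ḡ_x · m^p h^q · (Vm − E_x)` and first-order gating
`dx/dt = (x_∞(V, Ca) − x)/τ_x(V)`; steady states are Boltzmann functions
`x_∞ = 1/(1+exp((V_1/2−V)/k))`.  SK is purely calcium-gated (half-maximal at
0.3 µM), BK is calcium- and voltage-gated, TRPC5 is opened by NKB-receptor
drive with partial efficacy and potentiated to full opening by intracellular
calcium, and GIRK follows Dyn-receptor drive.  A single calcium pool is fed
by the HVA Ca²⁺ current and cleared first-order.  Units package-wide are
mV, ms, nS, pA, pF and µM, so that `nS·mV = pA` and `pA/pF = mV/ms`.

Around the model sits the full analysis pipeline of a patch-clamp study:
declarative voltage-/current-clamp protocols, in-silico pharmacology
(apamin, iberiotoxin, XE-991, TTX, Cd²⁺, the HVA-subtype antagonists as
fractional blocks), I–V curves and Boltzmann fits, drug-subtraction current
isolation, M-current deactivation amplitude, slow-EPSP metrics, rheobase
and F–I curves, a five-way firing-pattern classifier, two-parameter
conductance regime maps, conductance calibration against current-density
targets, the comparative 2^−ΔΔCT qPCR pipeline with standard-curve
efficiencies, and seeded synthetic-data generators for all of it.

## Worked example

```python
import kndysim as ks

for preset in ("ovx", "ovx_e2"):
    params = ks.load_preset(preset)
    trace = ks.simulate(params, ks.spontaneous_protocol(20.0))
    print(preset, ks.classify_firing(trace).label)
```

prints

```
ovx silent
ovx_e2 phasic_burst
```

— the estradiol-treated parameterization bursts spontaneously (55 bursts in
20 s, up/down states separated by ~20 mV) while the low-estradiol cell rests
near −60 mV.  Isolating currents by in-silico pharmacology and inverting
the measurement:

```python
from kndysim.calibration import calibrate_conductance, drug_sensitive_iv
from kndysim.protocols import apply_drug

iv = drug_sensitive_iv(apply_drug(ks.load_preset("ovx"), "ttx"), "SK")
print(iv.at(40.0) / iv.Cm_used)                       # 60.2  (pA/pF)
print(calibrate_conductance("SK", [(40.0, 60.2)],
                            ks.load_preset("ovx")))    # 28.1  (nS)
```

The apamin-sensitive density at the +40 mV step of the 500-ms K⁺ protocol
is 60.2 pA/pF, and calibrating the SK conductance against that single
printed target recovers ḡ_SK = 28.1 nS — the value the preset carries.
The `examples/` directory holds short narrative scripts, one per
capability (firing patterns, current isolation, slow EPSP, regime map,
qPCR); each prints what it computes and what the numbers mean.  A thin CLI
(`kndysim simulate|analyze|calibrate|map|synthesize|qpcr`) wraps the same
functions for shell use.

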