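# Shared kinetics for the arcuate kisspeptin (KNDy) neuron model.
# Units: mV, ms, nS, pA, pF, uM.  Conductances (gbar) are overridden by the
# per-state presets (ovx.yaml, ovx_e2.yaml); everything else is common, since
# estradiol alters channel expression levels but not gating kinetics.
state_label: custom
Cm: 25.0
calcium:
  ca_rest: 0.05         # uM
  tau: 220.0            # ms
  influx_per_pA: 7.505e-5  # uM / (pA ms); refined so g_SK = 28.1 nS gives the
                         # OVX apamin-sensitive 60.2 pA/pF at +40 mV
drive:
  nkb_on_rate: 0.03
  nkb_tau_off: 15000.0
  dyn_on_rate: 0.03
  dyn_tau_off: 3000.0
channels:
  NaT:
    gbar: 80.0
    erev: 60.0
    gating:
      m: {kind: activation, vhalf: -40.0, k: 6.0, exponent: 3,
          tau_min: 0.04, tau_amp: 0.3, tau_vpeak: -35.0, tau_sigma: 15.0}
      h: {kind: inactivation, vhalf: -46.0, k: 4.0, exponent: 1,
          tau_min: 0.5, tau_amp: 8.0, tau_vpeak: -60.0, tau_sigma: 20.0}
  NaP:
    gbar: 0.3
    erev: 60.0
    gating:
      m: {kind: activation, vhalf: -52.0, k: 5.0, exponent: 1, tau: 5.0}
  A:
    # fast-activating, slowly inactivating K+ current; together with BK it
    # provides the rapid spike repolarization (Kv4/Kv2-like)
    gbar: 16.0
    erev: -90.0
    gating:
      m: {kind: activation, vhalf: -35.0, k: 6.0, exponent: 1, tau: 2.0}
      h: {kind: inactivation, vhalf: -55.0, k: 6.0, exponent: 1, tau: 400.0,
          floor: 0.25}
  BK:
    gbar: 8.0
    erev: -90.0
    gating:
      # voltage- and calcium-dependent activation
      b: {kind: activation, vhalf: -15.0, k: 12.0, exponent: 1, tau: 1.0,
          ca_half: 0.13698, hill: 2.0}
  h:
    gbar: 0.4
    erev: -30.0
    gating:
      r: {kind: inactivation, vhalf: -80.0, k: 7.0, exponent: 1,
          tau_min: 100.0, tau_amp: 400.0, tau_vpeak: -85.0, tau_sigma: 20.0}
  SK:
    gbar: 28.1
    erev: -90.0
    gating:
      # purely calcium-gated; half-maximal activation at 0.3 uM.  The slow
      # effective time constant stands in for bulk-calcium/channel coupling
      # and sets the medium-AHP build-up.
      s: {ca_half: 0.3, hill: 4.0, exponent: 1, tau: 100.0}
  M:
    gbar: 0.5
    erev: -90.0
    gating:
      w: {kind: activation, vhalf: -50.0, k: 8.0, exponent: 1, tau: 150.0}
  T:
    gbar: 0.66
    erev: 60.0
    gating:
      m: {kind: activation, vhalf: -60.0, k: 5.0, exponent: 2, tau: 3.0}
      h: {kind: inactivation, vhalf: -74.0, k: 5.5, exponent: 1,
          tau_min: 30.0, tau_amp: 300.0, tau_vpeak: -55.0, tau_sigma: 12.0}
  Ca:
    gbar: 2.1
    erev: 60.0
    gating:
      m: {kind: activation, vhalf: -38.0, k: 9.0, exponent: 2, tau: 2.0}
      # partial inactivation: a 0.35 non-inactivating fraction keeps the
      # sustained HVA current that feeds SK/BK during 500-ms steps
      h: {kind: inactivation, vhalf: -48.9, k: 6.0, exponent: 1, tau: 60.0,
          floor: 0.35}
  TRPC5:
    gbar: 1.2
    erev: 10.0
    gating:
      # receptor drive (NKB) OR intracellular calcium opens the channel
      c: {ca_half: 0.35, hill: 2.0, exponent: 1, tau: 150.0, nkb_weight: 0.6}
  GIRK:
    gbar: 3.0
    erev: -90.0
    gating:
      # opened by Dyn receptor drive on top of a small constitutive fraction
      d: {constitutive: 0.05}
  leak:
    gbar: 0.8
    erev: -65.0
    gating: {}
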