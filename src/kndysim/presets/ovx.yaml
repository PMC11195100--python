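# Ovariectomized (vehicle-treated) state: maximal conductances in nS.
# g_SK = 28.1 nS and g_Ca = 2.1 nS / g_T = 0.66 nS are the published model
# values; g_BK is set so the ibTx-sensitive density at +40 mV matches the
# measured OVX 31.1 pA/pF.
state_label: OVX
conductances:
  NaT: 80.0
  NaP: 0.3
  A: 16.0
  BK: 7.454
  h: 0.4
  SK: 28.1
  M: 0.5
  T: 0.66
  Ca: 2.1
  TRPC5: 2.8
  GIRK: 1.0
  leak: 0.8
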