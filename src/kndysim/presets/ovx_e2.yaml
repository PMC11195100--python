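# Estradiol-treated ovariectomized state.  Relative to OVX: larger Ca, T, h,
# BK and M conductances; smaller TRPC5, GIRK and SK; g_BK = 20.0 nS and
# g_Ca = 2.8 nS / g_T = 5 nS are the published model values, g_SK is set so
# the apamin-sensitive density at +40 mV is ~50 pA/pF.
state_label: OVX_E2
conductances:
  NaT: 80.0
  NaP: 0.3
  A: 16.0
  BK: 20.0
  h: 1.0
  SK: 14.965
  M: 2.0
  T: 5.0
  Ca: 2.8
  TRPC5: 0.7
  GIRK: 0.5
  leak: 0.8
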