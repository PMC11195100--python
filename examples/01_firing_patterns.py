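"""Spontaneous firing of the two hormonal states.

Simulates 20 s of zero-input current clamp for the ovariectomized (OVX) and
estradiol-treated (OVX+E2) parameter sets and classifies the firing pattern.
The OVX cell rests silently; the OVX+E2 cell fires phasic bursts riding
up/down membrane-potential states, driven by its larger T-type Ca and
h-currents."""

import kndysim as ks

for preset in ("ovx", "ovx_e2"):
    params = ks.load_preset(preset)
    trace = ks.simulate(params, ks.spontaneous_protocol(20.0))
    cls = ks.classify_firing(trace)
    print(f"{preset:7s}: {cls.label:13s} "
          f"({cls.features['spike_count']} spikes, "
          f"{cls.features.get('burst_count', 0)} bursts, "
          f"median Vm {float(sorted(trace.V)[len(trace.V)//2]):.1f} mV)")
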