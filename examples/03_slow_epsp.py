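"""The NKB-driven slow EPSP and its TRPC5 dependence.

A 20-Hz, 10-s ligand pulse train (standing in for high-frequency
stimulation of the network) drives the NKB receptor; dynorphin is
co-released.  The OVX cell develops a sustained depolarization with
persistent firing that outlasts the train, carried by Ca-potentiated TRPC5
current.  Knocking the TRPC5 conductance down to 20% (a CRISPR-like
reduction) attenuates the depolarization and abolishes the persistent
firing."""

import numpy as np

import kndysim as ks

ovx = ks.load_preset("ovx")
kd = ovx.copy()
kd.channels["TRPC5"].gbar = 0.2 * ovx.channels["TRPC5"].gbar

protocol = ks.nkb_synchronization_protocol(observe_s=40.0)
for label, params in (("control", ovx), ("TRPC5 knockdown", kd)):
    trace = ks.simulate(params, protocol)
    m = ks.slow_epsp_metrics(trace)
    post = np.sum(ks.spike_times(trace) > protocol.epochs[0][1])
    print(f"{label:16s}: slow EPSP {m.R1:5.1f} mV, "
          f"{post} spikes after the train")
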