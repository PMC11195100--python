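"""Drug-subtraction current isolation and conductance calibration.

Runs the 500-ms K+-current step protocol with and without the SK blocker
apamin (and the BK blocker iberiotoxin), measures the drug-sensitive
current density at the +40 mV step, and then inverts the measurement:
given only the published density target, the calibration recovers the
maximal conductance that produced it."""

import kndysim as ks
from kndysim.calibration import calibrate_conductance, drug_sensitive_iv
from kndysim.protocols import apply_drug

ovx = ks.load_preset("ovx")
e2 = ks.load_preset("ovx_e2")

for label, params, channel in (("OVX apamin-sensitive (SK)", ovx, "SK"),
                               ("OVX+E2 ibTx-sensitive (BK)", e2, "BK")):
    iv = drug_sensitive_iv(apply_drug(params, "ttx"), channel)
    print(f"{label}: {iv.at(40.0)/iv.Cm_used:6.1f} pA/pF at +40 mV")

g_sk = calibrate_conductance("SK", [(40.0, 60.2)], ovx)
g_bk = calibrate_conductance("BK", [(40.0, 90.0)], e2)
print(f"calibrating g_SK against 60.2 pA/pF -> {g_sk:.1f} nS")
print(f"calibrating g_BK against 90.0 pA/pF -> {g_bk:.1f} nS")
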