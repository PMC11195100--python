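"""TRPC5/GIRK balance controls the response to saturating ligand drive.

Sweeps the TRPC5 and GIRK maximal conductances of the OVX-state model under
saturating NKB and Dyn receptor occupancy and classifies the firing at each
grid point.  Firing is eliminated where the TRPC5 conductance is low
relative to the GIRK conductance; the boundary runs diagonally through the
map."""

import numpy as np

import kndysim as ks

ovx = ks.load_preset("ovx")
rm = ks.regime_map(
    ovx,
    ("TRPC5", np.linspace(0.5, 3.0, 3)),
    ("GIRK", np.linspace(0.5, 3.0, 3)),
    ks.saturating_drive_protocol(15.0),
)
df = rm.to_frame()
df["fires"] = df["label"] != "silent"
print(df.pivot(index="GIRK", columns="TRPC5", values="label"))
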