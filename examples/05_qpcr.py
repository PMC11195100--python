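"""qPCR quantification: efficiency, ddCT fold changes, group statistics.

Generates a synthetic two-group experiment (5 animals per group, three
10-cell pools each) in which estradiol halves Trpc5 expression, then runs
the comparative 2^-ddCT pipeline and recovers the injected fold change.
Also evaluates the standard-curve efficiency formula and the
summary-statistic t-test on the whole-cell Ca-density comparison."""

import kndysim as ks
from kndysim.qpcr import group_summary

pools = ks.generate_qpcr_pools({"Trpc5": 0.5}, ct_sd=0.2,
                               n_animals=5, pools_per_animal=3, seed=7)
fc = ks.ddct_fold_change(pools, "Trpc5", "Gapdh", calibrator_group="oil")
print(group_summary(fc).round(3))

print("efficiency at slope -3.352:", ks.primer_efficiency(-3.352), "%")
r = ks.t_from_summary(7.2, 0.5, 40, 13.4, 0.9, 11)
print(f"Ca density comparison: t({r.df:.0f}) = {abs(r.t):.2f}, p = {r.p:.2g}")
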