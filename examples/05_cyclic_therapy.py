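"""Cyclic gefitinib therapy of a simulated NSCLC tumor.

Runs the empirical-seascape tumor simulation (2 replicates per penetration
length instead of 10) under the cyclic schedule — four one-week-on /
one-week-off cycles followed by four drug-free weeks — for three drug
penetration length scales, and summarizes tumor burden and drug resistance.
"""

from mswsim.experiments import therapy

res = therapy(length_scales=(2, 4, 16), replicates=2, seed=1)

cols = ["L", "mean_final_total", "mean_resistant_fraction", "extinct_replicates"]
print(res.summary[cols].round(3).to_string(index=False))
# L is the distance (lattice units) at which drug concentration halves.
# Shallow penetration (L = 2) leaves a large, mostly drug-sensitive tumor;
# intermediate penetration (L = 4) carves mutant selection windows that
# enrich resistant cells; deep penetration (L = 16) puts the whole grid in
# the net-loss regime and eradicates every replicate.
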