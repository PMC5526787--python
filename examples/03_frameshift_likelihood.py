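"""Fit the microhomology repair model and assess frameshift likelihood.

A resolution-frequency table (homology length, GC, distance to the break)
is fitted by ordinary least squares; each cut site's FSM likelihood is the
predicted-likelihood mass on deletions whose length is not divisible by 3.
"""

import numpy as np

from croatan import (assess_fsm, compute_hej_cutoff, enumerate_microhomologies,
                     fit_repair_model)
from croatan import simulate as sim

table, truth = sim.make_resolution_table(sim.RepairTableConfig(rng_seed=5))
model = fit_repair_model(table)
print("fitted coefficients (truth in parentheses):")
print(f"  intercept {model.intercept:+.4f} ({truth['intercept']:+.3f})")
for k, v in model.coefficients.items():
    print(f"  {k:11s} {v:+.4f} ({truth['coefficients'][k]:+.3f})")

# HEJ-applicability cutoff: median likelihood sum over background cut sites
rng = np.random.default_rng(6)
background = [("".join(rng.choice(list("ACGT"), size=60)), 30)
              for _ in range(200)]
cutoff = compute_hej_cutoff(model, background)
print(f"HEJ lower-limit cutoff (background median): {cutoff:.3f}")

site = "".join(rng.choice(list("ACGT"), size=60))
pairs = enumerate_microhomologies(site, 30)
a = assess_fsm(model, site, 30)
print(f"example site: {len(pairs)} microhomology pairs, "
      f"FSM likelihood {a.fsm_likelihood:.2f}, hej_sum {a.hej_sum:.2f}, "
      f"passes (> 0.66 and above cutoff): {a.passes_fsm_test}")
# A passing site is one where most predicted repair outcomes shift the
# reading frame AND homology-guided repair is plausible at all.
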