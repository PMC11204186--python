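"""Simulate one FISH cohort and recover its true separation with the top-k rule.

A rigid-mode cohort of 200 nuclei is simulated for probe pair #2-#3 in
AA-genotype cells (true 3D separation 2.2 um). Because the microscope
records only the 2D projection of a randomly oriented segment, the raw mean
projected distance underestimates the separation by a factor of pi/4; the
mean of the 40 largest measurements selects near-in-plane segments and
recovers the separation almost exactly.
"""

import numpy as np

from loopdist import estimator, fish_sim

table = fish_sim.simulate_cohort(pair=(2, 3), genotype="AA", n_nuclei=200, seed=7)
distances = fish_sim.pair_distances(table, homologs_per_nucleus=1)

print(f"simulated {len(distances)} projected distances (one per nucleus)")
print(f"raw mean:            {np.mean(distances):.3f} um   (~ pi/4 * 2.2 = {np.pi / 4 * 2.2:.3f})")

res = estimator.topk_distances(distances, k=40)
print(f"top-40-of-200 mean:  {res.mean:.3f} um   (true separation 2.2 um)")
print(f"top-40 SD:           {res.sd:.3f} um")

ratio, se = estimator.estimator_bias_oracle(n=200, k=40, reps=2000, seed=0)
print(f"\nMonte-Carlo bias of the rule: top-40/200 mean recovers {100 * ratio:.2f}% "
      f"(+/- {100 * 3 * se:.2f}%) of the true separation")
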