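"""Neutral X/A and Y/A diversity ratios from the forward XY simulator.

With equal numbers of breeding males and females there are 1.5 X copies and
0.5 Y copies per autosome pair, so at mutation-drift equilibrium Watterson's
theta should satisfy theta_X/theta_A = 3/4 and theta_Y/theta_A = 1/4.
"""

import numpy as np

from ylinkkit import simpop

ratios = []
for seed in range(5):
    pop = simpop.simulate_wf(simpop.WFConfig(seed=seed))
    x_a, y_a = pop.theta_ratios()
    print(f"seed {seed}: theta_X/theta_A = {x_a:.3f}   theta_Y/theta_A = {y_a:.3f}")
    ratios.append((x_a, y_a))

r = np.array(ratios)
print(f"\nmean over {len(r)} replicates: X/A = {r[:, 0].mean():.3f} (expect 0.75), "
      f"Y/A = {r[:, 1].mean():.3f} (expect 0.25)")
print("Per-replicate scatter is coalescent noise; the means converge on the "
      "copy-number expectations.")
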