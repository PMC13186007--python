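"""Cortical activation threshold and d' selectivity from spike counts.

Simulates one stimulating electrode's multi-channel cortical response
(logistic spike counts versus current, linear spatial falloff from the
best channel), then recovers the 50%-of-max threshold and the d' firing
falloff slope, and shows the rising threshold trend across degeneration
groups.
"""

import numpy as np

from orrquant import best_threshold, dprime_selectivity, generate_cortical
from orrquant.synthdata import GROUP_CORTICAL_THRESHOLD_UA, GROUP_DPRIME

resp, truth = generate_cortical(90.0, seed=8, falloff_per_mm=0.5)
print(f"single electrode: true threshold {truth['threshold_ua']:.1f} uA, "
      f"estimated {best_threshold(resp):.1f} uA")
sel = dprime_selectivity(resp)
print(f"d' selectivity: true {truth['d_prime']:.2f}, "
      f"estimated {sel.d_prime:.2f} per mm "
      f"(best channel {sel.best_channel_id})\n")

print("group  mean est. threshold (uA)   mean est. d'")
for g, mean in GROUP_CORTICAL_THRESHOLD_UA.items():
    thr, dp = [], []
    for k in range(10):
        r, _ = generate_cortical(mean, group_label=g, seed=100 * g + k,
                                 falloff_per_mm=GROUP_DPRIME[g])
        thr.append(best_threshold(r))
        dp.append(dprime_selectivity(r).d_prime)
    print(f"  {g}        {np.mean(thr):6.1f}                 "
          f"{np.mean(dp):.2f}")
print("\nThresholds rise with degeneration severity (group 0 lowest).")
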