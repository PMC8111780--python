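"""Membrane topology from paramagnetic relaxation enhancement.

Generates spectra with a water-soluble and a detergent-partitioning probe
over the same exposure profile, computes I/Iref attenuation profiles with
propagated uncertainties, and smooths them with the Gaussian
sequence-weighted moving average.
"""

import numpy as np
from scipy import stats

from shiftprobe import SyntheticSpec, gen_pre, pre_profile

spec = SyntheticSpec(seed=11)
water_spec, water_ref = gen_pre(spec, probe="watersoluble")
det_spec, det_ref = gen_pre(spec, probe="detergent")

water = pre_profile(water_spec, water_ref)
det = pre_profile(det_spec, det_ref)

tm = range(48, 80)  # transmembrane helix
loops = [r for r in water.smoothed if r < 29 or r > 123]
print(f"water-soluble probe, smoothed I/Iref: "
      f"TM mean {np.mean([water.smoothed[r] for r in tm]):.2f}, "
      f"terminal loops {np.mean([water.smoothed[r] for r in loops]):.2f}")
print(f"detergent probe, smoothed I/Iref:     "
      f"TM mean {np.mean([det.smoothed[r] for r in tm]):.2f}, "
      f"terminal loops {np.mean([det.smoothed[r] for r in loops]):.2f}")

common = sorted(set(water.ratios) & set(det.ratios))
rho = stats.spearmanr([water.ratios[r] for r in common],
                      [det.ratios[r] for r in common]).statistic
print(f"Spearman correlation between the two probes: {rho:.2f}")

# The water-soluble probe attenuates exposed residues (low ratios in loops),
# the detergent probe attenuates buried ones (low ratios in the TM helix);
# the strong anti-correlation is the topology signature.
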