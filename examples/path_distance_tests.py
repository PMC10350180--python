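"""Divergence and convergence of soma-to-target path distances.

Builds toy morphologies for two classes with controlled cable lengths:
within class 0, target R01 lies 500 µm farther than R00 (divergence), and
class 1 reaches both targets over paths 25% longer than class 0
(convergence). Rank-sum tests with BH FDR recover both effects.
"""

import numpy as np

import projectome as pj

offsets = np.array([[1000.0, 1500.0],   # class 0: R00 at 1000 µm, R01 at 1500 µm
                    [1250.0, 1875.0]])  # class 1: 25% longer throughout
config = pj.SyntheticConfig(seed=40, k_classes=2, neurons_per_class=12,
                            n_regions=2, profiles=np.full((2, 2), 0.5),
                            path_offsets=offsets, path_noise_sd=80.0)
neurons, _ = pj.generate_morphologies(config)
records = pj.collect_medians(neurons, config.true_labels())
print(f"{len(records)} (neuron, region) median path-distance records")

for label in ("class_0", "class_1"):
    results, _ = pj.divergence_test(records, label)
    for r in results:
        print(f"divergence  {r.comparison}: q={r.q_fdr:.2e} "
              f"significant={r.significant}  ({r.direction})")

for region in (pj.RegionLabel("R00"), pj.RegionLabel("R01")):
    results, _ = pj.convergence_test(records, region)
    for r in results:
        print(f"convergence {r.comparison}: q={r.q_fdr:.2e} "
              f"significant={r.significant}  ({r.direction})")

print("Within each class the nearer target is reached over significantly "
      "shorter cable, and at each shared target class_0's axons arrive over "
      "shorter paths than class_1's — the planted geometry, read back from "
      "the statistics.")
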