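"""Classify a synthetic three-class projection matrix.

Generates 90 neurons (three planted classes of 30) over 12 target regions,
runs the variance-gated recursive classification, and compares the result
with the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

import projectome as pj

config = pj.SyntheticConfig(seed=20, k_classes=3, neurons_per_class=30,
                            n_regions=12)
matrix, truth = pj.generate_matrix(config)
tree, assignment = pj.classify_recursive(matrix, pj.RandomizationConfig(seed=21))

root = tree.root.levene
print(f"root gate: var_real={root.var_real:.1f}  var_null={root.var_null:.1f}  "
      f"p={root.p_one_tailed:.2e}  decision={root.decision.value}")
sizes = {lab: len(assignment.members(lab)) for lab in assignment.class_labels()}
print(f"classes found: {sizes}")
ari = adjusted_rand_score([truth[n] for n in matrix.neuron_ids],
                          [assignment[n] for n in matrix.neuron_ids])
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print("A larger real-than-null angle variance opens the gate; recursion stops "
      "once every subgroup matches its own single-class null, and ARI 1.0 "
      "means the planted membership was recovered exactly.")
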