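"""Margin-preserving swap randomization of a count matrix.

Shows that the null preserves every neuron's axonal size (row sums) and
every region's total targeting (column sums) while erasing class structure,
widening nothing and narrowing the pairwise-angle spread toward the
single-class continuum.
"""

import numpy as np

import projectome as pj

matrix, _ = pj.generate_matrix(pj.SyntheticConfig(
    seed=5, k_classes=2, neurons_per_class=10, n_regions=8))
report = pj.randomize(matrix, pj.RandomizationConfig(seed=6))

print("row sums unchanged:   ",
      np.array_equal(report.matrix.row_sums(), matrix.row_sums()))
print("column sums unchanged:",
      np.array_equal(report.matrix.column_sums(), matrix.column_sums()))
print(f"accepted moves: {report.n_accepted}  "
      f"acceptance rate: {report.acceptance_rate:.2f}")

real = pj.pairwise_angles(matrix)
null = pj.pairwise_angles(report.matrix)
print(f"pairwise-angle variance  real: {real.variance():.1f}  "
      f"null: {null.variance():.1f}")
gate = pj.levene_one_tailed(real, null)
print(f"one-tailed Levene gate: decision={gate.decision.value}, "
      f"p={gate.p_one_tailed:.2e}")
print("The two-class matrix is significantly more variable than its own "
      "randomized continuum, which is exactly the evidence the classifier "
      "uses to split.")
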