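"""Estimate class population fractions by NNLS deconvolution.

Builds a synthetic regional projection-strength vector as an exact mixture
of two class patterns (25% / 75%), then recovers the mixing fractions from
the count matrix alone and derives each class's share of one target
region's afferents.
"""

import numpy as np
import pandas as pd

import projectome as pj

config = pj.SyntheticConfig(seed=7, k_classes=2, neurons_per_class=20,
                            n_regions=8,
                            profiles=pj.default_profiles(2, 8, disjoint=False))
matrix, truth = pj.generate_matrix(config)
labels = sorted(set(truth.values()))

raw_A = np.stack([
    matrix.counts[[i for i, n in enumerate(matrix.neuron_ids)
                   if truth[n] == lab]].sum(axis=0)
    for lab in labels
], axis=1).astype(float)
A, _ = pj.binormalize(raw_A)
true_fractions = np.array([0.25, 0.75])
regional = pd.DataFrame({
    "region": [str(r) for r in matrix.regions],
    "mean_volume": A @ true_fractions,
    "mean_density": np.ones(matrix.n_regions),
})

problem = pj.build_problem(matrix, truth, regional)
estimate = pj.nnls_solve(problem)
print("planted fractions: ",
      {lab: float(f) for lab, f in zip(labels, true_fractions)})
print("recovered fractions:",
      {lab: round(float(f), 4) for lab, f in zip(labels, estimate.fractions)})
print(f"squared residual: {estimate.residual_sq:.2e}")

profiles = pd.DataFrame(
    {lab: pj.class_profile(matrix, truth, lab) for lab in labels}).T
region = str(matrix.regions[0])
shares = pj.afferent_composition(estimate.fractions, profiles, region, labels)
print(f"afferent composition of {region}: "
      + ", ".join(f"{lab}={s:.1%}" for lab, s in shares.items()))
print("A near-zero residual means the regional strengths are an almost exact "
      "mixture of the class patterns; the shares say which class supplies "
      "that region's input.")
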