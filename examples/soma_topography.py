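"""Quantify spatial segregation of class somata with convex hulls.

Draws two overlapping and one distant soma cloud, sweeps hull-volume
outliers, and reports pairwise overlap/union volume ratios plus the layer
composition of one class.
"""

import numpy as np

import projectome as pj

rng = np.random.default_rng(30)
sets = [
    pj.SomaSet("A30", rng.normal(loc=(0, 0, 0), scale=120, size=(30, 3)),
               layers=["L2"] * 27 + ["L3"] * 3),
    pj.SomaSet("B25", rng.normal(loc=(150, 40, 0), scale=120, size=(25, 3))),
    pj.SomaSet("E10", rng.normal(loc=(2000, 0, 0), scale=120, size=(10, 3))),
]

report = pj.hull_report(sets)
print(report.per_class.to_string(index=False))
print()
for row in report.pairwise.itertuples():
    flag = "  (no shared volume)" if row.empty_intersection else ""
    print(f"{row.class_a} vs {row.class_b}: overlap/union = {row.ratio:.3f}{flag}")

comp = pj.layer_composition(report.retained["A30"])
print("\nlayer composition of A30:")
print(comp.to_string())
print("\nNearby clouds share a modest fraction of hull volume while the "
      "distant class is fully segregated (ratio 0); a layer fraction near "
      "0.9 indicates a laminar concentration of that class's somata.")
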