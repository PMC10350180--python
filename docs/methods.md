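# Methods

## The classification problem

A source brain region projecting to k target parcels could in principle
contain any of 2^k − 1 axonal projection types. Given whole-brain
single-neuron reconstructions registered to a common atlas, each neuron i
is summarized as a vector **v**ᵢ ∈ ℕᵏ of axonal-point counts per target
parcel. The question the classifier answers is whether the observed
collection of vectors is consistent with a *single* projection class whose
apparent diversity is random variation within the constraints of regional
connectivity (H₀), or whether statistically distinct projection classes
exist (H_A).

### Distance

The dissimilarity between neurons i and j is the arccosine of the cosine
similarity of their count vectors,

θᵢⱼ = arccos( ⟨**v**ᵢ, **v**ⱼ⟩ / (‖**v**ᵢ‖‖**v**ⱼ‖) ),

reported in degrees and clamped to [0, 180] against floating-point
overshoot. The angle is invariant to per-neuron scaling, so a neuron's
total axonal extent does not influence its class — only the *pattern* of
targeting does. Degrees (not radians) are the working scale throughout:
angle-distribution variances in the hundreds correspond to standard
deviations of 14–19°, the regime in which the variance gate operates.

### The single-class null

H₀'s distance distribution comes from randomizing the count matrix while
preserving both row sums (each neuron's axonal size) and column sums (each
region's total targeting). The randomizer applies stochastic unit moves:
pick two distinct neurons i ≠ j and two distinct regions a ≠ b uniformly
and move one point (i,a)→(i,b) and (j,b)→(j,a); moves that would drive a
cell negative are rejected and do not count. This is the minimal move that
exchanges axonal points between two neurons across two regions; its
magnitude (one point) is a design choice, since only the *kind* of swap is
inherent to the scheme. The chain length defaults to 10 accepted moves per
axonal point in the matrix — a generous mixing budget at the problem sizes
this package targets (verified empirically: acceptance rates sit near 1
and doubling the chain does not change gate decisions). The null distance
distribution pools the pairwise angles of `n_replicates` independent
randomized matrices (default 1, one randomized control matrix; larger
values smooth the null at extra cost).

Degenerate inputs: a matrix with fewer than two rows or two columns admits
no swap and raises; a chain that cannot find an acceptable move within
1000 × n_swaps attempts (e.g. all mass in one column) raises rather than
spinning. The unit moves are irreducible on the space of non-negative
integer matrices with fixed margins, which the tests confirm by exhaustive
state-space enumeration on small fixtures.

### The variance gate

If distinct classes exist, within-class angles are small and between-class
angles large, so the *real* angle distribution is wider than the null's.
The gate is a one-tailed Levene test on absolute deviations from each
group's mean (the "absolute" variant): an F statistic with
(1, n_real + n_null − 2) degrees of freedom, whose two-group p-value is
halved to the one-tailed p only when var_real > var_null. When
var_real ≤ var_null the split direction is impossible; p is reported as
not applicable and the group is kept whole. The pairwise angles entering
the test are not independent (each neuron appears in n − 1 pairs), so the
nominal F reference is an approximation; the gate's realized false-split
rate is therefore measured, not assumed (see calibration below).

### Recursive gating

Classification starts with all neurons lumped together. At each candidate
group with at least `min_testable` members (default 4 — below that there
are fewer than 6 pairwise angles and a variance test is meaningless), the
group's *own* submatrix (its rows, restricted to regions with nonzero
column sum) is randomized to build a group-specific null. If the gate
opens, the group's average-linkage (UPGMA) dendrogram — recomputed from
the group's own angles — is cut at its root into two subtrees and both are
re-examined; otherwise the group is a terminal class. Groups smaller than
`min_testable` terminate untested, which is how very small classes can
survive. Classes are labelled by decreasing size as letter + size ("A38" =
largest class with 38 members). Each node's null seeds derive from one
seed sequence spawned along the recursion, so the full tree is
reproducible from a single integer seed.

A non-root subgroup whose submatrix cannot be randomized (all members
projecting to a single region) terminates as a class with the gate marked
not-applicable rather than erroring; at the root the error propagates,
since classification of such a matrix is meaningless.

## Abundance deconvolution

Single-neuron data weight each *class* by its reconstruction count, not by
its true population size. Bulk anterograde tracing weights each *region*
by the whole population's output. The deconvolution matches the two:
column c of A holds class c's per-region axonal weights (sum of its
members' count vectors), and b holds per-region strengths (mean projection
volume × mean projection density over tracing experiments, normalized to
sum 1), restricted to the regions present in both sources. A is
sequentially bi-normalized — rows divided by their sums (removing regional
axonal-length differences), all cells rescaled by k_classes/m so the grand
total equals the number of classes, then columns divided by their sums
(removing invaded-region-count differences). Non-negative least squares
then finds x ≥ 0 minimizing ‖Ax − b‖; x is reported renormalized to sum 1
as class fractions, with the squared residual as a proxy for uncertainty.
Each class's share of one region's afferents is fraction(c) × profile(c,
region), normalized over classes.

The orientation of A (regions × classes) follows from the normalization
arithmetic: m rows summing to one give total m, and the rescale to
k_classes is only consistent when rows are regions. The per-region
strengths are consumed as already-averaged volume and density columns,
multiplied per region; averaging products per experiment instead is the
variant this package does not implement, as the inputs it accepts are the
published per-region averages.

## Soma topography

Somata of one class form a 3D point cloud; its convex hull is swept for
volume-leverage outliers: with V the full-set hull volume and n the number
of points, a point is flagged when its leave-one-out hull volume differs
from V by more than V/n. All flagged points are removed together in a
single sweep (the default; a sequential re-sweep is available by flag),
and if fewer than four points would remain — the minimum spanning a 3D
hull — the original set is kept unchanged. Note the criterion is
aggressive by construction: when one extreme point dominates the hull, the
points supporting the cone toward it are flagged too, and the <4 rule then
keeps the whole set; the sweep is a thresholding heuristic, not a robust
estimator.

Between two classes, segregation is the ratio of intersection to union
volume of the two hulls. The intersection of convex polytopes is convex,
so it is computed exactly as the half-space intersection of both hulls'
facet inequalities, seeded by the Chebyshev center found by linear
programming; an infeasible or measure-zero intersection is reported as
ratio 0 with an explicit empty-intersection flag (the
near-complete-segregation case) rather than an error. The exact volumes
are cross-checked against Monte-Carlo estimates in the tests.

## Path-distance statistics

Path distance is cable length: the sum of Euclidean segment lengths along
the unique root-to-node path (always ≥ the straight-line distance). The
unit of observation is the per-neuron *median* path distance per target
region — neurons, not axonal points, are the independent replicates;
pooling points would pseudo-replicate, since one neuron contributes
hundreds of correlated points. Two families of two-sample rank-sum
(Mann–Whitney) comparisons are run: divergence (one class, every pair of
its targets; ipsilateral and contralateral targets are never mixed because
contralateral paths are systematically longer) and convergence (one shared
target, every pair of classes reaching it). The exact rank-sum null is
used up to a combined n of 20, the tie-corrected normal approximation
beyond. Each family is corrected by Benjamini–Hochberg FDR at 0.05, with
the family defined as all pairwise comparisons within one analysis (one
class for divergence, one target for convergence). Reported directions
("X shorter than Y") always follow the sign of the median difference.

## Synthetic data: what it emulates and what it does not

The generator produces the three inputs the pipeline consumes.

*Count matrices* are Dirichlet-multinomial: class c has a region-weight
profile **p**_c (default: each class prefers its own block of regions with
75% of its mass, the rest spread uniformly; a disjoint variant removes the
background); a neuron draws proportions from Dirichlet(concentration ×
**p**_c) and counts from a multinomial over a log-normal total
(median ≈ 1000 axonal points, σ_log = 0.5, the scale of real
reconstructions). Dirichlet-multinomial is the minimal over-dispersed
count model that produces the within-class/between-class distance
structure the classifier is built around.

*Concentration calibration.* The swap null is approximately uniform over
margin-fixed tables, which is substantially over-dispersed relative to a
plain multinomial; a single-class generator therefore only sits "on the
continuum" at one dispersion level. The default concentration is
1.25 × n_regions (≈ 1.25 Dirichlet weight per region on a uniform
profile), chosen once so that at the reference condition — 50 neurons, 12
regions, default totals — the root gate's realized false-split rate
matches its nominal α = 0.05 (measured at ≈ 0.05 over 600 calibration
replicates; markedly smaller concentrations push the rate toward 1,
markedly larger toward 0). This calibration is a property of the
generator/null pair at the reference condition and is treated as
approximate at other matrix shapes.

*Morphologies* are star-shaped trees: one straight branch per targeted
region, tips spaced symmetrically around a configured class × region path
offset (so with zero noise the per-neuron median path distance equals the
offset exactly), plus Gaussian per-tip jitter. *Somata* are isotropic
Gaussian clouds per class (default SD 100 µm, cloud centers 400 µm apart)
with layers assigned by thresholds on one axis.

What the generators do *not* emulate: realistic axonal geometry (branch
angles, tortuosity, bouton clustering), spatially correlated registration
error, hemispheric asymmetries, or region-size effects on point counts.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under its own model assumptions; they do not certify
performance on real reconstructions, where over-dispersion beyond
Dirichlet-multinomial or annotation artifacts may shift the gate's
operating point.

## Numerical choices and degenerate inputs

- Cosine similarities are clipped to [−1, 1] before arccos; angles to
  [0, 180] degrees.
- Variances use the unbiased (n − 1) estimator.
- UPGMA ties are resolved by the linkage implementation's first-occurrence
  rule; test fixtures avoid ties, and identical seeds always reproduce
  identical trees.
- Zero-norm rows (neurons with no extra-source axon) are rejected by the
  distance computation and dropped with a report at tabulation.
- Points exactly on the hemisphere midline count as ipsilateral; the
  midline is a required, atlas-specific configuration scalar, never a
  built-in constant.
- Nodes without an atlas parcel stay in the tree (they carry cable for
  path distances) but are excluded from count tabulation, with their
  totals reported.
- Hull computations treat coplanar point sets as degenerate (volume 0 in
  the outlier sweep; an error where a 3D hull is required).
- All randomness flows through seeded NumPy generators or the seeded swap
  kernel; seeds for recursive nulls and replicate pools are spawned from
  one seed sequence.

## Problem sizes

The bundled statistical checks run at desk scale: calibration uses 200
single-class draws of 50 neurons × 12 regions; recovery uses 50 replicates
per planted class count (2, 3, 5) at 30 neurons per class; solver/oracle
comparisons use 100 random problems with up to 4 classes; Monte-Carlo hull
cross-checks use 10⁶ samples. These sizes were chosen to make the binomial
noise on measured rates small relative to the bands being checked while
keeping the whole suite comfortably fast on one CPU.

## Known limitations

- The Levene gate's F reference ignores the dependence among pairwise
  angles; calibration is empirical, at the reference condition.
- The recursion tests subtrees independently; no multiplicity correction
  is applied across the tree's gates (matching the method's design), so
  deep recursions on large samples carry the usual family-wise caveats.
- The NNLS abundance model assumes the regional strengths are a
  non-negative mixture of the class patterns over exactly the shared
  regions; regions seen by only one source of data are silently outside
  the problem.
- The hull-overlap ratio compares volumes only; two interleaved but
  low-density clouds can still show high overlap.
- `n_swaps` sufficiency is heuristic (10 × total points); no formal
  mixing diagnostic beyond the reported acceptance rate is provided.
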