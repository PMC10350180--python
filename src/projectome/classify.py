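"""Variance-gated recursive classification of projection vectors.

The classifier asks, at every candidate group of neurons, whether the
group's pairwise projection differences are more variable than expected
under a single-class null:

1.  Pairwise differences are arccosine angles between count vectors
    (degrees; scale-invariant, so a neuron's total axonal size does not
    matter, only its targeting pattern).
2.  The null distribution of angles comes from margin-preserving swap
    randomization of the group's own count submatrix (see ``nullmodel``).
3.  A one-tailed Levene test (absolute deviations from the group mean)
    decides whether the real angles have significantly larger variance
    than the null angles. Only a larger real variance counts as evidence
    for sub-classes; otherwise the test is reported as not applicable and
    the group is kept whole.
4.  If the gate opens, the group's average-linkage (UPGMA) dendrogram is
    cut at its root into two subgroups and the procedure recurses, until
    no subgroup yields a significant result. Accepted leaves are the
    projection classes.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.stats import levene as _scipy_levene

from .errors import NullModelUndefinedError, ValidationError
from .matrix import ProjectionMatrix
from .nullmodel import RandomizationConfig, randomize

DEFAULT_ALPHA = 0.05
#: Smallest group on which the variance gate is attempted: below 4 members
#: there are fewer than 6 pairwise angles and the test is meaningless, so
#: smaller groups become terminal (untested) classes.
DEFAULT_MIN_TESTABLE = 4

_SEED_MOD = 2**31


# ---------------------------------------------------------------------------
# Pairwise arccosine distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceDistribution:
    """Condensed vector of pairwise angles (degrees) between n_items vectors.

    Order matches scipy's condensed convention: (0,1), (0,2), ...,
    (n-2,n-1). Every angle lies in [0, 180]; proportional vectors are at 0.
    ``n_items=None`` marks a pooled distribution (angles concatenated from
    several replicate matrices), for which the pair-count invariant does
    not apply.
    """

    angles: np.ndarray
    n_items: Optional[int]

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.n_items is not None:
            expected = self.n_items * (self.n_items - 1) // 2
            if self.angles.shape != (expected,):
                raise ValidationError(
                    f"expected {expected} pairwise angles for {self.n_items} "
                    f"items, got shape {self.angles.shape}"
                )
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() > 180):
            raise ValidationError("angles must lie in [0, 180] degrees")

    def variance(self) -> float:
        return float(np.var(self.angles, ddof=1))


def pairwise_angles(matrix: ProjectionMatrix) -> DistanceDistribution:
    """Arccosine of cosine similarity for every unordered pair of rows.

    Angles are reported in degrees and clamped to [0, 180] against
    floating-point overshoot. A zero-norm row has no direction and is an
    error naming the neuron.
    """
    X = matrix.counts.astype(float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(
            f"neuron {matrix.neuron_ids[zero[0]]!r} has a zero projection vector"
        )
    unit = X / norms[:, None]
    cosine = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(matrix.n_neurons, k=1)
    angles = np.degrees(np.arccos(cosine[iu]))
    return DistanceDistribution(np.clip(angles, 0.0, 180.0), matrix.n_neurons)


# ---------------------------------------------------------------------------
# One-tailed Levene gate
# ---------------------------------------------------------------------------

class Decision(str, Enum):
    SPLIT = "split"  # reject the single-class null
    STOP = "stop"  # retain the single-class null
    NOT_APPLICABLE = "not_applicable"  # gate could not be evaluated


@dataclass
class LeveneResult:
    """Outcome of the variance gate at one node.

    ``p_one_tailed`` is defined only when the real variance exceeds the
    null variance (the one-tailed direction of interest); otherwise it is
    None and the reported decision is to stop, mirroring the "p = N/A"
    convention for a real variance below the null.
    """

    var_real: float
    var_null: float
    p_one_tailed: Optional[float]
    alpha: float
    decision: Decision
    statistic: Optional[float] = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "var_real": self.var_real,
            "var_null": self.var_null,
            "p_one_tailed": self.p_one_tailed,
            "alpha": self.alpha,
            "decision": self.decision.value,
            "statistic": self.statistic,
            "note": self.note,
        }


def levene_one_tailed(
    real: DistanceDistribution,
    null: DistanceDistribution,
    alpha: float = DEFAULT_ALPHA,
) -> LeveneResult:
    """One-tailed Levene test: are real angles MORE variable than null angles?

    Uses the classical statistic on absolute deviations from each group's
    mean — an F statistic with (1, n_real + n_null - 2) degrees of freedom.
    The two-group F p-value is two-sided in the variances; it is halved to
    the one-tailed p only when var_real > var_null. When var_real <=
    var_null the split direction is impossible and p is not applicable.
    """
    if real.angles.size < 2 or null.angles.size < 2:
        raise ValidationError("Levene gate needs >= 2 angles in each distribution")
    var_real = real.variance()
    var_null = null.variance()
    if var_real <= var_null:
        return LeveneResult(var_real, var_null, None, alpha, Decision.STOP,
                            note="real variance not above null; p = N/A")
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p_two = _scipy_levene(real.angles, null.angles, center="mean")
    if not np.isfinite(stat):
        return LeveneResult(var_real, var_null, None, alpha, Decision.STOP,
                            statistic=None,
                            note="degenerate samples; Levene statistic undefined")
    p_one = float(p_two) / 2.0
    decision = Decision.SPLIT if p_one < alpha else Decision.STOP
    return LeveneResult(var_real, var_null, p_one, alpha, decision,
                        statistic=float(stat))


# ---------------------------------------------------------------------------
# Average-linkage dendrogram
# ---------------------------------------------------------------------------

def average_linkage(distribution: DistanceDistribution) -> np.ndarray:
    """Deterministic UPGMA linkage matrix over the condensed angle vector."""
    if distribution.n_items < 2:
        raise ValidationError("average linkage needs at least 2 items")
    return linkage(distribution.angles, method="average")


def _cluster_members(Z: np.ndarray, cluster: int, n: int) -> list[int]:
    """Leaf indices under a (possibly internal) linkage cluster id."""
    stack, members = [cluster], []
    while stack:
        c = stack.pop()
        if c < n:
            members.append(c)
        else:
            row = Z[c - n]
            stack.extend((int(row[0]), int(row[1])))
    return sorted(members)


def root_split(Z: np.ndarray, n: int) -> tuple[list[int], list[int]]:
    """Cut the dendrogram at its root into the two top-level subtrees."""
    left, right = int(Z[-1, 0]), int(Z[-1, 1])
    return _cluster_members(Z, left, n), _cluster_members(Z, right, n)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick string with merge heights converted to branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(cluster: int, parent_height: float) -> str:
        if cluster < n:
            return f"{labels[cluster]}:{parent_height:.6g}"
        row = Z[cluster - n]
        height = float(row[2])
        inner = ",".join(
            render(int(child), height) for child in (row[0], row[1])
        )
        return f"({inner}):{parent_height - height:.6g}"

    row = Z[-1]
    height = float(row[2])
    inner = ",".join(render(int(child), height) for child in (row[0], row[1]))
    return f"({inner});"


# ---------------------------------------------------------------------------
# Recursive gated classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationNode:
    members: list[str]
    levene: Optional[LeveneResult] = None
    children: Optional[tuple["ClassificationNode", "ClassificationNode"]] = None
    class_label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["ClassificationNode"]:
        if self.is_leaf:
            return [self]
        out: list[ClassificationNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "members": self.members,
            "class_label": self.class_label,
            "levene": None if self.levene is None else self.levene.to_dict(),
            "children": None
            if self.children is None
            else [c.to_dict() for c in self.children],
        }


@dataclass
class ClassificationTree:
    root: ClassificationNode
    alpha: float
    min_testable: int
    newick: str = ""

    def classes(self) -> list[ClassificationNode]:
        return self.root.leaves()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "min_testable": self.min_testable,
            "newick": self.newick,
            "root": self.root.to_dict(),
        }


@dataclass
class ClassAssignment:
    """Map neuron_id -> class label (letter + class size, e.g. "A38")."""

    labels: dict[str, str] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return [n for n, lab in self.labels.items() if lab == label]

    def class_labels(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def n_classes(self) -> int:
        return len(set(self.labels.values()))

    def __getitem__(self, neuron_id: str) -> str:
        return self.labels[neuron_id]

    def as_dict(self) -> dict[str, str]:
        return dict(self.labels)


def _letter(index: int) -> str:
    letters = string.ascii_uppercase
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = letters[rem] + out
    return out


def _null_angles(
    submatrix: ProjectionMatrix, config: RandomizationConfig, seeds: list[int]
) -> DistanceDistribution:
    """Pooled pairwise angles from the configured number of null replicates."""
    pooled = []
    for seed in seeds:
        report = randomize(submatrix, config, seed_override=seed)
        pooled.append(pairwise_angles(report.matrix).angles)
    return DistanceDistribution(np.concatenate(pooled), None)


def classify_recursive(
    matrix: ProjectionMatrix,
    rand_config: RandomizationConfig,
    alpha: float = DEFAULT_ALPHA,
    min_testable: int = DEFAULT_MIN_TESTABLE,
) -> tuple[ClassificationTree, ClassAssignment]:
    """Recursively split neurons into projection classes gated by variance.

    Starting from all neurons lumped together, each candidate group with at
    least ``min_testable`` members is tested against its own swap-null; on
    a significant one-tailed Levene result the group's UPGMA dendrogram is
    cut at the root and both halves are re-examined. Terminal groups are
    the projection classes, labelled by decreasing size as letter + size
    ("A38" = largest class, 38 members). Fully reproducible given the
    config seed.
    """
    if min_testable < DEFAULT_MIN_TESTABLE:
        raise ValidationError(f"min_testable must be >= {DEFAULT_MIN_TESTABLE}")
    root_ss = np.random.SeedSequence(rand_config.seed)

    full_dist = pairwise_angles(matrix)
    newick = (
        linkage_to_newick(average_linkage(full_dist), matrix.neuron_ids)
        if matrix.n_neurons >= 2
        else ""
    )

    def visit(members: list[str], ss: np.random.SeedSequence, is_root: bool
              ) -> ClassificationNode:
        node = ClassificationNode(members=list(members))
        if len(members) < min_testable:
            return node
        sub = matrix.subset(members, drop_empty_regions=True)
        real = pairwise_angles(sub)
        seeds = [
            int(s) % _SEED_MOD
            for s in ss.generate_state(rand_config.n_replicates)
        ]
        try:
            null = _null_angles(sub, rand_config, seeds)
        except NullModelUndefinedError as exc:
            if is_root:
                raise
            node.levene = LeveneResult(
                real.variance(), float("nan"), None, alpha,
                Decision.NOT_APPLICABLE, note=str(exc),
            )
            return node
        node.levene = levene_one_tailed(real, null, alpha)
        if node.levene.decision is Decision.SPLIT:
            Z = average_linkage(real)
            left_idx, right_idx = root_split(Z, sub.n_neurons)
            left = [sub.neuron_ids[i] for i in left_idx]
            right = [sub.neuron_ids[i] for i in right_idx]
            child_ss = ss.spawn(2)
            node.children = (
                visit(left, child_ss[0], False),
                visit(right, child_ss[1], False),
            )
        return node

    root = visit(list(matrix.neuron_ids), root_ss, True)
    tree = ClassificationTree(root=root, alpha=alpha, min_testable=min_testable,
                              newick=newick)

    # label leaves by decreasing size, ties by first member's matrix order
    order = {nid: i for i, nid in enumerate(matrix.neuron_ids)}
    leaves = sorted(
        tree.classes(),
        key=lambda leaf: (-len(leaf.members), min(order[m] for m in leaf.members)),
    )
    assignment = ClassAssignment()
    for rank, leaf in enumerate(leaves):
        label = f"{_letter(rank)}{len(leaf.members)}"
        leaf.class_label = label
        for member in leaf.members:
            assignment.labels[member] = label
    # keep matrix row order in the mapping for stable output files
    assignment.labels = {
        nid: assignment.labels[nid] for nid in matrix.neuron_ids
    }
    return tree, assignment
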