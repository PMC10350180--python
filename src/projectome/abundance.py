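"""Class abundance deconvolution against regional projection strengths.

Single-neuron reconstructions give each class's axonal pattern but not how
many neurons the source region holds per class. Bulk anterograde tracing
gives per-region projection strengths for the whole source population.
Matching the two — find non-negative class fractions x minimizing
||A x - b||, where column c of A is class c's (bi-normalized) per-region
axonal weight and b the normalized regional strength vector — recovers the
relative population size of every class, plus each class's share of the
afferents a given target receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .errors import UndefinedCompositionError, ValidationError
from .matrix import ProjectionMatrix


def binormalize(raw_A: np.ndarray) -> tuple[np.ndarray, dict]:
    """Sequential bi-normalization of the regions x classes weight matrix.

    Step 1 divides each row (region) by its sum, normalizing away regional
    axonal length. Step 2 rescales every cell by k_classes/m so the grand
    total equals the number of classes. Step 3 divides each column (class)
    by its sum, normalizing away the number of invaded regions. Returns the
    step-3 matrix and a log of the intermediate totals.
    """
    A = np.asarray(raw_A, dtype=float)
    if A.ndim != 2:
        raise ValidationError("weight matrix must be 2-D (regions x classes)")
    if np.any(A < 0):
        raise ValidationError("weight matrix must be non-negative")
    m, k = A.shape
    row_sums = A.sum(axis=1)
    if np.any(row_sums == 0):
        bad = int(np.flatnonzero(row_sums == 0)[0])
        raise ValidationError(f"region row {bad} sums to zero")
    col_check = A.sum(axis=0)
    if np.any(col_check == 0):
        bad = int(np.flatnonzero(col_check == 0)[0])
        raise ValidationError(f"class column {bad} sums to zero")
    step1 = A / row_sums[:, None]
    step2 = step1 * (k / m)
    col_sums = step2.sum(axis=0)
    step3 = step2 / col_sums[None, :]
    log = {
        "total_step1": float(step1.sum()),  # = m
        "total_step2": float(step2.sum()),  # = k_classes by construction
        "column_sums_step2": col_sums.tolist(),
        "total_step3": float(step3.sum()),
    }
    return step3, log


@dataclass
class AbundanceProblem:
    """Bi-normalized regions x classes matrix A with normalized target b."""

    A: np.ndarray
    b: np.ndarray
    regions: list[str]
    class_labels: list[str]
    normalization_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        m, k = self.A.shape
        if self.b.shape != (m,):
            raise ValidationError(f"b must have length {m}, got {self.b.shape}")
        if np.any(self.A < 0) or np.any(self.b < 0):
            raise ValidationError("A and b must be non-negative")
        if len(self.regions) != m or len(self.class_labels) != k:
            raise ValidationError("region / class label lengths do not match A")


@dataclass
class AbundanceEstimate:
    x_raw: np.ndarray
    residual_sq: float
    class_labels: list[str]

    @property
    def fractions(self) -> np.ndarray:
        """x renormalized to sum 1 (reported as class percentages)."""
        total = self.x_raw.sum()
        if total == 0:
            return np.zeros_like(self.x_raw)
        return self.x_raw / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.class_labels)


def build_problem(
    matrix: ProjectionMatrix,
    assignment: Mapping[str, str],
    regional: pd.DataFrame,
) -> AbundanceProblem:
    """Assemble (A, b) from a count matrix, a class assignment, and the
    regional strength table (columns region, mean_volume, mean_density).

    Only regions present both in the matrix and in the regional table enter
    the problem (the cross-referencing rule). Per region, the target weight
    is mean projection volume times mean projection density, normalized to
    sum 1. Raw A sums the class members' count vectors per region and is
    then bi-normalized.
    """
    class_labels = sorted(set(assignment.values()))
    matrix_regions = [str(r) for r in matrix.regions]
    regional = regional.copy()
    regional["region"] = regional["region"].astype(str)
    strengths = {
        row.region: float(row.mean_volume) * float(row.mean_density)
        for row in regional.itertuples()
    }
    shared = [r for r in matrix_regions if r in strengths]
    if len(shared) < 2:
        raise ValidationError(
            "fewer than 2 regions shared between the matrix and regional table"
        )
    region_idx = [matrix_regions.index(r) for r in shared]
    raw_A = np.zeros((len(shared), len(class_labels)), dtype=float)
    for c, label in enumerate(class_labels):
        members = [n for n in matrix.neuron_ids if assignment.get(n) == label]
        if not members:
            raise ValidationError(f"class {label!r} has no member neurons")
        rows = [matrix.neuron_ids.index(n) for n in members]
        summed = matrix.counts[rows].sum(axis=0).astype(float)
        raw_A[:, c] = summed[region_idx]
    keep = raw_A.sum(axis=1) > 0  # regions untouched by every class cannot constrain x
    shared = [r for r, k in zip(shared, keep) if k]
    raw_A = raw_A[keep]
    A, log = binormalize(raw_A)
    b = np.array([strengths[r] for r in shared], dtype=float)
    if b.sum() == 0:
        raise ValidationError("regional strengths are all zero on shared regions")
    b = b / b.sum()
    return AbundanceProblem(A, b, shared, class_labels, log)


def nnls_solve(problem: AbundanceProblem) -> AbundanceEstimate:
    """Non-negative least squares fit of class fractions to regional strengths."""
    x, rnorm = _scipy_nnls(problem.A, problem.b)
    return AbundanceEstimate(
        x_raw=x, residual_sq=float(rnorm**2), class_labels=list(problem.class_labels)
    )


def afferent_composition(
    class_fractions: Sequence[float],
    class_profiles: pd.DataFrame,
    region: str,
    class_labels: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Share of a target region's afferents contributed by each class.

    ``class_profiles`` has one row per class and one column per region,
    each row a per-region fraction of that class's axonal extent. The
    share of class c is proportional to fraction(c) * profile(c, region),
    normalized over classes.
    """
    if class_labels is None:
        class_labels = list(class_profiles.index)
    fractions = np.asarray(class_fractions, dtype=float)
    if region not in class_profiles.columns:
        raise UndefinedCompositionError(f"region {region!r} not in class profiles")
    weights = fractions * class_profiles[region].to_numpy(dtype=float)
    total = weights.sum()
    if total <= 0:
        raise UndefinedCompositionError(
            f"no class projects to region {region!r}; composition undefined"
        )
    return pd.Series(weights / total, index=list(class_labels))
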