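"""Single-class "continuum" null via margin-preserving swap randomization.

The null hypothesis is that all neurons in a source region belong to one
projection class whose apparent diversity is random variation within the
constraints of regional connectivity. A null count matrix with exactly that
structure is produced by repeated stochastic unit swaps of axonal points
between two neurons across two target regions: pick rows i != j and columns
a != b, move one point (i,a)->(i,b) and (j,b)->(j,a). Every accepted move
preserves all row sums (per-neuron axonal size) and column sums (regional
targeting) and keeps counts non-negative; moves that would drive a cell
negative are rejected and do not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .errors import NullModelUndefinedError
from .matrix import ProjectionMatrix

#: Multiplier giving the default chain length: 10 accepted moves per axonal
#: point in the matrix, a generous mixing budget at desk scale.
DEFAULT_SWAPS_PER_POINT = 10

_SEED_MOD = 2**31


@dataclass(frozen=True)
class RandomizationConfig:
    """Chain length, seed, and number of pooled null replicates.

    ``n_swaps=None`` means the default of ``DEFAULT_SWAPS_PER_POINT`` times
    the matrix total. ``n_replicates`` independent randomized matrices are
    pooled when building a null distance distribution (1 reproduces a
    single randomized control matrix; more smooths the null).
    """

    seed: int
    n_swaps: Optional[int] = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_swaps is not None and self.n_swaps < 1:
            raise ValueError("n_swaps must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def resolve_swaps(self, matrix_total: int) -> int:
        if self.n_swaps is not None:
            return self.n_swaps
        return max(1, DEFAULT_SWAPS_PER_POINT * int(matrix_total))

    def replicate_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % _SEED_MOD for s in ss.generate_state(self.n_replicates)]


@njit(cache=True)
def _swap_chain(counts, n_swaps, seed, max_attempts):  # pragma: no cover - jit
    np.random.seed(seed)
    n, m = counts.shape
    accepted = 0
    attempts = 0
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i = np.random.randint(0, n)
        j = np.random.randint(0, n - 1)
        if j >= i:
            j += 1
        a = np.random.randint(0, m)
        b = np.random.randint(0, m - 1)
        if b >= a:
            b += 1
        # the unit move takes one point from (i,a) and one from (j,b)
        if counts[i, a] > 0 and counts[j, b] > 0:
            counts[i, a] -= 1
            counts[i, b] += 1
            counts[j, a] += 1
            counts[j, b] -= 1
            accepted += 1
    return accepted, attempts


@dataclass
class RandomizationReport:
    matrix: ProjectionMatrix
    n_accepted: int
    n_attempted: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0


def randomize(
    matrix: ProjectionMatrix,
    config: RandomizationConfig,
    seed_override: Optional[int] = None,
) -> RandomizationReport:
    """Return a randomized copy of ``matrix`` with identical margins.

    Applies exactly ``n_swaps`` accepted unit moves (rejections are free).
    Deterministic given the seed. Raises if the matrix has fewer than two
    rows or columns (a swap needs two neurons and two regions) or if the
    chain cannot find an acceptable move (e.g. all mass in one column).
    """
    if matrix.n_neurons < 2 or matrix.n_regions < 2:
        raise NullModelUndefinedError(
            "swap randomization needs >= 2 neurons and >= 2 regions, got "
            f"{matrix.n_neurons} x {matrix.n_regions}"
        )
    seed = config.seed if seed_override is None else seed_override
    n_swaps = config.resolve_swaps(int(matrix.counts.sum()))
    counts = np.ascontiguousarray(matrix.counts, dtype=np.int64).copy()
    max_attempts = 1000 * n_swaps
    accepted, attempted = _swap_chain(counts, n_swaps, seed % _SEED_MOD, max_attempts)
    if accepted < n_swaps:
        raise NullModelUndefinedError(
            f"swap chain stalled after {attempted} attempts "
            f"({accepted}/{n_swaps} accepted); the matrix admits too few moves"
        )
    randomized = ProjectionMatrix(
        list(matrix.neuron_ids), list(matrix.regions), counts
    )
    return RandomizationReport(randomized, accepted, attempted)


def randomized_replicates(
    matrix: ProjectionMatrix, config: RandomizationConfig
) -> list[RandomizationReport]:
    """Independent randomized matrices, one per configured replicate."""
    return [randomize(matrix, config, seed_override=s) for s in config.replicate_seeds()]
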