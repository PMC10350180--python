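"""Neuron x region axonal-count matrices and per-class projection profiles.

Each neuron is summarized as a k-dimensional vector of axonal-point counts,
one component per target parcel (optionally split into ipsilateral and
contralateral columns relative to the soma hemisphere). The matrix of these
vectors is the object the classifier operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reconstruction import NeuronReconstruction, Structure

_ML_AXES = ("x", "y", "z")


class Side(str, Enum):
    IPSI = "ipsi"
    CONTRA = "contra"
    UNSPLIT = "unsplit"


@dataclass(frozen=True, order=True)
class RegionLabel:
    """A target parcel, optionally qualified by hemisphere relative to the soma."""

    parcel_id: str
    side: Side = Side.UNSPLIT

    def __str__(self) -> str:
        if self.side is Side.UNSPLIT:
            return self.parcel_id
        return f"{self.parcel_id}:{self.side.value}"

    @classmethod
    def parse(cls, label: str) -> "RegionLabel":
        if ":" in label:
            parcel, side = label.rsplit(":", 1)
            if side in (Side.IPSI.value, Side.CONTRA.value):
                return cls(parcel, Side(side))
        return cls(label, Side.UNSPLIT)


@dataclass
class ProjectionMatrix:
    """Non-negative integer counts of axonal points per neuron per region."""

    neuron_ids: list[str]
    regions: list[RegionLabel]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.neuron_ids), len(self.regions)):
            raise ValidationError(
                f"count array shape {self.counts.shape} does not match "
                f"{len(self.neuron_ids)} neurons x {len(self.regions)} regions"
            )
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValidationError("duplicate neuron ids")
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("duplicate (parcel, side) region labels")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at neuron {self.neuron_ids[i]!r}, "
                f"region {self.regions[j]}"
            )

    # -- views -------------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def row(self, neuron_id: str) -> np.ndarray:
        return self.counts[self.neuron_ids.index(neuron_id)]

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.neuron_ids, name="neuron_id"),
            columns=[str(r) for r in self.regions],
        )

    def subset(
        self,
        neuron_ids: Optional[Sequence[str]] = None,
        drop_empty_regions: bool = False,
    ) -> "ProjectionMatrix":
        """Row subset (given neuron ids), optionally dropping all-zero columns."""
        if neuron_ids is None:
            neuron_ids = self.neuron_ids
        rows = [self.neuron_ids.index(n) for n in neuron_ids]
        counts = self.counts[rows]
        regions = list(self.regions)
        if drop_empty_regions:
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            regions = [r for r, k in zip(regions, keep) if k]
        return ProjectionMatrix(list(neuron_ids), regions, counts.copy())


@dataclass
class TabulationResult:
    """Output of :func:`tabulate`: the matrix plus everything set aside."""

    matrix: ProjectionMatrix
    source_collaterals: pd.DataFrame
    dropped_neurons: list[str] = field(default_factory=list)
    unassigned_nodes: dict[str, int] = field(default_factory=dict)
    hemisphere_split: bool = False


def _side_of(value: float, midline: float) -> int:
    # Points exactly on the midline count as ipsilateral.
    return 1 if value >= midline else -1


def tabulate(
    neurons: Iterable[NeuronReconstruction],
    midline: Optional[float] = None,
    split_hemispheres: bool = False,
    exclude_source: Optional[set[str]] = None,
    ml_axis: str = "z",
    include_unassigned: bool = False,
) -> TabulationResult:
    """Count axonal points per neuron per parcel.

    Every reconstruction node flagged as axon contributes one count to its
    parcel; nodes with the unassigned-parcel sentinel are kept in the tree
    but excluded from tabulation (their totals are reported). When
    ``split_hemispheres`` is set, each node is classed ipsi/contra by
    comparing the sign of (mediolateral coordinate - midline) with the
    soma's sign; ``midline`` is then required (it is atlas-specific and
    never assumed). Parcels listed in ``exclude_source`` are removed from
    the matrix columns and their counts reported separately as source
    collaterals. Neurons left with zero extra-source axonal counts are
    reported and dropped.
    """
    if ml_axis not in _ML_AXES:
        raise ValidationError(f"ml_axis must be one of {_ML_AXES}, got {ml_axis!r}")
    if split_hemispheres:
        if midline is None or not np.isfinite(midline):
            raise ValidationError("hemisphere splitting requires a finite midline")
    exclude_source = exclude_source or set()

    per_neuron: dict[str, dict[RegionLabel, int]] = {}
    collaterals: dict[str, dict[str, int]] = {}
    unassigned: dict[str, int] = {}
    for neuron in neurons:
        counts: dict[RegionLabel, int] = {}
        collat: dict[str, int] = {}
        soma_sign = (
            _side_of(getattr(neuron.soma, ml_axis), midline) if split_hemispheres else 0
        )
        n_unassigned = 0
        for node in neuron.nodes:
            if node.structure is not Structure.AXON:
                continue
            parcel = node.parcel_id
            from .reconstruction import UNASSIGNED_PARCEL

            if parcel == UNASSIGNED_PARCEL and not include_unassigned:
                n_unassigned += 1
                continue
            if parcel in exclude_source:
                collat[parcel] = collat.get(parcel, 0) + 1
                continue
            if split_hemispheres:
                side = (
                    Side.IPSI
                    if _side_of(getattr(node, ml_axis), midline) == soma_sign
                    else Side.CONTRA
                )
            else:
                side = Side.UNSPLIT
            label = RegionLabel(parcel, side)
            counts[label] = counts.get(label, 0) + 1
        if neuron.neuron_id in per_neuron:
            raise ValidationError(f"duplicate neuron id {neuron.neuron_id!r}")
        per_neuron[neuron.neuron_id] = counts
        collaterals[neuron.neuron_id] = collat
        if n_unassigned:
            unassigned[neuron.neuron_id] = n_unassigned

    dropped = [nid for nid, counts in per_neuron.items() if sum(counts.values()) == 0]
    kept = [nid for nid in per_neuron if nid not in dropped]
    regions = sorted({label for nid in kept for label in per_neuron[nid]})
    arr = np.zeros((len(kept), len(regions)), dtype=np.int64)
    region_pos = {label: j for j, label in enumerate(regions)}
    for i, nid in enumerate(kept):
        for label, c in per_neuron[nid].items():
            arr[i, region_pos[label]] = c

    collat_df = (
        pd.DataFrame.from_dict(collaterals, orient="index")
        .fillna(0)
        .astype(int)
        .rename_axis("neuron_id")
        .sort_index(axis=1)
    )
    matrix = ProjectionMatrix(kept, regions, arr)
    return TabulationResult(
        matrix=matrix,
        source_collaterals=collat_df,
        dropped_neurons=dropped,
        unassigned_nodes=unassigned,
        hemisphere_split=split_hemispheres,
    )


def class_profile(
    matrix: ProjectionMatrix,
    assignment: Mapping[str, str],
    class_label: str,
) -> pd.Series:
    """Per-region fraction of a class's total (extra-source) axonal count.

    Sums the class members' rows and divides by the class total, so the
    dominant entry answers questions like "what share of this class's
    axonal extent lands in its main target".
    """
    members = [nid for nid in matrix.neuron_ids if assignment.get(nid) == class_label]
    if not members:
        raise ValidationError(f"class {class_label!r} has no members in the matrix")
    rows = [matrix.neuron_ids.index(n) for n in members]
    totals = matrix.counts[rows].sum(axis=0).astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValidationError(f"class {class_label!r} has zero total count")
    return pd.Series(totals / grand, index=[str(r) for r in matrix.regions])
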