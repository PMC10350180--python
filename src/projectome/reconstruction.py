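"""Rooted-tree representation of a whole-brain single-neuron reconstruction.

A reconstruction is an ordered collection of 3D points in a common atlas
frame (µm), each carrying a structure flag (soma / axon / dendrite) and an
atlas parcel identifier. The soma is the root; every other node points to a
parent that appears earlier in traversal order. Axonal points are the raw
material for both the projection count matrix and soma-to-target path
distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .errors import StructuralError, ValidationError

#: Sentinel parcel for nodes whose atlas assignment is missing. Such nodes
#: stay in the tree (they carry cable for path distances) but are excluded
#: from count tabulation.
UNASSIGNED_PARCEL = "unassigned"


class Structure(str, Enum):
    SOMA = "soma"
    AXON = "axon"
    DENDRITE = "dendrite"


@dataclass(frozen=True)
class AxonalPoint:
    """One reconstruction node: 3D position, parent link, structure, parcel."""

    node_id: int
    x: float
    y: float
    z: float
    parent_id: Optional[int]  # None for the root (soma)
    structure: Structure
    parcel_id: str = UNASSIGNED_PARCEL

    def __post_init__(self) -> None:
        for axis, value in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not math.isfinite(value):
                raise ValidationError(
                    f"node {self.node_id}: non-finite {axis} coordinate {value!r}"
                )

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class NeuronReconstruction:
    """A neuron as a rooted tree of :class:`AxonalPoint`.

    Invariants (enforced by ``validate``, called on construction):

    * exactly one root (the soma, ``parent_id is None``);
    * every ``parent_id`` refers to a node that appears *earlier* in
      ``nodes``, so the tree is acyclic and connected by construction;
    * node ids are unique.
    """

    neuron_id: str
    nodes: list[AxonalPoint]
    soma_layer: Optional[str] = None
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise StructuralError(f"neuron {self.neuron_id}: empty reconstruction")
        seen: dict[int, int] = {}
        roots = 0
        for pos, node in enumerate(self.nodes):
            if node.node_id in seen:
                raise StructuralError(
                    f"neuron {self.neuron_id}: duplicate node id {node.node_id}"
                )
            if node.parent_id is None:
                roots += 1
                if pos != 0:
                    raise StructuralError(
                        f"neuron {self.neuron_id}: root node {node.node_id} "
                        "is not first in traversal order"
                    )
            elif node.parent_id not in seen:
                raise StructuralError(
                    f"neuron {self.neuron_id}: node {node.node_id} references "
                    f"parent {node.parent_id} that does not appear before it"
                )
            seen[node.node_id] = pos
        if roots != 1:
            raise StructuralError(
                f"neuron {self.neuron_id}: expected exactly one root, found {roots}"
            )
        self._index = seen

    # -- accessors ---------------------------------------------------------

    @property
    def soma(self) -> AxonalPoint:
        return self.nodes[0]

    @property
    def soma_parcel_id(self) -> str:
        return self.soma.parcel_id

    def node(self, node_id: int) -> AxonalPoint:
        try:
            return self.nodes[self._index[node_id]]
        except KeyError:
            raise StructuralError(
                f"neuron {self.neuron_id}: unknown node id {node_id}"
            ) from None

    def parent(self, node_id: int) -> Optional[AxonalPoint]:
        pid = self.node(node_id).parent_id
        return None if pid is None else self.node(pid)

    def axon_nodes(self) -> list[AxonalPoint]:
        return [n for n in self.nodes if n.structure is Structure.AXON]

    def __len__(self) -> int:
        return len(self.nodes)


def iter_axon_nodes(neurons: Iterable[NeuronReconstruction]):
    for neuron in neurons:
        for node in neuron.axon_nodes():
            yield neuron, node
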