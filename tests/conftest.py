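import json

import numpy as np
import pytest

from projectome import (
    AxonalPoint,
    NeuronReconstruction,
    ProjectionMatrix,
    RegionLabel,
    Structure,
)


def make_neuron(neuron_id, soma_xyz, axon_specs, soma_parcel="SRC", layer=None):
    """Build a neuron from (x, y, z, parent_offset, parcel) axon specs.

    ``parent_offset`` is the index into the node list (0 = soma) of the
    parent, so chains and branches are easy to write by hand.
    """
    nodes = [
        AxonalPoint(1, *soma_xyz, parent_id=None, structure=Structure.SOMA,
                    parcel_id=soma_parcel)
    ]
    for i, (x, y, z, parent_offset, parcel) in enumerate(axon_specs, start=2):
        nodes.append(
            AxonalPoint(i, x, y, z, parent_id=nodes[parent_offset].node_id,
                        structure=Structure.AXON, parcel_id=parcel)
        )
    return NeuronReconstruction(neuron_id, nodes, soma_layer=layer)


@pytest.fixture
def chain_neuron():
    """Soma at origin, two axon nodes in a 3-4-5 construction."""
    return make_neuron(
        "chain", (0, 0, 0),
        [(3, 0, 0, 0, "P"), (3, 4, 0, 1, "P")],
    )


@pytest.fixture
def branched_neuron():
    """Soma with two branches: one 2-node branch in P, one 3-node in Q."""
    return make_neuron(
        "branched", (0, 0, 0),
        [
            (10, 0, 0, 0, "P"),
            (20, 0, 0, 1, "P"),
            (0, 10, 0, 0, "Q"),
            (0, 20, 0, 3, "Q"),
            (0, 30, 0, 4, "Q"),
        ],
    )


@pytest.fixture
def small_matrix():
    return ProjectionMatrix(
        ["n1", "n2", "n3"],
        [RegionLabel("A"), RegionLabel("B")],
        np.array([[3, 4], [4, 3], [1, 0]]),
    )


def write_mouselight_json(path, neuron_id, soma, axon_nodes, parcel_key="allenId"):
    """Write a minimal MouseLight-style JSON file for parser tests."""
    payload = {
        "neuron": {
            "idString": neuron_id,
            "soma": {"sampleNumber": 1, **soma},
            "axon": [
                {"sampleNumber": sn, "x": x, "y": y, "z": z,
                 "parentNumber": parent, parcel_key: parcel}
                for sn, x, y, z, parent, parcel in axon_nodes
            ],
            "dendrite": [],
        }
    }
    path.write_text(json.dumps(payload))
    return path
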