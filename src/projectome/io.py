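"""Readers and writers for every external representation the tool touches.

* single-neuron reconstruction JSON (MouseLight-style dialect, see README),
* SWC morphology interchange,
* neuron x region count-matrix CSV (rows = neurons, columns = parcels),
* regional anterograde projection-strength CSV (region, mean_volume,
  mean_density),
* soma CSV (neuron_id, class, x, y, z, layer).

All CSVs are UTF-8 with a header row. Matrix CSV round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import MalformedInputError, StructuralError, ValidationError
from .matrix import ProjectionMatrix, RegionLabel
from .reconstruction import (
    UNASSIGNED_PARCEL,
    AxonalPoint,
    NeuronReconstruction,
    Structure,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Reconstruction JSON
# ---------------------------------------------------------------------------

@dataclass
class JsonSchema:
    """Key names of the reconstruction JSON dialect.

    Public single-neuron datasets use slightly different field names for the
    same content (e.g. ``allenId`` vs ``structureIdValue`` for the atlas
    parcel); the defaults accept either, and all names can be overridden.
    """

    neuron_key: str = "neuron"
    id_key: str = "idString"
    soma_key: str = "soma"
    axon_key: str = "axon"
    dendrite_key: str = "dendrite"
    node_id_key: str = "sampleNumber"
    parent_key: str = "parentNumber"
    parcel_keys: tuple[str, ...] = ("allenId", "structureIdValue")
    layer_key: str = "somaLayer"
    root_parent_values: tuple = (-1, None)


def _parcel_of(record: dict, schema: JsonSchema) -> str:
    for key in schema.parcel_keys:
        if key in record and record[key] is not None:
            return str(record[key])
    return UNASSIGNED_PARCEL


def _coords(record: dict, context: str) -> tuple[float, float, float]:
    try:
        return float(record["x"]), float(record["y"]), float(record["z"])
    except (KeyError, TypeError, ValueError) as exc:
        raise MalformedInputError(f"{context}: missing or non-numeric coordinate") from exc


def read_reconstruction_json(
    path: PathLike, schema: Optional[JsonSchema] = None
) -> NeuronReconstruction:
    """Read one neuron from a MouseLight-style JSON file.

    The file holds a neuron object with a soma record and lists of axon and
    dendrite nodes; each node carries x/y/z (µm, common atlas frame), a node
    id, a parent reference (root parent encoded as -1) and an atlas parcel
    id. Nodes without a parcel id are kept with the ``unassigned`` sentinel.
    """
    schema = schema or JsonSchema()
    with open(path) as fh:
        payload = json.load(fh)
    if schema.neuron_key in payload:
        obj = payload[schema.neuron_key]
    elif "neurons" in payload:
        neurons = payload["neurons"]
        if len(neurons) != 1:
            raise MalformedInputError(
                f"{path}: expected a single neuron, found {len(neurons)}"
            )
        obj = neurons[0]
    else:
        obj = payload

    neuron_id = str(obj.get(schema.id_key) or Path(path).stem)
    soma_rec = obj.get(schema.soma_key)
    if soma_rec is None:
        raise MalformedInputError(f"{path}: neuron {neuron_id} has no soma record")
    sx, sy, sz = _coords(soma_rec, f"{neuron_id} soma")
    soma_id = int(soma_rec.get(schema.node_id_key, 0))
    nodes = [
        AxonalPoint(
            node_id=soma_id,
            x=sx,
            y=sy,
            z=sz,
            parent_id=None,
            structure=Structure.SOMA,
            parcel_id=_parcel_of(soma_rec, schema),
        )
    ]
    for key, structure in (
        (schema.axon_key, Structure.AXON),
        (schema.dendrite_key, Structure.DENDRITE),
    ):
        for rec in obj.get(key) or []:
            context = f"{neuron_id} {structure.value} node {rec.get(schema.node_id_key)}"
            x, y, z = _coords(rec, context)
            try:
                node_id = int(rec[schema.node_id_key])
            except (KeyError, TypeError, ValueError) as exc:
                raise MalformedInputError(f"{context}: missing node id") from exc
            parent_raw = rec.get(schema.parent_key, -1)
            parent: Optional[int]
            if parent_raw in schema.root_parent_values:
                parent = soma_id
            else:
                parent = int(parent_raw)
            nodes.append(
                AxonalPoint(
                    node_id=node_id,
                    x=x,
                    y=y,
                    z=z,
                    parent_id=parent,
                    structure=structure,
                    parcel_id=_parcel_of(rec, schema),
                )
            )
    layer = obj.get(schema.layer_key)
    try:
        return NeuronReconstruction(
            neuron_id=neuron_id,
            nodes=nodes,
            soma_layer=None if layer is None else str(layer),
        )
    except StructuralError as exc:
        raise MalformedInputError(f"{path}: {exc}") from exc


def write_reconstruction_json(
    neuron: NeuronReconstruction, path: PathLike, schema: Optional[JsonSchema] = None
) -> None:
    """Write a neuron in the same JSON dialect ``read_reconstruction_json`` reads."""
    schema = schema or JsonSchema()
    parcel_key = schema.parcel_keys[0]

    def record(node: AxonalPoint) -> dict:
        rec = {
            schema.node_id_key: node.node_id,
            "x": node.x,
            "y": node.y,
            "z": node.z,
            schema.parent_key: -1
            if node.parent_id is None or node.parent_id == neuron.soma.node_id
            else node.parent_id,
        }
        if node.parcel_id != UNASSIGNED_PARCEL:
            rec[parcel_key] = node.parcel_id
        return rec

    soma = neuron.soma
    obj = {
        schema.id_key: neuron.neuron_id,
        schema.soma_key: {
            schema.node_id_key: soma.node_id,
            "x": soma.x,
            "y": soma.y,
            "z": soma.z,
            **(
                {parcel_key: soma.parcel_id}
                if soma.parcel_id != UNASSIGNED_PARCEL
                else {}
            ),
        },
        schema.axon_key: [
            record(n) for n in neuron.nodes if n.structure is Structure.AXON
        ],
        schema.dendrite_key: [
            record(n) for n in neuron.nodes if n.structure is Structure.DENDRITE
        ],
    }
    if neuron.soma_layer is not None:
        obj[schema.layer_key] = neuron.soma_layer
    with open(path, "w") as fh:
        json.dump({schema.neuron_key: obj}, fh, indent=1)


def read_reconstruction_dir(
    directory: PathLike, schema: Optional[JsonSchema] = None
) -> list[NeuronReconstruction]:
    """Read every ``*.json`` reconstruction in a directory, sorted by name."""
    paths = sorted(Path(directory).glob("*.json"))
    return [read_reconstruction_json(p, schema) for p in paths]


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

_SWC_TYPE = {Structure.SOMA: 1, Structure.AXON: 2, Structure.DENDRITE: 3}
_SWC_STRUCT = {1: Structure.SOMA, 2: Structure.AXON, 3: Structure.DENDRITE}


def export_swc(neuron: NeuronReconstruction, path: PathLike, radius: float = 1.0) -> None:
    """Write a standard 7-column SWC file (soma first, root parent = -1)."""
    with open(path, "w") as fh:
        fh.write(f"# neuron {neuron.neuron_id}\n")
        fh.write("# index type x y z radius parent\n")
        for node in neuron.nodes:
            parent = -1 if node.parent_id is None else node.parent_id
            fh.write(
                f"{node.node_id} {_SWC_TYPE[node.structure]} "
                f"{node.x:.6g} {node.y:.6g} {node.z:.6g} {radius:.6g} {parent}\n"
            )


def read_swc(path: PathLike, neuron_id: Optional[str] = None) -> NeuronReconstruction:
    """Read an SWC morphology (parcel information is not part of SWC)."""
    nodes: list[AxonalPoint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MalformedInputError(f"{path}:{lineno}: expected 7 columns")
            idx, typ, x, y, z, _radius, parent = parts
            structure = _SWC_STRUCT.get(int(typ), Structure.AXON)
            pid: Optional[int] = int(parent)
            if pid == -1:
                pid = None
            nodes.append(
                AxonalPoint(
                    node_id=int(idx),
                    x=float(x),
                    y=float(y),
                    z=float(z),
                    parent_id=pid,
                    structure=structure,
                )
            )
    return NeuronReconstruction(neuron_id or Path(path).stem, nodes)


# ---------------------------------------------------------------------------
# Count-matrix CSV
# ---------------------------------------------------------------------------

def read_matrix_csv(path: PathLike) -> ProjectionMatrix:
    """Read a neuron x region count matrix.

    Layout: header row of region labels (optionally ``parcel:ipsi`` /
    ``parcel:contra``), first column of neuron ids, remaining cells
    non-negative integers. Validation errors name the offending cell.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    neuron_ids = [str(i) for i in df.index]
    regions = [RegionLabel.parse(str(c)) for c in df.columns]
    counts = np.zeros(df.shape, dtype=np.int64)
    for i, nid in enumerate(neuron_ids):
        for j, col in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at neuron {nid!r}, "
                    f"region {col!r}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count {value} at neuron {nid!r}, region {col!r}"
                )
            counts[i, j] = value
    return ProjectionMatrix(neuron_ids, regions, counts)


def write_matrix_csv(matrix: ProjectionMatrix, path: PathLike) -> None:
    matrix.to_dataframe().to_csv(path)


# ---------------------------------------------------------------------------
# Soma and regional-strength CSVs
# ---------------------------------------------------------------------------

@dataclass
class SomaTable:
    """Per-neuron soma coordinates with class and layer labels."""

    frame: pd.DataFrame  # columns: neuron_id, class, x, y, z, layer

    def points(self, class_label: str) -> np.ndarray:
        sub = self.frame[self.frame["class"] == class_label]
        return sub[["x", "y", "z"]].to_numpy(dtype=float)

    def layers(self, class_label: str) -> list:
        sub = self.frame[self.frame["class"] == class_label]
        return list(sub["layer"])

    def classes(self) -> list[str]:
        return sorted(self.frame["class"].unique())


_SOMA_COLUMNS = ["neuron_id", "class", "x", "y", "z"]


def read_soma_csv(path: PathLike) -> SomaTable:
    df = pd.read_csv(path)
    missing = [c for c in _SOMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: soma CSV missing columns {missing}")
    if "layer" not in df.columns:
        df["layer"] = pd.NA
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = df.loc[~np.isfinite(coords).all(axis=1), "neuron_id"].tolist()
        raise ValidationError(f"{path}: non-finite soma coordinates for {bad}")
    return SomaTable(df[_SOMA_COLUMNS + ["layer"]].copy())


def write_soma_csv(table: SomaTable, path: PathLike) -> None:
    table.frame.to_csv(path, index=False)


def read_regional_csv(path: PathLike) -> pd.DataFrame:
    """Regional anterograde projection strengths: region, mean_volume, mean_density.

    These per-region averages over tracing experiments are the raw material
    for the deconvolution target vector b (volume x density per region).
    """
    df = pd.read_csv(path)
    required = ["region", "mean_volume", "mean_density"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: regional CSV missing columns {missing}")
    values = df[["mean_volume", "mean_density"]].to_numpy(dtype=float)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: regional strengths must be finite and >= 0")
    return df[required].copy()


# ---------------------------------------------------------------------------
# Assignment CSV
# ---------------------------------------------------------------------------

def read_assignment_csv(path: PathLike) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"neuron_id", "class"}.issubset(df.columns):
        raise ValidationError(f"{path}: assignment CSV needs neuron_id and class columns")
    return dict(zip(df["neuron_id"], df["class"]))


def write_assignment_csv(assignment: dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"neuron_id": list(assignment), "class": list(assignment.values())}
    ).to_csv(path, index=False)
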