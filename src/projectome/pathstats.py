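"""Soma-to-target path distances and divergence/convergence rank tests.

Path distance is cable length: the sum of Euclidean segment lengths along
the unique root-to-node path of the reconstruction tree (always at least
the straight-line soma-to-node distance). For each neuron and each target
region it invades, the median path distance over that neuron's axonal
points in the region is the unit of observation — neurons, not points, are
the independent replicates.

Two families of comparisons are run with two-sample rank-sum tests and
Benjamini–Hochberg FDR control at 0.05:

* divergence — within one class, compare per-neuron medians between every
  pair of its targets (ipsilateral and contralateral targets are never
  mixed, since contralateral paths are systematically longer);
* convergence — for one shared target, compare per-neuron medians between
  every pair of classes that reach it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import StructuralError, ValidationError
from .matrix import RegionLabel, Side, _side_of
from .reconstruction import UNASSIGNED_PARCEL, NeuronReconstruction, Structure

ALPHA_FDR = 0.05
#: Combined sample size up to which the exact rank-sum null is used.
EXACT_RANKSUM_MAX_N = 20


# ---------------------------------------------------------------------------
# Path distances
# ---------------------------------------------------------------------------

def path_distances_from_soma(neuron: NeuronReconstruction) -> dict[int, float]:
    """Cable distance from the soma to every node, keyed by node id."""
    dist: dict[int, float] = {}
    for node in neuron.nodes:
        if node.parent_id is None:
            dist[node.node_id] = 0.0
        else:
            parent = neuron.node(node.parent_id)
            step = math.dist(node.xyz, parent.xyz)
            dist[node.node_id] = dist[parent.node_id] + step
    return dist


def path_distance(neuron: NeuronReconstruction, node_id: int) -> float:
    """Cable distance from the soma to one node."""
    if node_id not in neuron._index:
        raise StructuralError(f"neuron {neuron.neuron_id}: unknown node {node_id}")
    total = 0.0
    node = neuron.node(node_id)
    while node.parent_id is not None:
        parent = neuron.node(node.parent_id)
        total += math.dist(node.xyz, parent.xyz)
        node = parent
    return total


@dataclass
class PathDistanceRecord:
    neuron_id: str
    class_label: str
    region: RegionLabel
    distances: np.ndarray
    median_distance: float


def collect_medians(
    neurons: Iterable[NeuronReconstruction],
    assignment: Mapping[str, str],
    midline: Optional[float] = None,
    split_hemispheres: bool = False,
    exclude_source: Optional[set[str]] = None,
    ml_axis: str = "z",
) -> list[PathDistanceRecord]:
    """One record per (neuron, invaded region): all path distances + median.

    Regions are labelled exactly as in matrix tabulation (same hemisphere
    convention); a neuron contributes no record for regions it does not
    invade. Unassigned-parcel nodes carry cable but produce no record.
    """
    exclude_source = exclude_source or set()
    records: list[PathDistanceRecord] = []
    for neuron in neurons:
        label = assignment.get(neuron.neuron_id)
        if label is None:
            continue
        dist = path_distances_from_soma(neuron)
        soma_sign = (
            _side_of(getattr(neuron.soma, ml_axis), midline)
            if split_hemispheres
            else 0
        )
        per_region: dict[RegionLabel, list[float]] = {}
        for node in neuron.nodes:
            if node.structure is not Structure.AXON:
                continue
            if node.parcel_id == UNASSIGNED_PARCEL or node.parcel_id in exclude_source:
                continue
            if split_hemispheres:
                side = (
                    Side.IPSI
                    if _side_of(getattr(node, ml_axis), midline) == soma_sign
                    else Side.CONTRA
                )
            else:
                side = Side.UNSPLIT
            per_region.setdefault(RegionLabel(node.parcel_id, side), []).append(
                dist[node.node_id]
            )
        for region, values in sorted(per_region.items()):
            arr = np.asarray(values, dtype=float)
            records.append(
                PathDistanceRecord(
                    neuron_id=neuron.neuron_id,
                    class_label=label,
                    region=region,
                    distances=arr,
                    median_distance=float(np.median(arr)),
                )
            )
    return records


def records_to_frame(records: Sequence[PathDistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in records],
            "class": [r.class_label for r in records],
            "region": [str(r.region) for r in records],
            "side": [r.region.side.value for r in records],
            "n_points": [len(r.distances) for r in records],
            "median_distance": [r.median_distance for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Rank tests with FDR control
# ---------------------------------------------------------------------------

def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    method = "exact" if len(x) + len(y) <= EXACT_RANKSUM_MAX_N else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TestResult:
    comparison: str  # "<group1> vs <group2> @ <context>"
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_raw: float
    q_fdr: float = float("nan")
    significant: bool = False
    direction: str = ""  # "<smaller-median group> shorter" or "no difference"


def _direction(label_a: str, label_b: str, med_a: float, med_b: float) -> str:
    if med_a < med_b:
        return f"{label_a} shorter than {label_b}"
    if med_b < med_a:
        return f"{label_b} shorter than {label_a}"
    return "no median difference"


def _run_family(
    groups: dict[str, np.ndarray], context: str, min_n: int = 2
) -> tuple[list[TestResult], list[str]]:
    """All pairwise rank-sum tests within one BH family."""
    notices = []
    usable = {}
    for name, values in groups.items():
        if len(values) < min_n:
            notices.append(
                f"{name} @ {context}: only {len(values)} medians; excluded"
            )
        else:
            usable[name] = np.asarray(values, dtype=float)
    names = sorted(usable)
    results: list[TestResult] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            stat, p = _ranksum(usable[a], usable[b])
            results.append(
                TestResult(
                    comparison=f"{a} vs {b} @ {context}",
                    group_a=a,
                    group_b=b,
                    n_a=len(usable[a]),
                    n_b=len(usable[b]),
                    statistic=stat,
                    p_raw=p,
                    direction=_direction(
                        a, b, float(np.median(usable[a])), float(np.median(usable[b]))
                    ),
                )
            )
    if results:
        q = fdr_adjust([r.p_raw for r in results])
        for r, qv in zip(results, q):
            r.q_fdr = float(qv)
            r.significant = bool(qv < ALPHA_FDR)
    return results, notices


def divergence_test(
    records: Sequence[PathDistanceRecord],
    class_label: str,
    targets: Optional[Sequence[RegionLabel]] = None,
) -> tuple[list[TestResult], list[str]]:
    """Within one class, compare per-neuron median path distances between
    every pair of its target regions (same hemisphere side only). One BH
    family per class."""
    class_records = [r for r in records if r.class_label == class_label]
    if targets is not None:
        wanted = set(targets)
        class_records = [r for r in class_records if r.region in wanted]
    by_target: dict[RegionLabel, list[float]] = {}
    for r in class_records:
        by_target.setdefault(r.region, []).append(r.median_distance)

    results: list[TestResult] = []
    notices: list[str] = []
    raw: list[TestResult] = []
    for side in (Side.IPSI, Side.CONTRA, Side.UNSPLIT):
        side_groups = {
            str(region): np.asarray(vals, dtype=float)
            for region, vals in by_target.items()
            if region.side is side
        }
        if not side_groups:
            continue
        fam, notes = _run_family(side_groups, f"class {class_label}")
        raw.extend(fam)
        notices.extend(notes)
    # one FDR family per class across all its tested target pairs
    if raw:
        q = fdr_adjust([r.p_raw for r in raw])
        for r, qv in zip(raw, q):
            r.q_fdr = float(qv)
            r.significant = bool(qv < ALPHA_FDR)
        results = raw
    return results, notices


def convergence_test(
    records: Sequence[PathDistanceRecord],
    target: RegionLabel,
) -> tuple[list[TestResult], list[str]]:
    """For one shared target, compare per-neuron median path distances
    between every pair of classes reaching it. One BH family per target."""
    target_records = [r for r in records if r.region == target]
    by_class: dict[str, list[float]] = {}
    for r in target_records:
        by_class.setdefault(r.class_label, []).append(r.median_distance)
    if len(by_class) < 2:
        return [], [
            f"target {target}: only {len(by_class)} class(es) reach it; no test"
        ]
    groups = {c: np.asarray(v, dtype=float) for c, v in by_class.items()}
    return _run_family(groups, f"target {target}")


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "q_fdr": [r.q_fdr for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    )
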