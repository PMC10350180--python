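"""Soma topography: convex-hull volumes, outlier removal, and overlaps.

Whether two projection classes occupy distinct territory in the source
region is quantified by the ratio of the intersection volume to the union
volume of the two classes' soma convex hulls, after a volume-leverage
outlier sweep. The intersection of two convex hulls is itself convex, so
it is computed exactly as the half-space intersection of both hulls'
facet inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .errors import DegenerateGeometryError, ValidationError

#: Fewest points that can span a 3D convex hull.
MIN_HULL_POINTS = 4


@dataclass
class SomaSet:
    """Soma center coordinates (µm) of one class, with optional layer labels."""

    class_label: str
    points: np.ndarray
    layers: Optional[list] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(
                f"class {self.class_label}: points must be n x 3, "
                f"got {self.points.shape}"
            )
        if self.points.shape[0] < 1:
            raise ValidationError(f"class {self.class_label}: empty soma set")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(f"class {self.class_label}: non-finite coordinates")
        if self.layers is not None and len(self.layers) != len(self.points):
            raise ValidationError(
                f"class {self.class_label}: {len(self.layers)} layer labels for "
                f"{len(self.points)} points"
            )

    def __len__(self) -> int:
        return len(self.points)


def _hull_volume(points: np.ndarray) -> float:
    if len(points) < MIN_HULL_POINTS:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0  # coplanar / collinear point set has no 3D volume


def remove_hull_outliers(soma: SomaSet, sequential: bool = False) -> SomaSet:
    """Drop points whose removal changes the hull volume by more than V/n.

    Default is a single sweep: every point is tested against the FULL-set
    hull volume V (leave-one-out volume differing from V by more than V/n
    flags the point), and all flagged points are removed together. If the
    sweep would leave fewer than four points — the minimum for a 3D hull —
    the original set is returned unchanged. ``sequential=True`` instead
    repeats the sweep on the reduced set until no point is flagged.
    """
    points = soma.points
    n = len(points)
    if n < MIN_HULL_POINTS:
        return soma
    V = _hull_volume(points)
    if V == 0.0:
        return soma  # degenerate hull: no volume criterion to apply

    def flagged(pts: np.ndarray, volume: float) -> np.ndarray:
        diffs = np.array(
            [abs(volume - _hull_volume(np.delete(pts, i, axis=0)))
             for i in range(len(pts))]
        )
        return diffs > volume / len(pts)

    keep = ~flagged(points, V)
    if keep.sum() < MIN_HULL_POINTS:
        return soma
    if sequential:
        while True:
            pts = points[keep]
            vol = _hull_volume(pts)
            if vol == 0.0:
                break
            flags = flagged(pts, vol)
            if not flags.any() or (len(pts) - flags.sum()) < MIN_HULL_POINTS:
                break
            idx = np.flatnonzero(keep)
            keep[idx[flags]] = False
    layers = (
        None
        if soma.layers is None
        else [lab for lab, k in zip(soma.layers, keep) if k]
    )
    return SomaSet(soma.class_label, points[keep], layers)


def _halfspaces(hull: ConvexHull) -> np.ndarray:
    # each facet row is [a, b, c, d] with a*x + b*y + c*z + d <= 0 inside
    return hull.equations


def _interior_point(halfspaces: np.ndarray) -> Optional[np.ndarray]:
    """Chebyshev center of the polytope; None if empty (or measure zero)."""
    norms = np.linalg.norm(halfspaces[:, :-1], axis=1, keepdims=True)
    c = np.zeros(4)
    c[-1] = -1.0  # maximize the inscribed radius
    A_ub = np.hstack([halfspaces[:, :-1], norms])
    b_ub = -halfspaces[:, -1]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * 3 + [(0, None)],
                  method="highs")
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


@dataclass
class OverlapResult:
    class_a: str
    class_b: str
    volume_a: float
    volume_b: float
    volume_intersection: float
    volume_union: float
    ratio: float
    empty_intersection: bool = False


def hull_overlap(a: SomaSet, b: SomaSet) -> OverlapResult:
    """Exact intersection/union volume ratio of two soma hulls.

    The intersection polytope is the half-space intersection of both
    hulls' facets, seeded by its Chebyshev center; an empty or measure-zero
    intersection yields ratio 0 with a flag rather than an error (the
    near-complete-segregation case). Degenerate input hulls (fewer than 4
    points or coplanar) are an error.
    """
    hulls = []
    for s in (a, b):
        if len(s) < MIN_HULL_POINTS:
            raise DegenerateGeometryError(
                f"class {s.class_label}: needs >= {MIN_HULL_POINTS} points for a hull"
            )
        try:
            hulls.append(ConvexHull(s.points))
        except QhullError as exc:
            raise DegenerateGeometryError(
                f"class {s.class_label}: degenerate point set ({exc})"
            ) from exc
    vol_a, vol_b = (float(h.volume) for h in hulls)
    combined = np.vstack([_halfspaces(h) for h in hulls])
    interior = _interior_point(combined)
    if interior is None:
        return OverlapResult(a.class_label, b.class_label, vol_a, vol_b,
                             0.0, vol_a + vol_b, 0.0, empty_intersection=True)
    try:
        intersection = HalfspaceIntersection(combined, interior)
        vol_i = float(ConvexHull(intersection.intersections).volume)
    except QhullError:
        return OverlapResult(a.class_label, b.class_label, vol_a, vol_b,
                             0.0, vol_a + vol_b, 0.0, empty_intersection=True)
    vol_u = vol_a + vol_b - vol_i
    return OverlapResult(a.class_label, b.class_label, vol_a, vol_b,
                         vol_i, vol_u, vol_i / vol_u)


def layer_composition(soma: SomaSet) -> pd.DataFrame:
    """Counts and fractions of somata per layer label."""
    if soma.layers is None:
        raise ValidationError(f"class {soma.class_label}: no layer labels")
    missing = [i for i, lab in enumerate(soma.layers) if lab is None or lab != lab]
    if missing:
        raise ValidationError(
            f"class {soma.class_label}: unlabeled points at indices {missing}"
        )
    series = pd.Series(soma.layers).value_counts().sort_index()
    return pd.DataFrame(
        {"count": series, "fraction": series / series.sum()}
    ).rename_axis("layer")


@dataclass
class HullReport:
    """Per-class hulls after outlier removal plus all pairwise overlaps."""

    per_class: pd.DataFrame  # class, n_points, n_removed, volume
    pairwise: pd.DataFrame  # class_a, class_b, volumes, ratio, empty flag
    retained: dict[str, SomaSet] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def hull_report(
    soma_sets: Sequence[SomaSet], sequential_outliers: bool = False
) -> HullReport:
    """Outlier-swept hull volumes for every class and overlap for every pair."""
    retained = {}
    rows = []
    for soma in soma_sets:
        kept = remove_hull_outliers(soma, sequential=sequential_outliers)
        retained[soma.class_label] = kept
        rows.append(
            {
                "class": soma.class_label,
                "n_points": len(kept),
                "n_removed": len(soma) - len(kept),
                "volume": _hull_volume(kept.points),
            }
        )
    pair_rows = []
    labels = [s.class_label for s in soma_sets]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            result = hull_overlap(retained[labels[i]], retained[labels[j]])
            pair_rows.append(
                {
                    "class_a": result.class_a,
                    "class_b": result.class_b,
                    "volume_a": result.volume_a,
                    "volume_b": result.volume_b,
                    "volume_intersection": result.volume_intersection,
                    "volume_union": result.volume_union,
                    "ratio": result.ratio,
                    "empty_intersection": result.empty_intersection,
                }
            )
    return HullReport(pd.DataFrame(rows), pd.DataFrame(pair_rows), retained)
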