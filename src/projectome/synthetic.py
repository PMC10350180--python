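"""Synthetic fixtures with the statistical structure the method assumes.

Three generators, all driven by one seeded NumPy generator:

* class-structured neuron x region count matrices (Dirichlet-multinomial:
  each class has a region-weight profile; a neuron draws its region
  proportions from Dirichlet(concentration x profile) and its counts from
  a multinomial over a log-normal axonal total);
* toy tree morphologies whose region-labelled axonal tips sit at
  controlled path distances from the soma (class- and region-specific
  offsets plus noise), for path-distance analyses;
* class-specific 3D Gaussian soma clouds with layer labels assigned by
  thresholds on one axis, for topography analyses.

The Dirichlet-multinomial is the minimal over-dispersed count model that
reproduces the within-class/between-class distance picture the classifier
is built around; the default concentration is calibrated so that a
single-class draw sits on the swap-randomization continuum (see
docs/methods.md for the calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import SomaTable
from .matrix import ProjectionMatrix, RegionLabel
from .reconstruction import AxonalPoint, NeuronReconstruction, Structure

#: Dirichlet concentration multiplier: within-class dispersion of region
#: proportions (alpha = concentration x profile). The default, ``None``,
#: resolves to 1.25 x n_regions, the dispersion at which a single-class
#: draw sits on the margin-preserving swap continuum: the root gate's
#: realized false-split rate then matches its nominal level (calibrated at
#: the 50-neuron, 12-region reference condition; see docs/methods.md).
DEFAULT_CONCENTRATION = None
CONCENTRATION_PER_REGION = 1.25
#: Log-normal parameters of per-neuron total axonal points
#: (median exp(6.9) ~ 1000 points, a realistic reconstruction scale).
DEFAULT_LOG_TOTAL_MEAN = 6.9
DEFAULT_LOG_TOTAL_SIGMA = 0.5
#: Share of a class's profile mass on its own preferred regions.
DEFAULT_DOMINANT_SHARE = 0.75


def default_profiles(
    k_classes: int,
    n_regions: int,
    dominant_share: float = DEFAULT_DOMINANT_SHARE,
    disjoint: bool = False,
) -> np.ndarray:
    """Class region-weight profiles: each class prefers its own block of
    regions (share ``dominant_share``), spreading the rest uniformly.
    ``disjoint=True`` removes the background entirely (orthogonal supports).
    """
    if k_classes < 1 or n_regions < max(2, k_classes):
        raise ValidationError(
            f"need n_regions >= max(2, k_classes), got {k_classes} x {n_regions}"
        )
    profiles = np.zeros((k_classes, n_regions))
    block = n_regions // k_classes
    for c in range(k_classes):
        lo = c * block
        hi = n_regions if c == k_classes - 1 else (c + 1) * block
        own = np.arange(lo, hi)
        if disjoint:
            profiles[c, own] = 1.0 / len(own)
        else:
            profiles[c, :] = (1.0 - dominant_share) / n_regions
            profiles[c, own] += dominant_share / len(own)
    return profiles / profiles.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    """Study conditions for the generators. All randomness flows from ``seed``."""

    seed: int
    k_classes: int = 2
    neurons_per_class: int | Sequence[int] = 30
    n_regions: int = 12
    profiles: Optional[np.ndarray] = None  # k_classes x n_regions, rows sum to 1
    concentration: Optional[float] = DEFAULT_CONCENTRATION  # None -> n_regions
    log_total_mean: float = DEFAULT_LOG_TOTAL_MEAN
    log_total_sigma: float = DEFAULT_LOG_TOTAL_SIGMA
    # --- morphology / soma parameters -----------------------------------
    soma_means: Optional[np.ndarray] = None  # k_classes x 3 (µm)
    soma_sigma: float = 100.0  # isotropic cloud SD (µm)
    path_offsets: Optional[np.ndarray] = None  # k_classes x n_regions (µm)
    path_noise_sd: float = 0.0  # per-point jitter on path length (µm)
    points_per_region: int = 5
    tip_spacing: float = 20.0  # symmetric spacing of tips around the offset (µm)
    layer_thresholds: tuple[float, float] = (-50.0, 50.0)  # on y, cloud-relative
    layer_names: tuple[str, str, str] = ("L1", "L2", "L3")

    def __post_init__(self) -> None:
        if self.k_classes < 1:
            raise ValidationError("k_classes must be >= 1")
        if np.isscalar(self.neurons_per_class):
            self.neurons_per_class = [int(self.neurons_per_class)] * self.k_classes
        self.neurons_per_class = [int(n) for n in self.neurons_per_class]
        if len(self.neurons_per_class) != self.k_classes:
            raise ValidationError("neurons_per_class length must equal k_classes")
        if any(n < 1 for n in self.neurons_per_class):
            raise ValidationError("neurons_per_class entries must be >= 1")
        if self.profiles is None:
            self.profiles = default_profiles(self.k_classes, self.n_regions)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (self.k_classes, self.n_regions):
            raise ValidationError(
                f"profiles must be {self.k_classes} x {self.n_regions}"
            )
        if np.any(self.profiles < 0):
            raise ValidationError("profiles must be non-negative")
        if self.concentration is None:
            self.concentration = CONCENTRATION_PER_REGION * self.n_regions
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")

    def region_names(self) -> list[str]:
        return [f"R{j:02d}" for j in range(self.n_regions)]

    def neuron_ids(self) -> list[str]:
        ids = []
        for c, n in enumerate(self.neurons_per_class):
            ids.extend(f"S{c}{i:03d}" for i in range(n))
        return ids

    def true_labels(self) -> dict[str, str]:
        labels = {}
        for c, n in enumerate(self.neurons_per_class):
            for i in range(n):
                labels[f"S{c}{i:03d}"] = f"class_{c}"
        return labels


def generate_matrix(config: SyntheticConfig) -> tuple[ProjectionMatrix, dict[str, str]]:
    """Dirichlet-multinomial count matrix plus the planted class labels."""
    rng = np.random.default_rng(config.seed)
    region_labels = [RegionLabel(r) for r in config.region_names()]
    rows = []
    for c, n in enumerate(config.neurons_per_class):
        alpha = config.profiles[c] * config.concentration
        alpha = np.where(alpha > 0, alpha, 1e-9)  # Dirichlet needs positive alpha
        for _ in range(n):
            total = max(1, int(round(rng.lognormal(
                config.log_total_mean, config.log_total_sigma))))
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(total, p))
    counts = np.asarray(rows, dtype=np.int64)
    matrix = ProjectionMatrix(config.neuron_ids(), region_labels, counts)
    return matrix, config.true_labels()


def _default_soma_means(k_classes: int, spacing: float = 400.0) -> np.ndarray:
    means = np.zeros((k_classes, 3))
    means[:, 0] = spacing * np.arange(k_classes)
    return means


def generate_morphologies(
    config: SyntheticConfig,
) -> tuple[list[NeuronReconstruction], SomaTable]:
    """Toy rooted trees with region-labelled tips at controlled path distances.

    Each neuron grows one straight branch per region its class targets
    (positive path offset); tips along a branch are spaced symmetrically
    around the configured offset, so with zero noise the per-neuron median
    path distance to a region equals the offset exactly. Somata are drawn
    from the class's Gaussian cloud; layers are assigned by thresholding
    the soma's y coordinate relative to the class cloud center.
    """
    rng = np.random.default_rng(config.seed)
    soma_means = (
        _default_soma_means(config.k_classes)
        if config.soma_means is None
        else np.asarray(config.soma_means, dtype=float)
    )
    offsets = config.path_offsets
    if offsets is None:
        # default: each targeted region at 1000 + 500*j µm, shared by classes
        offsets = np.where(
            config.profiles > 1e-12,
            1000.0 + 500.0 * np.arange(config.n_regions)[None, :],
            0.0,
        )
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (config.k_classes, config.n_regions):
        raise ValidationError(
            f"path_offsets must be {config.k_classes} x {config.n_regions}"
        )
    regions = config.region_names()
    t1, t2 = config.layer_thresholds
    neurons: list[NeuronReconstruction] = []
    soma_rows = []
    for c, n in enumerate(config.neurons_per_class):
        for i in range(n):
            nid = f"S{c}{i:03d}"
            soma_xyz = rng.normal(soma_means[c], config.soma_sigma)
            dy = soma_xyz[1] - soma_means[c][1]
            layer = (
                config.layer_names[0]
                if dy < t1
                else config.layer_names[1] if dy < t2 else config.layer_names[2]
            )
            nodes = [
                AxonalPoint(1, *soma_xyz, parent_id=None, structure=Structure.SOMA)
            ]
            next_id = 2
            m = config.points_per_region
            centered = config.tip_spacing * (np.arange(m) - (m - 1) / 2.0)
            for j, region in enumerate(regions):
                L = offsets[c, j]
                if L <= 0:
                    continue
                targets = L + centered + rng.normal(0, config.path_noise_sd, size=m)
                targets = np.sort(np.maximum(targets, 1.0))
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                parent = 1
                for t in targets:
                    xyz = soma_xyz + direction * t
                    nodes.append(
                        AxonalPoint(
                            next_id,
                            *xyz,
                            parent_id=parent,
                            structure=Structure.AXON,
                            parcel_id=region,
                        )
                    )
                    parent = next_id
                    next_id += 1
            neurons.append(
                NeuronReconstruction(neuron_id=nid, nodes=nodes, soma_layer=layer)
            )
            soma_rows.append(
                {
                    "neuron_id": nid,
                    "class": f"class_{c}",
                    "x": soma_xyz[0],
                    "y": soma_xyz[1],
                    "z": soma_xyz[2],
                    "layer": layer,
                }
            )
    return neurons, SomaTable(pd.DataFrame(soma_rows))
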