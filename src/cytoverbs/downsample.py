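"""Per-group cell downsampling: constant count, proportion, or density
equalization.

All three strategies honor the table's active ``group_keys`` (set with
:func:`~cytoverbs.table.group_cells`); an ungrouped table is one group.
Output rows are always a subset of input rows in their original relative
order, and identical ``(table, parameters, seed)`` always yields identical
output: each group draws from its own random stream derived from the seed
and a stable hash of the group key, so group order cannot change results.

The density strategy is the SPADE-style scheme: estimate each cell's local
density as its fixed-radius neighbor count, discard the sparsest cells as
outliers, keep low-density cells outright, and keep high-density cells with
probability inversely proportional to their density so that retained
density is equalized at the target level.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError, TooFewCellsError
from .table import CytoTable, _grouped_indices, channel_matrix

_AUTO_KNN = 15  # auto-radius: median distance to this nearest neighbor


@dataclass
class DensitySpec:
    """Parameters of density-dependent downsampling.

    channels
        Channel subset defining the metric space (default: all markers).
    outlier_percentile
        Density quantile below which cells are discarded as outliers.
    target_percentile
        Density quantile at which retained density is equalized.
    radius
        Fixed neighbor-counting radius, or "auto" for the median distance
        to the 15th nearest neighbor.
    """

    channels: Sequence[str] | None = None
    outlier_percentile: float = 0.01
    target_percentile: float = 0.10
    radius: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_percentile", "target_percentile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if not self.outlier_percentile < self.target_percentile:
            raise ParameterError(
                "outlier_percentile must be below target_percentile "
                f"({self.outlier_percentile} >= {self.target_percentile})"
            )
        if self.radius != "auto" and not float(self.radius) > 0:
            raise ParameterError(f"radius must be positive or 'auto', got {self.radius}")


def _group_rng(seed: int, key: object) -> np.random.Generator:
    """Group-scoped stream: stable across platforms and group order."""
    digest = hashlib.blake2s(repr(key).encode(), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")])
    )


def _take(table: CytoTable, rows: np.ndarray) -> CytoTable:
    rows = np.sort(rows)  # preserve original relative order
    out = table.iloc[rows].reset_index(drop=True)
    return CytoTable(out, panel=table.panel, group_keys=list(table.group_keys))


def downsample_constant(table: CytoTable, n: int, seed: int = 0) -> CytoTable:
    """Simple random sample of ``min(n, group size)`` cells per group."""
    if not isinstance(n, (int, np.integer)) or n <= 0:
        raise ParameterError(f"n must be a positive integer, got {n}")
    keep: list[np.ndarray] = []
    for key, idx in _grouped_indices(table):
        if len(idx) <= n:
            if len(idx) < n:
                warnings.warn(
                    f"group {key!r} has only {len(idx)} cells (< n={n}); keeping all",
                    stacklevel=2,
                )
            keep.append(idx)
        else:
            rng = _group_rng(seed, key)
            keep.append(rng.choice(idx, size=n, replace=False))
    return _take(table, np.concatenate(keep))


def downsample_proportional(table: CytoTable, prop: float, seed: int = 0) -> CytoTable:
    """Keep ``round(prop * group size)`` cells per group (round half to even)."""
    if not 0.0 < prop <= 1.0:
        raise ParameterError(f"prop must lie in (0, 1], got {prop}")
    if prop == 1.0:
        return _take(table, np.arange(len(table)))
    keep: list[np.ndarray] = []
    for key, idx in _grouped_indices(table):
        n = int(np.round(prop * len(idx)))
        rng = _group_rng(seed, key)
        keep.append(rng.choice(idx, size=min(n, len(idx)), replace=False))
    return _take(table, np.concatenate(keep))


def local_density(points: np.ndarray, radius: float | str = "auto") -> np.ndarray:
    """Local density of each point: count of points (self included) within
    Euclidean distance ``radius``.  Exact, via a k-d tree."""
    tree = cKDTree(points)
    if radius == "auto":
        k = min(_AUTO_KNN + 1, len(points))  # +1: query includes self
        dists, _ = tree.query(points, k=k)
        radius = float(np.median(dists[:, -1]))
        if radius == 0.0:
            # degenerate cloud (coincident points): any positive radius
            # counts all coincident neighbors
            radius = np.finfo(float).eps
    counts = tree.query_ball_point(points, r=float(radius), return_length=True)
    return np.asarray(counts, dtype=np.float64)


def downsample_density(table: CytoTable, spec: DensitySpec) -> CytoTable:
    """SPADE-style density equalization within each group.

    Per group: densities ``d_i`` are fixed-radius neighbor counts; cells
    below the outlier-percentile density OD are dropped, cells at or below
    the target-percentile density TD are kept, and denser cells survive
    independently with probability ``TD / d_i``.
    """
    keep: list[np.ndarray] = []
    for key, idx in _grouped_indices(table):
        if len(idx) < 20:
            raise TooFewCellsError(
                f"group {key!r} has {len(idx)} cells; density downsampling needs >= 20"
            )
        sub = _take(table, idx)
        pts = channel_matrix(sub, spec.channels)
        d = local_density(pts, spec.radius)
        # inverse empirical CDF: densities are discrete counts, and linear
        # interpolation between well-separated density modes would place the
        # target mid-gap instead of at an observed density
        od = np.quantile(d, spec.outlier_percentile, method="inverted_cdf")
        td = np.quantile(d, spec.target_percentile, method="inverted_cdf")
        rng = _group_rng(spec.seed, key)
        u = rng.random(len(idx))
        survive = (d >= od) & ((d <= td) | (u < td / d))
        keep.append(idx[survive])
    return _take(table, np.concatenate(keep))
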