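"""Ground-truth-labeled synthetic cytometry cohorts.

The generator emulates a two-arm mass-cytometry case/control study as a
Gaussian mixture on the arcsinh scale: each cluster (cell population) has a
mean marker signature drawn once from uniform[0, 4]; cells scatter around
it with spherical s.d. 0.3.  Per-sample cluster proportions are Dirichlet
(concentration 50 x base proportions), and an optional planted effect
shifts one cluster's proportion or one marker's expression in arm B only.
Raw instrument-scale counts are produced by the inverse transform
(cofactor * sinh) plus uniform(-0.5, 0.5) acquisition randomization noise
clamped at zero — so the package's own preprocessing pipeline recovers the
asinh-scale values up to count discretization.

Everything is driven by one seed; every sample derives its own stream from
(seed, sample index), so cohorts are fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fcs import write_fcs
from .table import CytoTable, Panel, PanelEntry

_MARKER_POOL = [
    "CD45", "CD3", "CD4", "CD8", "CD19", "CD20", "CD33", "CD34", "CD38",
    "CD45RA", "CD56", "CD90", "CD123", "HLA-DR", "CD11b", "CD14", "CD16",
    "CD25", "CD127", "TCRgd",
]


def default_marker_names(n: int) -> list[str]:
    names = list(_MARKER_POOL[:n])
    while len(names) < n:
        names.append(f"marker{len(names) + 1:02d}")
    return names


@dataclass
class Effect:
    """Planted between-arm difference on one target cluster."""

    target_cluster: int  # 1-based cluster id
    proportion_delta: float | None = None
    expression_delta: float | None = None
    marker: str | None = None  # required with expression_delta


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a modest two-arm CyTOF study: 10 samples per arm,
    8 cell populations over 10 markers, 1000 cells per sample, population
    signatures uniform[0, 4] on the arcsinh scale with s.d. 0.3, and
    per-sample Dirichlet proportion noise at concentration 50.
    """

    n_samples_per_arm: int = 10
    n_clusters: int = 8
    n_markers: int = 10
    cells_per_sample: int = 1000
    cluster_means: np.ndarray | None = None  # clusters x markers, asinh scale
    cluster_sd: float = 0.3
    concentration: float = 50.0
    base_proportions: np.ndarray | None = None  # defaults to uniform
    effect: Effect | None = None
    cofactor: float = 5.0
    seed: int = 0
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_samples_per_arm, self.n_clusters, self.n_markers,
               self.cells_per_sample) < 1:
            raise ParameterError("cohort dimensions must be positive")
        if self.cluster_sd < 0:
            raise ParameterError("cluster_sd must be non-negative")
        if not self.marker_names:
            self.marker_names = default_marker_names(self.n_markers)
        if len(self.marker_names) != self.n_markers:
            raise ParameterError("marker_names length must equal n_markers")
        if self.base_proportions is None:
            self.base_proportions = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.base_proportions = np.asarray(self.base_proportions, dtype=np.float64)
        if abs(self.base_proportions.sum() - 1.0) > 1e-9 or (
            self.base_proportions <= 0
        ).any():
            raise ParameterError("base_proportions must be positive and sum to 1")
        if self.cluster_means is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed), 0xC0])
            )
            self.cluster_means = rng.uniform(
                0.0, 4.0, size=(self.n_clusters, self.n_markers)
            )
        self.cluster_means = np.asarray(self.cluster_means, dtype=np.float64)
        if self.cluster_means.shape != (self.n_clusters, self.n_markers):
            raise ParameterError("cluster_means must be clusters x markers")
        if self.effect is not None:
            e = self.effect
            if not 1 <= e.target_cluster <= self.n_clusters:
                raise ParameterError(f"target_cluster {e.target_cluster} out of range")
            if e.proportion_delta is not None:
                p = self.base_proportions[e.target_cluster - 1] + e.proportion_delta
                if not 0.0 < p < 1.0:
                    raise ParameterError(
                        "effect would push the target proportion outside (0, 1)"
                    )
            if e.expression_delta is not None and e.marker not in self.marker_names:
                raise ParameterError(f"effect marker {e.marker!r} not in panel")

    def panel(self) -> Panel:
        return Panel([PanelEntry(m, m, "marker") for m in self.marker_names])


def _shifted_proportions(base: np.ndarray, target: int, delta: float) -> np.ndarray:
    """Add ``delta`` to the target cluster, rescaling the others."""
    out = base.copy()
    t = target - 1
    rest = 1.0 - base[t]
    out[t] = base[t] + delta
    out[np.arange(len(base)) != t] *= (1.0 - out[t]) / rest
    return out


def _sample_rng(spec: CohortSpec, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1 + int(sample_index)])
    )


def simulate_cells(
    spec: CohortSpec,
    sample_id: str,
    sample_index: int = 0,
    arm: str = "A",
    proportions: np.ndarray | None = None,
) -> tuple[CytoTable, np.ndarray]:
    """Draw one sample's cells on the raw (instrument) scale.

    Cluster membership is multinomial in the sample's Dirichlet proportions;
    marker values are Normal(cluster mean, cluster_sd) on the asinh scale,
    inverse-transformed to counts and blurred with uniform(-0.5, 0.5)
    randomization noise clamped at zero.  Returns the raw table and the
    hidden true labels (1-based cluster ids).
    """
    rng = _sample_rng(spec, sample_index)
    if proportions is None:
        proportions = rng.dirichlet(spec.concentration * spec.base_proportions)
    else:
        rng.dirichlet(spec.concentration * spec.base_proportions)  # keep stream aligned
        proportions = np.asarray(proportions, dtype=np.float64)

    means = spec.cluster_means
    if (
        arm == "B"
        and spec.effect is not None
        and spec.effect.expression_delta is not None
    ):
        means = means.copy()
        j = spec.marker_names.index(spec.effect.marker)
        means[spec.effect.target_cluster - 1, j] += spec.effect.expression_delta

    labels = rng.choice(spec.n_clusters, size=spec.cells_per_sample, p=proportions) + 1
    asinh_vals = means[labels - 1] + rng.normal(
        0.0, spec.cluster_sd, size=(spec.cells_per_sample, spec.n_markers)
    )
    raw = spec.cofactor * np.sinh(asinh_vals)
    raw = np.maximum(0.0, raw + rng.uniform(-0.5, 0.5, size=raw.shape))
    df = pd.DataFrame(raw, columns=spec.marker_names)
    table = CytoTable(df, panel=spec.panel())
    table.insert(0, "sample_id", sample_id)
    return table, labels


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[CytoTable], pd.DataFrame, dict]:
    """Simulate the full two-arm cohort.

    Returns per-sample tables (raw scale, each with its ``sample_id``
    column and hidden labels under ``.true_cluster``), the sample metadata
    (sample_id, arm), and a truth record holding per-sample proportions and
    the planted effect.
    """
    tables: list[CytoTable] = []
    meta_rows = []
    truth: dict = {
        "proportions": {},
        "labels": {},
        "effect": None if spec.effect is None else vars(spec.effect).copy(),
        "seed": spec.seed,
    }
    idx = 0
    for arm in ("A", "B"):
        for i in range(spec.n_samples_per_arm):
            sid = f"sample_{arm}{i + 1:02d}"
            rng = _sample_rng(spec, idx)
            props = rng.dirichlet(spec.concentration * spec.base_proportions)
            if (
                arm == "B"
                and spec.effect is not None
                and spec.effect.proportion_delta is not None
            ):
                props = _shifted_proportions(
                    props, spec.effect.target_cluster, spec.effect.proportion_delta
                )
            table, labels = simulate_cells(
                spec, sid, sample_index=idx, arm=arm, proportions=props
            )
            table[".true_cluster"] = np.array([str(v) for v in labels], dtype=object)
            tables.append(table)
            meta_rows.append({"sample_id": sid, "arm": arm})
            truth["proportions"][sid] = props.tolist()
            truth["labels"][sid] = labels.tolist()
            idx += 1
    metadata = pd.DataFrame(meta_rows)
    return tables, metadata, truth


def write_fixture_set(spec: CohortSpec, directory: str | Path) -> list[Path]:
    """Materialize a cohort on disk: one FCS file per sample plus
    ``metadata.csv`` and ``truth.json``.  Byte-identical for a fixed seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables, metadata, truth = simulate_cohort(spec)
    paths: list[Path] = []
    for table, sid in zip(tables, metadata["sample_id"]):
        channels_only = CytoTable(
            pd.DataFrame(table)[spec.panel().column_names], panel=spec.panel()
        )
        paths.append(write_fcs(channels_only, directory / f"{sid}.fcs"))
    meta_path = directory / "metadata.csv"
    metadata.to_csv(meta_path, index=False)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths + [meta_path, truth_path]
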