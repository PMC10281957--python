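"""Cell clustering: FlowSOM-style SOM + metaclustering, or k-means.

The self-organizing map (SOM) is a grid of prototype ("codebook") vectors
trained by online competitive learning: each presented cell moves its
best-matching node (BMU) and the nodes within the current grid neighborhood
toward itself.  Nodes are then *metaclustered* — the codebook vectors are
grouped by average-linkage hierarchical clustering cut at ``k`` groups —
and every cell inherits the metacluster of its BMU.  Average-linkage
metaclustering is deterministic, unlike consensus clustering with
subsampling, which keeps results exactly reproducible from a seed.

Both back-ends sit behind one verb, :func:`cluster_cells`, which augments
the table with a single ``.cluster`` column of text labels "1".."k".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .errors import ParameterError
from .table import CytoTable, augment_column_name, channel_matrix

DEFAULT_GRID = (10, 10)
DEFAULT_K = 20


@dataclass
class SomModel:
    """A (possibly trained) self-organizing map.

    codebook rows are node weight vectors, ordered row-major over the grid
    (node id = row * grid_cols + col).  ``metacluster_map`` maps node id to
    a metacluster id in 1..k once :func:`metacluster_codes` has run.
    """

    grid_rows: int = DEFAULT_GRID[0]
    grid_cols: int = DEFAULT_GRID[1]
    codebook: np.ndarray | None = None
    rlen: int = 10
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None  # None -> grid diagonal / 2
    metacluster_map: dict[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def node_coordinates(self) -> np.ndarray:
        rr, cc = np.divmod(np.arange(self.n_nodes), self.grid_cols)
        return np.column_stack([rr, cc]).astype(np.float64)


def _bmu(codebook: np.ndarray, x: np.ndarray) -> int:
    # ties resolve to the lowest node id (argmin returns the first minimum)
    d = ((codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d))


def assign_nodes(codebook: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Best-matching node id for every row of ``data`` (nearest codebook
    vector, Euclidean; ties to the lowest node id)."""
    from scipy.spatial.distance import cdist

    return cdist(data, codebook, metric="sqeuclidean").argmin(axis=1)


def train_som(
    data: np.ndarray,
    model: SomModel | None = None,
    seed: int = 0,
) -> SomModel:
    """Online SOM training, deterministic given the seed.

    The codebook is initialized by sampling distinct cells.  Training makes
    ``rlen`` passes over freshly seeded permutations of the cells; at each
    step the learning rate decays linearly from ``alpha_start`` to
    ``alpha_end`` and the (bubble) neighborhood radius from ``radius_start``
    (default: half the grid diagonal) to 0.5, measured in grid units.
    """
    model = model or SomModel()
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ParameterError("data must be a cells x channels matrix")
    if np.isnan(data).any():
        raise ParameterError("SOM training data contains missing values")
    n, n_chan = data.shape
    n_nodes = model.n_nodes
    if model.codebook is not None and model.codebook.shape[1] != n_chan:
        raise ParameterError(
            f"codebook has {model.codebook.shape[1]} channels, data has {n_chan}"
        )
    if n < n_nodes:
        warnings.warn(
            f"training on {n} cells for {n_nodes} nodes; codebook will be "
            "undertrained", stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x50D]))

    if model.codebook is not None:
        codebook = model.codebook.astype(np.float64).copy()
    else:
        pick = rng.choice(n, size=min(n_nodes, n), replace=False)
        codebook = data[pick].copy()
        if n < n_nodes:  # recycle cells when the grid outnumbers them
            extra = rng.choice(n, size=n_nodes - n, replace=True)
            codebook = np.vstack([codebook, data[extra]])

    radius_start = (
        model.radius_start
        if model.radius_start is not None
        else np.hypot(model.grid_rows - 1, model.grid_cols - 1) / 2.0
    )
    coords = model.node_coordinates()
    grid_dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))

    total = model.rlen * n
    step = 0
    for _ in range(model.rlen):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(1, total - 1)
            alpha = model.alpha_start + (model.alpha_end - model.alpha_start) * frac
            radius = radius_start + (0.5 - radius_start) * frac
            x = data[i]
            bmu = _bmu(codebook, x)
            mask = grid_dist[bmu] <= radius
            codebook[mask] += alpha * (x - codebook[mask])
            step += 1

    return SomModel(
        grid_rows=model.grid_rows,
        grid_cols=model.grid_cols,
        codebook=codebook,
        rlen=model.rlen,
        alpha_start=model.alpha_start,
        alpha_end=model.alpha_end,
        radius_start=radius_start,
        metacluster_map=None,
    )


def metacluster_codes(model: SomModel, k: int) -> SomModel:
    """Group SOM nodes into ``k`` metaclusters.

    Average-linkage hierarchical clustering of the codebook vectors
    (Euclidean), cut at ``k`` groups.  Metacluster ids are relabeled 1..k by
    descending node count, ties broken by the lower minimum node id.
    """
    if model.codebook is None:
        raise ParameterError("model has no trained codebook")
    if not 1 <= k <= model.n_nodes:
        raise ParameterError(f"k={k} outside 1..{model.n_nodes} nodes")
    if k == model.n_nodes:
        raw = np.arange(1, k + 1)
    else:
        z = linkage(model.codebook, method="average", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")
    groups: dict[int, list[int]] = {}
    for node, g in enumerate(raw):
        groups.setdefault(int(g), []).append(node)
    ordered = sorted(groups.values(), key=lambda nodes: (-len(nodes), min(nodes)))
    mapping = {node: new_id for new_id, nodes in enumerate(ordered, start=1)
               for node in nodes}
    out = SomModel(**{f: getattr(model, f) for f in
                      ("grid_rows", "grid_cols", "rlen", "alpha_start",
                       "alpha_end", "radius_start")})
    out.codebook = model.codebook
    out.metacluster_map = mapping
    return out


def cluster_cells(
    table: CytoTable,
    method: str = "som",
    k: int = DEFAULT_K,
    channels: Sequence[str] | None = None,
    seed: int = 0,
    som_model: SomModel | None = None,
) -> CytoTable:
    """Augment the table with a ``.cluster`` column of labels "1".."k".

    method "som": train a SOM on the selected channels, metacluster its
    codebook into ``k`` groups, and label each cell by its best-matching
    node's metacluster.  method "kmeans": Lloyd iteration with seeded
    k-means++ initialization, at most 300 iterations, relative inertia
    tolerance 1e-4.  Data should already be variance-stabilized (arcsinh);
    the verb does not transform.
    """
    if method not in ("som", "kmeans"):
        raise ParameterError(f"unknown clustering method {method!r}")
    if channels is not None and len(list(channels)) == 0:
        raise ParameterError("empty channel set")
    data = channel_matrix(table, channels)
    n = len(table)
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} exceeds the {n} cells available")

    if method == "kmeans":
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=10, max_iter=300,
            tol=1e-4, random_state=int(seed) % (2**32),
        )
        labels = km.fit_predict(data) + 1
    else:
        model = som_model or SomModel()
        model = train_som(data, model, seed=seed)
        model = metacluster_codes(model, k)
        nodes = assign_nodes(model.codebook, data)
        meta = np.array([model.metacluster_map[i] for i in range(model.n_nodes)])
        labels = meta[nodes]

    out = table.copy()
    col = augment_column_name(out, ".cluster")
    out[col] = np.array([str(v) for v in labels], dtype=object)
    return out
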