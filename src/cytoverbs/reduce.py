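"""Dimensionality reduction verbs: PCA (internal), tSNE and UMAP (delegated).

PCA is computed in-package via the singular value decomposition of the
centered data matrix — numerically equivalent to eigendecomposition of the
(n-1)-denominator covariance matrix but stabler for thin matrices.  tSNE
and UMAP are delegated to established implementations (scikit-learn's
Barnes-Hut tSNE and umap-learn) behind the same augment contract:
re-implementing stochastic neighbor embeddings is out of proportion to the
package's purpose.

By default PCA centers but does not rescale, because cytometry channels are
already variance-stabilized after the arcsinh transform; pass ``scale=True``
to standardize first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ParameterError
from .table import CytoTable, augment_column_name, channel_matrix


@dataclass
class PcaModel:
    """Fitted PCA: channel means, orthonormal loadings (channels x d), and
    the explained variance (descending eigenvalues of the covariance)."""

    means: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    d: int
    channels: list[str]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.means) @ self.loadings


def _augment(table: CytoTable, names: list[str], coords: np.ndarray) -> CytoTable:
    out = table.copy()
    for j, base in enumerate(names):
        out[augment_column_name(out, base)] = coords[:, j]
    return out


def reduce_pca(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    d: int = 2,
    scale: bool = False,
) -> tuple[CytoTable, PcaModel]:
    """Project cells onto the top-``d`` principal components.

    Loadings are the top eigenvectors of the (n-1)-denominator covariance
    matrix, obtained via SVD of the centered data.  Sign convention: within
    each loading the entry of largest absolute value is positive.  Augments
    the table with ``.pc1`` ... ``.pc<d>``.
    """
    if channels is None:
        channels = table.marker_columns
    channels = list(channels)
    x = channel_matrix(table, channels)
    n, p = x.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 cells")
    if not 1 <= d <= min(n - 1, p):
        raise ParameterError(f"d={d} outside 1..min(n-1, channels)={min(n - 1, p)}")
    means = x.mean(axis=0)
    xc = x - means
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    if not np.any(xc):
        raise DegenerateDataError("all channels are constant; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[:d].T  # channels x d
    explained = (s[:d] ** 2) / (n - 1)
    # sign convention: largest-|.| entry of each loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = xc @ loadings
    model = PcaModel(
        means=means, loadings=loadings, explained_variance=explained, d=d,
        channels=channels,
    )
    names = [f".pc{j + 1}" for j in range(d)]
    return _augment(table, names, scores), model


def reduce_tsne(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    d: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> CytoTable:
    """Barnes-Hut tSNE embedding, augmenting ``.tsne1``/``.tsne2``.

    Deterministic for a fixed seed under single-threaded execution.
    """
    n = len(table)
    if n <= 3 * perplexity:
        raise ParameterError(
            f"perplexity {perplexity} too large for {n} cells (need n > 3*perplexity)"
        )
    from sklearn.manifold import TSNE

    x = channel_matrix(table, channels)
    emb = TSNE(
        n_components=d, perplexity=perplexity, random_state=int(seed) % (2**32),
        init="pca", method="barnes_hut", n_jobs=1,
    ).fit_transform(x)
    return _augment(table, [f".tsne{j + 1}" for j in range(d)], emb)


def reduce_umap(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    d: int = 2,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> CytoTable:
    """UMAP embedding (delegated to umap-learn), augmenting ``.umap1``/``.umap2``."""
    n = len(table)
    if n_neighbors >= n:
        raise ParameterError(f"n_neighbors={n_neighbors} must be below n_cells={n}")
    import umap  # deferred: numba compilation is expensive

    x = channel_matrix(table, channels)
    emb = umap.UMAP(
        n_components=d, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=int(seed) % (2**32),
    ).fit_transform(x)
    return _augment(table, [f".umap{j + 1}" for j in range(d)], np.asarray(emb))
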