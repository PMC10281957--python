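import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cytoverbs import CohortSpec, CytoTable, Panel, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


def make_table(matrix, columns, annotations=None) -> CytoTable:
    """Small helper: numeric matrix + column names -> CytoTable with an
    all-marker panel, plus optional annotation columns."""
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(columns))
    if annotations:
        for k, v in annotations.items():
            df[k] = v
    return CytoTable(df, panel=Panel.from_columns(columns))


@pytest.fixture
def two_channel_table() -> CytoTable:
    return make_table([[1.0, 2.0], [3.0, 4.0]], ["a", "b"])


@pytest.fixture(scope="session")
def small_cohort():
    """A small effect-free cohort: 3 samples/arm, 5 clusters, 6 markers."""
    spec = CohortSpec(
        n_samples_per_arm=3, n_clusters=5, n_markers=6,
        cells_per_sample=300, seed=11,
    )
    tables, metadata, truth = simulate_cohort(spec)
    return spec, tables, metadata, truth


def four_blob_data(seed: int, n_per_blob: int = 500, sd: float = 0.2):
    """Four isotropic Gaussian blobs with pairwise center distance >= 10."""
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0, 0, 0, 0], [10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0]], float
    )
    X = np.vstack([rng.normal(c, sd, size=(n_per_blob, 4)) for c in centers])
    labels = np.repeat(np.arange(4), n_per_blob)
    return X, labels


def ring_points(n: int, center, rng, radius: float = 1.0) -> np.ndarray:
    """Points uniform on a circle: spatially uniform local density with no
    edge effects, so density-equalization closed forms are exact."""
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
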