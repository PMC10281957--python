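"""Sample-level feature extraction.

These verbs collapse the cell-level table to the whole-sample level: one
row per sample, one column per aggregated feature.  Feature columns follow
the fixed, parseable naming scheme ``<type>@<cluster>[@<marker>[@<condition>]]``:

- ``abundance@c``      proportion of the sample's cells in cluster c (in [0,1])
- ``ct@c@m``           central tendency (median/mean) of marker m in cluster c
- ``pos@c@m``          fraction of cluster-c cells above a positivity threshold
- ``emd@c@m@cond``     earth mover's distance of marker m in cluster c between
                       stimulation condition ``cond`` and the basal condition
- ``jsd@c@m@cond``     Jensen-Shannon divergence on the same bins (nats)

Abundances over all clusters observed anywhere sum to 1 for every sample
(clusters unobserved in a sample contribute exact zeros).  A central
tendency for an absent (sample, cluster) stratum is a missing value, never
zero — "no cells" is not "zero expression".
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    MissingColumnError,
    MissingReferenceError,
    ParameterError,
)
from .preprocess import DEFAULT_COFACTOR
from .table import CytoTable

CLUSTER_COL = ".cluster"
EMD_BINS = 100

#: default positivity cutoff: 10 raw counts on the arcsinh scale (cofactor 5)
DEFAULT_POS_THRESHOLD = float(np.arcsinh(10.0 / DEFAULT_COFACTOR))


def _require(table: CytoTable, *cols: str) -> pd.DataFrame:
    df = pd.DataFrame(table)
    for c in cols:
        if c not in df.columns:
            raise MissingColumnError(f"table lacks required column {c!r}")
    return df


def _cluster_order(labels: pd.Series) -> list:
    uniq = labels.dropna().unique().tolist()
    try:
        return sorted(uniq, key=lambda v: (0, int(v)))
    except (TypeError, ValueError):
        return sorted(uniq, key=str)


def _sample_order(df: pd.DataFrame) -> list:
    return df["sample_id"].drop_duplicates().tolist()


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def extract_abundance(table: CytoTable) -> pd.DataFrame:
    """Per-sample cluster proportions ``abundance@c`` (rows sum to 1)."""
    df = _require(table, "sample_id", CLUSTER_COL)
    clusters = _cluster_order(df[CLUSTER_COL])
    counts = (
        df.groupby(["sample_id", CLUSTER_COL], sort=False, observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=clusters, fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"abundance@{c}" for c in clusters]
    out = props.reset_index()
    return out.set_index("sample_id").loc[_sample_order(df)].reset_index()


def extract_central_tendency(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    stat: str = "median",
) -> pd.DataFrame:
    """Per (sample, cluster, marker) central tendency ``ct@c@m``.

    An empty (sample, cluster) stratum yields a missing value.
    """
    if stat not in ("median", "mean"):
        raise ParameterError(f"unknown stat {stat!r} (need median or mean)")
    df = _require(table, "sample_id", CLUSTER_COL)
    channels = list(channels) if channels is not None else table.marker_columns
    bad = [c for c in channels if c not in table.marker_columns]
    if bad:
        raise ParameterError(f"not marker channels: {bad}")
    clusters = _cluster_order(df[CLUSTER_COL])
    agg = df.groupby(["sample_id", CLUSTER_COL], sort=False, observed=True)[
        channels
    ].agg(stat)
    wide = agg.unstack(CLUSTER_COL)  # columns: (marker, cluster)
    cols, names = [], []
    for c in clusters:
        for m in channels:
            names.append(f"ct@{c}@{m}")
            cols.append(
                wide[(m, c)] if (m, c) in wide.columns
                else pd.Series(np.nan, index=wide.index)
            )
    out = pd.concat(cols, axis=1)
    out.columns = names
    return out.loc[_sample_order(df)].rename_axis("sample_id").reset_index()


def extract_threshold(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    threshold: float = DEFAULT_POS_THRESHOLD,
) -> pd.DataFrame:
    """Percent-positive features ``pos@c@m``: fraction of (sample, cluster)
    cells with marker value strictly above ``threshold`` (transformed scale)."""
    df = _require(table, "sample_id", CLUSTER_COL)
    channels = list(channels) if channels is not None else table.marker_columns
    clusters = _cluster_order(df[CLUSTER_COL])
    flags = df[["sample_id", CLUSTER_COL]].copy()
    for m in channels:
        flags[m] = (df[m] > threshold).astype(float)
    agg = flags.groupby(["sample_id", CLUSTER_COL], sort=False, observed=True)[
        channels
    ].mean()
    wide = agg.unstack(CLUSTER_COL)
    cols, names = [], []
    for c in clusters:
        for m in channels:
            names.append(f"pos@{c}@{m}")
            cols.append(
                wide[(m, c)] if (m, c) in wide.columns
                else pd.Series(np.nan, index=wide.index)
            )
    out = pd.concat(cols, axis=1)
    out.columns = names
    return out.loc[_sample_order(df)].rename_axis("sample_id").reset_index()


# ---------------------------------------------------------------------------
# binned distribution distances
# ---------------------------------------------------------------------------

def _binned_pair(a: np.ndarray, b: np.ndarray, bins: int = EMD_BINS):
    """Histogram two samples on a shared grid of ``bins`` points spanning
    their pooled range inclusive.  Returns (p, q, spacing)."""
    pooled = np.concatenate([a, b])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi == lo:
        p = np.zeros(bins)
        p[0] = 1.0
        return p, p.copy(), 0.0
    spacing = (hi - lo) / (bins - 1)
    idx_a = np.clip(np.round((a - lo) / spacing).astype(int), 0, bins - 1)
    idx_b = np.clip(np.round((b - lo) / spacing).astype(int), 0, bins - 1)
    p = np.bincount(idx_a, minlength=bins) / len(a)
    q = np.bincount(idx_b, minlength=bins) / len(b)
    return p, q, spacing


def binned_emd(a: np.ndarray, b: np.ndarray, bins: int = EMD_BINS) -> float:
    """1-D earth mover's distance between two samples on a shared grid:
    L1 distance of the empirical CDFs times the grid spacing."""
    p, q, spacing = _binned_pair(np.asarray(a, float), np.asarray(b, float), bins)
    return float(spacing * np.abs(np.cumsum(p - q)).sum())


def binned_jsd(a: np.ndarray, b: np.ndarray, bins: int = EMD_BINS) -> float:
    """Jensen-Shannon divergence (natural log) on the shared grid; empty
    bins are allowed (0 * log 0 = 0), so the value lies in [0, ln 2]."""
    p, q, _ = _binned_pair(np.asarray(a, float), np.asarray(b, float), bins)
    m = 0.5 * (p + q)

    def kl(r: np.ndarray) -> float:
        nz = r > 0
        return float(np.sum(r[nz] * np.log(r[nz] / m[nz])))

    return 0.5 * kl(p) + 0.5 * kl(q)


def extract_distance(
    table: CytoTable,
    condition_col: str,
    basal_level: str,
    channels: Sequence[str] | None = None,
    method: str = "emd",
    bins: int = EMD_BINS,
) -> pd.DataFrame:
    """Stimulation-response features: per (sample, cluster, marker,
    non-basal condition) distance between the condition's and the basal
    marker distribution, ``emd@c@m@cond`` or ``jsd@c@m@cond``.

    Distances are computed on a shared grid spanning the pooled range of
    the compared pair.  Strata with no cells on either side are missing.
    """
    if method not in ("emd", "jsd"):
        raise ParameterError(f"unknown distance method {method!r}")
    df = _require(table, "sample_id", CLUSTER_COL, condition_col)
    channels = list(channels) if channels is not None else table.marker_columns
    kernel = binned_emd if method == "emd" else binned_jsd

    samples = _sample_order(df)
    conditions = [c for c in df[condition_col].dropna().unique() if c != basal_level]
    clusters = _cluster_order(df[CLUSTER_COL])
    for s in samples:
        if basal_level not in set(df.loc[df["sample_id"] == s, condition_col]):
            raise MissingReferenceError(
                f"sample {s!r} has no cells at basal level {basal_level!r}"
            )

    rows = {}
    grouped = df.groupby(["sample_id", condition_col, CLUSTER_COL],
                         sort=False, observed=True)
    index = {key: sub for key, sub in grouped}
    for s in samples:
        rec = {}
        for cond in conditions:
            for c in clusters:
                basal = index.get((s, basal_level, c))
                stim = index.get((s, cond, c))
                for m in channels:
                    name = f"{method}@{c}@{m}@{cond}"
                    if basal is None or stim is None or not len(basal) or not len(stim):
                        rec[name] = np.nan
                    else:
                        rec[name] = kernel(
                            stim[m].to_numpy(float), basal[m].to_numpy(float), bins
                        )
        rows[s] = rec
    out = pd.DataFrame.from_dict(rows, orient="index").loc[samples]
    return out.rename_axis("sample_id").reset_index()


# ---------------------------------------------------------------------------
# combined extraction
# ---------------------------------------------------------------------------

_FAMILIES = {
    "abundance": lambda t, kw: extract_abundance(t),
    "ct": lambda t, kw: extract_central_tendency(t, **kw),
    "pos": lambda t, kw: extract_threshold(t, **kw),
    "emd": lambda t, kw: extract_distance(t, method="emd", **kw),
    "jsd": lambda t, kw: extract_distance(t, method="jsd", **kw),
}


def extract_features(
    table: CytoTable,
    features: Sequence[str | tuple[str, dict]],
) -> pd.DataFrame:
    """Column-wise join of the requested feature families on ``sample_id``.

    ``features`` entries are family names ("abundance", "ct", "pos", "emd",
    "jsd") or ``(name, kwargs)`` pairs.  Sample-level metadata columns
    (annotation columns constant within every sample) are carried along.
    Duplicate requests are deduplicated with a warning.
    """
    if not features:
        raise ParameterError("empty feature specification")
    seen = set()
    normalized: list[tuple[str, dict]] = []
    for f in features:
        name, kw = (f, {}) if isinstance(f, str) else (f[0], dict(f[1]))
        if name not in _FAMILIES:
            raise ParameterError(f"unknown feature family {name!r}")
        key = (name, tuple(sorted(kw.items())))
        if key in seen:
            warnings.warn(f"duplicate feature request {name!r} ignored", stacklevel=2)
            continue
        seen.add(key)
        normalized.append((name, kw))

    blocks = [_FAMILIES[name](table, kw) for name, kw in normalized]
    out = blocks[0]
    for block in blocks[1:]:
        out = out.merge(block, on="sample_id", how="outer", sort=False)

    # sample-level metadata: annotation columns constant within each sample
    df = pd.DataFrame(table)
    chan = set(table.channel_columns)
    candidates = [
        c for c in df.columns
        if c not in chan and c != "sample_id" and not str(c).startswith(".")
    ]
    if candidates:
        per_sample = df.groupby("sample_id", sort=False)[candidates].nunique(dropna=False)
        constant = [c for c in candidates if (per_sample[c] <= 1).all()]
        if constant:
            meta = df.groupby("sample_id", sort=False)[constant].first().reset_index()
            out = out.merge(meta, on="sample_id", how="left", sort=False)
    return out
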