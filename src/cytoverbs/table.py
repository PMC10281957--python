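"""Tidy cell-level data model.

A :class:`CytoTable` is a :class:`pandas.DataFrame` with one row per cell.
Columns are either *channel* columns (numeric measurements, one per protein
channel) or *annotation* columns (sample id, cluster label, embedding
coordinates, joined metadata).  Which columns are channels is decided by the
attached :class:`Panel` — the panel is the single source of truth, so no
naming heuristics are needed.

Every verb in the package accepts a CytoTable and returns a CytoTable;
augmenting verbs add columns and never drop, reorder, or mutate existing
ones.  The panel and the active grouping keys ride along as dataframe
metadata and survive pandas operations via ``_metadata``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousJoinError,
    ChannelClassError,
    ChannelMismatchError,
    MissingColumnError,
)

MARKER = "marker"
TECHNICAL = "technical"


@dataclass(frozen=True)
class PanelEntry:
    """One measured channel: raw instrument name, human-readable antigen
    name, and whether the channel is a biological marker or a technical
    channel (time, event length, barcoding metals, ...)."""

    channel_name: str
    antigen_name: str
    channel_class: str = MARKER

    def __post_init__(self) -> None:
        if self.channel_class not in (MARKER, TECHNICAL):
            raise ValueError(f"unknown channel class {self.channel_class!r}")


@dataclass
class Panel:
    """Ordered channel metadata for an acquisition panel.

    ``antigen_name`` is the name the corresponding CytoTable column carries;
    ``channel_name`` is the raw instrument channel ($PnN in FCS files).
    """

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.channel_name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel names in panel: {dupes}")

    # -- lookups -----------------------------------------------------------
    @property
    def column_names(self) -> list[str]:
        """Column names as they appear in a CytoTable (antigen names)."""
        return [e.antigen_name for e in self.entries]

    @property
    def marker_columns(self) -> list[str]:
        return [e.antigen_name for e in self.entries if e.channel_class == MARKER]

    @property
    def technical_columns(self) -> list[str]:
        return [e.antigen_name for e in self.entries if e.channel_class == TECHNICAL]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, column: str) -> bool:
        return column in self.column_names

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Panel) and self.entries == other.entries

    # -- construction ------------------------------------------------------
    @classmethod
    def from_columns(cls, columns: Iterable[str]) -> "Panel":
        """Infer an all-marker panel from plain column names."""
        return cls([PanelEntry(c, c, MARKER) for c in columns])

    # -- serialization (sidecar JSON used by the CLI) ----------------------
    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "channel_name": e.channel_name,
                    "antigen_name": e.antigen_name,
                    "channel_class": e.channel_class,
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "Panel":
        return cls([PanelEntry(**d) for d in json.loads(text)])


class CytoTable(pd.DataFrame):
    """Tidy cell table: one row per cell, panel metadata attached.

    Parameters
    ----------
    data
        Anything :class:`pandas.DataFrame` accepts.
    panel
        The :class:`Panel` describing which columns are channels.  When
        omitted it can be attached later; most verbs require it.
    group_keys
        Names of annotation columns currently used as grouping keys.
    """

    _metadata = ["panel", "group_keys"]

    def __init__(self, data=None, *args, panel: Panel | None = None,
                 group_keys: Sequence[str] | None = None, **kwargs):
        super().__init__(data, *args, **kwargs)
        if panel is not None:
            object.__setattr__(self, "panel", panel)
        elif not hasattr(self, "panel"):
            object.__setattr__(self, "panel", None)
        if group_keys is not None:
            object.__setattr__(self, "group_keys", list(group_keys))
        elif not hasattr(self, "group_keys"):
            object.__setattr__(self, "group_keys", [])

    @property
    def _constructor(self):
        return CytoTable

    # -- views -------------------------------------------------------------
    @property
    def channel_columns(self) -> list[str]:
        """Channel columns actually present, in panel order."""
        if self.panel is None:
            return []
        return [c for c in self.panel.column_names if c in self.columns]

    @property
    def marker_columns(self) -> list[str]:
        if self.panel is None:
            return []
        return [c for c in self.panel.marker_columns if c in self.columns]

    @property
    def annotation_columns(self) -> list[str]:
        chan = set(self.channel_columns)
        return [c for c in self.columns if c not in chan]


# ---------------------------------------------------------------------------
# verbs
# ---------------------------------------------------------------------------

def bind_samples(tables: Sequence[CytoTable], sample_ids: Sequence[str]) -> CytoTable:
    """Row-bind per-sample tables into one table with a ``sample_id`` column.

    All tables must share an identical channel set (order-insensitive); the
    first table's panel is retained and its column order is used.
    """
    if len(tables) == 0 or len(tables) != len(sample_ids):
        raise ValueError("need equally many tables and sample ids, at least one")
    ref = tables[0]
    ref_channels = set(ref.channel_columns)
    for t in tables[1:]:
        other = set(t.channel_columns)
        if other != ref_channels:
            diff = sorted(ref_channels.symmetric_difference(other))
            raise ChannelMismatchError(
                f"tables do not share a channel set; differing channels: {diff}"
            )
    parts = []
    for t, sid in zip(tables, sample_ids):
        part = pd.DataFrame(t).copy()
        if "sample_id" not in part.columns:
            part.insert(0, "sample_id", sid)
        else:
            part["sample_id"] = sid
        parts.append(part)
    out = pd.concat(parts, axis=0, ignore_index=True)
    return CytoTable(out, panel=ref.panel, group_keys=list(ref.group_keys))


def join_sample_metadata(table: CytoTable, meta: pd.DataFrame) -> CytoTable:
    """Left-join sample-level metadata onto cells via ``sample_id``.

    Cells of samples absent from ``meta`` get missing values; the row count
    never changes.  Duplicate sample ids in ``meta`` are an error because the
    join would multiply rows.
    """
    if "sample_id" not in table.columns:
        raise MissingColumnError("table has no sample_id column")
    if "sample_id" not in meta.columns:
        raise MissingColumnError("metadata has no sample_id column")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise AmbiguousJoinError(f"duplicate sample_id in metadata: {dupes}")
    merged = pd.DataFrame(table).merge(meta, on="sample_id", how="left", sort=False)
    assert len(merged) == len(table)
    return CytoTable(merged, panel=table.panel, group_keys=list(table.group_keys))


def group_cells(table: CytoTable, keys: Sequence[str]) -> CytoTable:
    """Set the grouping keys honored by grouped verbs (downsample, extract).

    Keys must be annotation columns — grouping by a measurement channel is
    rejected.  Values are untouched; only the ``group_keys`` attribute is set.
    """
    keys = list(keys)
    channels = set(table.channel_columns)
    for k in keys:
        if k not in table.columns:
            raise MissingColumnError(f"unknown grouping key: {k!r}")
        if k in channels:
            raise ChannelClassError(
                f"{k!r} is a channel column; channels are not grouping keys"
            )
    out = table.copy()
    object.__setattr__(out, "group_keys", keys)
    return out


def channel_matrix(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    *,
    include_technical: bool = False,
) -> np.ndarray:
    """Dense cells x channels float matrix bridging to numeric kernels.

    Default channel set is every marker-class channel in panel order.
    Requesting a technical-class channel requires ``include_technical=True``;
    annotation columns are never allowed.
    """
    if table.panel is None:
        from .errors import MissingPanelError

        raise MissingPanelError("table has no panel attached")
    if channels is None:
        channels = table.marker_columns
    else:
        channels = list(channels)
        allowed = set(table.marker_columns)
        technical = set(table.panel.technical_columns)
        for c in channels:
            if c in allowed:
                continue
            if c in technical:
                if not include_technical:
                    raise ChannelClassError(
                        f"{c!r} is a technical channel; pass include_technical=True"
                    )
            elif c in table.columns:
                raise ChannelClassError(f"{c!r} is not a channel column")
            else:
                raise MissingColumnError(f"unknown channel: {c!r}")
    return pd.DataFrame(table)[list(channels)].to_numpy(dtype=np.float64)


def augment_column_name(table: pd.DataFrame, base: str) -> str:
    """Collision-safe name for an augment column: ``base``, else ``base.1``,
    ``base.2``, ... deterministically."""
    if base not in table.columns:
        return base
    i = 1
    while f"{base}.{i}" in table.columns:
        i += 1
    warnings.warn(
        f"column {base!r} already exists; augmenting as {base}.{i}", stacklevel=3
    )
    return f"{base}.{i}"


def _grouped_indices(table: CytoTable) -> list[tuple[object, np.ndarray]]:
    """(group key, positional row indices) pairs honoring ``group_keys``.

    With no grouping keys the whole table is one group keyed ``None``.
    Groups are iterated in first-appearance order; indices are ascending so
    the original relative row order is preserved downstream.
    """
    if not table.group_keys:
        return [(None, np.arange(len(table)))]
    df = pd.DataFrame(table)
    codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(df[list(table.group_keys)])
        if len(table.group_keys) > 1
        else df[table.group_keys[0]],
        sort=False,
    )
    out = []
    keys_seen = {}
    for pos, code in enumerate(codes):
        keys_seen.setdefault(code, []).append(pos)
    keyframe = df[list(table.group_keys)]
    for code, positions in keys_seen.items():
        first = positions[0]
        key = tuple(keyframe.iloc[first]) if len(table.group_keys) > 1 else keyframe.iloc[first, 0]
        out.append((key, np.asarray(positions, dtype=np.intp)))
    return out
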