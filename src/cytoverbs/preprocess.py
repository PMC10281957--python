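"""Variance stabilization and channel conditioning.

Mass-cytometry ion counts are approximately Poisson at the low end and
multiplicative at the high end, so the standard variance-stabilizing map is
``x -> asinh(x / cofactor)``.  The conventional cofactor is 5 for mass
cytometry (150 is customary for fluorescence data).  Acquisition software
additionally adds uniform sub-integer "randomization" noise to the integer
counts for display purposes; :func:`undo_randomization` restores the counts
by round-half-up followed by clamping at zero.

The default preprocessing pipeline is fixed and documented:
``undo_randomization`` then ``transform_arcsinh``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .table import CytoTable

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0  # mass cytometry convention; use 150 for fluorescence


@dataclass
class TransformSpec:
    """Parameters of the variance-stabilizing transform.

    cofactor
        Positive divisor applied before asinh (dimensionless).
    undo_noise
        Whether to strip acquisition randomization noise first.
    channels
        Channel subset to transform; ``None`` means all marker channels.
    """

    cofactor: float = DEFAULT_COFACTOR
    undo_noise: bool = True
    channels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ParameterError(f"cofactor must be positive, got {self.cofactor}")


def _resolve_channels(table: CytoTable, channels: Sequence[str] | None) -> list[str]:
    if channels is None:
        return table.marker_columns
    channels = list(channels)
    markers = set(table.marker_columns)
    bad = [c for c in channels if c not in markers]
    if bad:
        raise ParameterError(f"not marker channels: {bad}")
    return channels


def _apply(table: CytoTable, channels: list[str], fn) -> CytoTable:
    out = table.copy()
    for c in channels:
        out[c] = fn(pd.DataFrame(table)[c].to_numpy(dtype=np.float64))
    return out


def transform_arcsinh(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> CytoTable:
    """Replace each selected value x with ``asinh(x / cofactor)``.

    Strictly monotone, hence rank-preserving within each channel; all other
    columns are untouched.
    """
    if not cofactor > 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    cols = _resolve_channels(table, channels)
    logger.info("arcsinh transform: %d channels, cofactor %g", len(cols), cofactor)
    return _apply(table, cols, lambda x: np.arcsinh(x / cofactor))


def transform_inverse(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> CytoTable:
    """Inverse of :func:`transform_arcsinh`: ``x -> cofactor * sinh(x)``."""
    if not cofactor > 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    cols = _resolve_channels(table, channels)
    return _apply(table, cols, lambda x: cofactor * np.sinh(x))


def undo_randomization(
    table: CytoTable, channels: Sequence[str] | None = None
) -> CytoTable:
    """Strip sub-integer acquisition noise: round half up, clamp at zero.

    Idempotent on non-negative integer data.  Must be applied to raw counts,
    before any arcsinh transform — the function does not police this.
    """
    cols = _resolve_channels(table, channels)
    return _apply(table, cols, lambda x: np.maximum(0.0, np.floor(x + 0.5)))


def scale_channels(
    table: CytoTable,
    channels: Sequence[str] | None = None,
    center: bool = True,
    scale: bool = True,
) -> CytoTable:
    """Standardize channels: subtract the mean and/or divide by the sample
    standard deviation (n-1 denominator).

    A zero-variance channel with ``scale=True`` is left centered and flagged
    with a warning instead of producing NaNs.
    """
    cols = _resolve_channels(table, channels)
    out = table.copy()
    flagged = []
    for c in cols:
        x = pd.DataFrame(table)[c].to_numpy(dtype=np.float64)
        if center:
            x = x - x.mean()
        if scale:
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            if sd == 0.0:
                flagged.append(c)
            else:
                x = x / sd
        out[c] = x
    if flagged:
        warnings.warn(
            f"zero-variance channels left unscaled: {flagged}", stacklevel=2
        )
    return out


def preprocess(
    table: CytoTable, spec: TransformSpec | None = None
) -> CytoTable:
    """Default preprocessing pipeline: de-randomize (optional), then arcsinh."""
    spec = spec or TransformSpec()
    out = table
    if spec.undo_noise:
        logger.info("preprocess: undo_randomization -> transform_arcsinh")
        out = undo_randomization(out, spec.channels)
    return transform_arcsinh(out, spec.channels, spec.cofactor)
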