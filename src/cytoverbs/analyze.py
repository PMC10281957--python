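"""Differential abundance and differential expression across sample groups.

Both analyses operate on the sample-level feature matrix and a binary
outcome.  Differential abundance tests each cluster's proportion: the
proportions are clipped to [1e-6, 1 - 1e-6], logit-transformed, and
compared between outcomes with a Welch two-sample t-test (or a paired
t-test when a pairing column is given).  Differential expression applies
the same test to each cluster x marker central-tendency feature, skipping
units missing in more than half the samples of either group.  P-values are
adjusted with the Benjamini-Hochberg step-up procedure within each call,
over the units actually tested.

Effects are reported as the difference of group means (second outcome
level minus first, with levels sorted ascending), in logit-proportion
units for abundance and transformed-expression units for expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyResultError,
    InsufficientReplicatesError,
    ParameterError,
)

logger = logging.getLogger(__name__)

PROP_CLIP = 1e-6


@dataclass(frozen=True)
class TestResult:
    """One tested unit: a cluster, or a (cluster, marker) pair."""

    unit: str
    effect: float
    statistic: float
    p_value: float
    q_value: float
    n_group_a: int
    n_group_b: int


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t-test with a defined answer for zero-variance data: equal
    constant groups give (0, 1); distinct constants give (+/-inf, 0)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = b.mean() - a.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(max(p, np.finfo(float).tiny))


def _paired(diffs: np.ndarray) -> tuple[float, float]:
    if diffs.var(ddof=1) == 0.0:
        if diffs.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(diffs.mean()) * np.inf), 0.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(max(p, np.finfo(float).tiny))


def _binary_groups(features: pd.DataFrame, outcome_col: str):
    if outcome_col not in features.columns:
        raise ParameterError(f"outcome column {outcome_col!r} missing")
    levels = sorted(features[outcome_col].dropna().unique(), key=str)
    if len(levels) != 2:
        raise ParameterError(
            f"outcome must be binary; found levels {levels!r}"
        )
    a = features[features[outcome_col] == levels[0]]
    b = features[features[outcome_col] == levels[1]]
    return levels, a, b


def _run_tests(
    features: pd.DataFrame,
    columns: list[str],
    outcome_col: str,
    paired_col: str | None,
    min_present: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    levels, ga, gb = _binary_groups(features, outcome_col)
    skipped: list[str] = []
    rows = []
    for col in columns:
        xa = ga[col].to_numpy(dtype=np.float64)
        xb = gb[col].to_numpy(dtype=np.float64)
        frac_a = np.mean(~np.isnan(xa)) if len(xa) else 0.0
        frac_b = np.mean(~np.isnan(xb)) if len(xb) else 0.0
        if frac_a < min_present or frac_b < min_present:
            skipped.append(col)
            continue
        if paired_col is None:
            xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
            if len(xa) < 2 or len(xb) < 2:
                raise InsufficientReplicatesError(
                    f"need >= 2 samples per outcome level for {col!r} "
                    f"(got {len(xa)} and {len(xb)})"
                )
            t, p = _welch(xa, xb)
            effect = float(xb.mean() - xa.mean())
            na, nb = len(xa), len(xb)
        else:
            if paired_col not in features.columns:
                raise ParameterError(f"pairing column {paired_col!r} missing")
            pa = ga.set_index(paired_col)[col]
            pb = gb.set_index(paired_col)[col]
            common = pa.index.intersection(pb.index)
            diffs = (pb.loc[common] - pa.loc[common]).to_numpy(dtype=np.float64)
            diffs = diffs[~np.isnan(diffs)]
            if len(diffs) < 2:
                raise InsufficientReplicatesError(
                    f"need >= 2 complete pairs for {col!r} (got {len(diffs)})"
                )
            t, p = _paired(diffs)
            effect = float(diffs.mean())
            na = nb = len(diffs)
        rows.append((col, effect, t, p, na, nb))

    if not rows:
        raise EmptyResultError("no testable units after missingness filtering")
    out = pd.DataFrame(
        rows, columns=["unit", "effect", "statistic", "p_value",
                       "n_group_a", "n_group_b"],
    )
    out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    out = out[["unit", "effect", "statistic", "p_value", "q_value",
               "n_group_a", "n_group_b"]]
    out.attrs["outcome_levels"] = levels
    out.attrs["skipped_units"] = skipped
    if skipped:
        logger.info("skipped %d units with >50%% missing values", len(skipped))
    return out, skipped


def analyze_abundance(
    features: pd.DataFrame,
    outcome_col: str,
    paired_col: str | None = None,
) -> pd.DataFrame:
    """Differential cluster abundance.

    Tests each ``abundance@c`` feature on the logit scale (proportions
    clipped to [1e-6, 1-1e-6]) with a Welch (or paired) t-test, BH-adjusted
    across clusters.  Returns one tidy row per cluster with unit, effect,
    statistic, p_value, q_value and group sizes.
    """
    cols = [c for c in features.columns if str(c).startswith("abundance@")]
    if not cols:
        raise ParameterError("no abundance@ features present")
    work = features.copy()
    for c in cols:
        p = work[c].astype(float).clip(PROP_CLIP, 1.0 - PROP_CLIP)
        work[c] = np.log(p / (1.0 - p))
    result, _ = _run_tests(work, cols, outcome_col, paired_col)
    result["unit"] = result["unit"].str.replace("abundance@", "", regex=False)
    return result


def analyze_expression(
    features: pd.DataFrame,
    outcome_col: str,
    paired_col: str | None = None,
) -> pd.DataFrame:
    """Differential marker expression per (cluster, marker) unit.

    Tests each ``ct@c@m`` feature with a Welch (or paired) t-test; units
    with missing values in more than half the samples of either group are
    skipped and listed in ``result.attrs["skipped_units"]``.  BH adjustment
    runs jointly across all tested units.
    """
    cols = [c for c in features.columns if str(c).startswith("ct@")]
    if not cols:
        raise ParameterError("no ct@ features present")
    result, _ = _run_tests(features, cols, outcome_col, paired_col)
    result["unit"] = result["unit"].str.replace("ct@", "", regex=False)
    return result
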