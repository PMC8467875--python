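"""Test–retest repeatability and cross-condition reproducibility statistics.

Per feature, agreement between two measurement sets (test vs retest, or two
acquisition conditions) is summarized by Lin's concordance correlation
coefficient (CCC) and by the normalized dynamic range (DR),

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
    DR  = 1 - mean|x_i - y_i| / (max(x, y) - min(x, y))

with population (1/n) moments. A feature is *repeatable* when CCC and DR
both reach their cutoffs (default 0.9 each) and *reproducible* across two
conditions when CCC alone reaches its cutoff. Group-level percentages are
compared with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNDEFINED",
    "StabilityRecord",
    "ReproducibilityMatrix",
    "GroupComparison",
    "ccc",
    "dynamic_range",
    "repeatability_analysis",
    "reproducibility_analysis",
    "compare_percentages",
    "records_to_frame",
]

#: marker for degenerate (undefined) CCC/DR values; NaN so it propagates
#: visibly and compares False against any cutoff
UNDEFINED = float("nan")


@dataclass(frozen=True)
class StabilityRecord:
    feature_name: str
    condition_a: str
    condition_b: str
    ccc: float
    dr: float
    repeatable: bool
    reproducible: bool
    ccc_threshold: float = 0.9
    dr_threshold: float = 0.9


@dataclass(frozen=True)
class ReproducibilityMatrix:
    """Symmetric matrix of % of features with CCC >= threshold per pair."""

    conditions: tuple[str, ...]
    pct: np.ndarray
    threshold: float = 0.9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pct, index=self.conditions, columns=self.conditions)


@dataclass(frozen=True)
class GroupComparison:
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group_a, group_b, p_adj


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    Returns the undefined marker (NaN) when both variances and the mean gap
    are zero (two identical constant vectors carry no agreement information).
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    vx, vy = x.var(), y.var()
    gap = (x.mean() - y.mean()) ** 2
    denom = vx + vy + gap
    if denom == 0:
        return UNDEFINED
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / denom)


def dynamic_range(x, y) -> float:
    """Normalized dynamic range: 1 - mean|x - y| / pooled observed range.

    Near 1 means the feature's between-object range is large relative to its
    test–retest differences. With zero pooled range: 1 if all paired
    differences are zero, otherwise the undefined marker.
    """
    x, y = _paired(x, y)
    rng = float(max(x.max(), y.max()) - min(x.min(), y.min()))
    mad = float(np.abs(x - y).mean())
    if rng == 0:
        return 1.0 if mad == 0 else UNDEFINED
    return 1.0 - mad / rng


def _check_tables(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if list(a.columns) != list(b.columns):
        extra_a = set(a.columns) - set(b.columns)
        extra_b = set(b.columns) - set(a.columns)
        raise ValueError(
            f"feature catalogues differ (only in first: {sorted(extra_a)}; "
            f"only in second: {sorted(extra_b)}; or column order differs)"
        )
    if list(a.index) != list(b.index):
        raise ValueError("object sets differ between tables")


def repeatability_analysis(
    test: pd.DataFrame,
    retest: pd.DataFrame,
    c_thr: float = 0.9,
    d_thr: float = 0.9,
    condition_a: str = "test",
    condition_b: str = "retest",
) -> tuple[list[StabilityRecord], float]:
    """Per-feature CCC/DR against the cutoffs; returns records and the
    percentage of repeatable features.

    Features with undefined CCC or DR count as non-repeatable (and are
    flagged by their NaN statistic in the records).
    """
    _check_tables(test, retest)
    records: list[StabilityRecord] = []
    n_rep = 0
    for name in test.columns:
        c = ccc(test[name].to_numpy(), retest[name].to_numpy())
        d = dynamic_range(test[name].to_numpy(), retest[name].to_numpy())
        rep = bool(not math.isnan(c) and not math.isnan(d) and c >= c_thr and d >= d_thr)
        records.append(
            StabilityRecord(
                feature_name=name,
                condition_a=condition_a,
                condition_b=condition_b,
                ccc=c,
                dr=d,
                repeatable=rep,
                reproducible=bool(not math.isnan(c) and c >= c_thr),
                ccc_threshold=c_thr,
                dr_threshold=d_thr,
            )
        )
        n_rep += rep
    pct = 100.0 * n_rep / len(test.columns)
    return records, pct


def reproducibility_analysis(
    tables: dict[str, pd.DataFrame], c_thr: float = 0.9
) -> ReproducibilityMatrix:
    """Pairwise percentage of features with CCC >= threshold across conditions.

    The diagonal is 100% by definition. Features whose CCC is undefined for a
    pair count as failing for that pair unless they are degenerate
    (constant and identical) in *both* conditions of every pair, which cannot
    occur with continuous features; the conservative rule is documented.
    """
    keys = tuple(tables)
    first = tables[keys[0]]
    for k in keys[1:]:
        _check_tables(first, tables[k])
    n = len(keys)
    pct = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = tables[keys[i]], tables[keys[j]]
            ok = 0
            for name in first.columns:
                c = ccc(a[name].to_numpy(), b[name].to_numpy())
                ok += bool(not math.isnan(c) and c >= c_thr)
            pct[i, j] = pct[j, i] = 100.0 * ok / len(first.columns)
    return ReproducibilityMatrix(conditions=keys, pct=pct, threshold=c_thr)


def compare_percentages(groups: dict[str, np.ndarray | list]) -> GroupComparison:
    """One-way ANOVA over groups of percentages, with Tukey HSD pairwise
    adjusted p-values.

    With zero variance everywhere (all groups identical), returns the
    documented early result F = 0, p = 1 and all Tukey p-values 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    names = list(arrays)
    pooled = np.concatenate(list(arrays.values()))
    means = {k: float(v.mean()) for k, v in arrays.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in arrays.items()}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if pooled.var() == 0:
        tukey_df = pd.DataFrame(
            [(a, b, 1.0) for a, b in pairs], columns=["group_a", "group_b", "p_adj"]
        )
        return GroupComparison(means, sds, 0.0, 1.0, tukey_df)
    f_stat, p_val = stats.f_oneway(*arrays.values())
    res = stats.tukey_hsd(*arrays.values())
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rows.append((a, names[j], float(res.pvalue[i, j])))
    tukey_df = pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])
    return GroupComparison(means, sds, float(f_stat), float(p_val), tukey_df)


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of stability records (one row per feature)."""
    return pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in records],
            "condition_a": [r.condition_a for r in records],
            "condition_b": [r.condition_b for r in records],
            "ccc": [r.ccc for r in records],
            "dr": [r.dr for r in records],
            "repeatable": [r.repeatable for r in records],
            "reproducible": [r.reproducible for r in records],
        }
    )
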