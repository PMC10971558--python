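"""Tumor growth analysis from caliper measurements.

Volumes follow the modified-ellipsoid caliper formula V = ½·L·W² (length =
longest dimension, width perpendicular to it). Group comparison uses
one-way fixed-effects ANOVA on raw volumes followed by pairwise Welch
(unequal-variance) t-tests with Bonferroni correction, matching the usual
preclinical mean ± SD reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tumor_volume",
    "percent_reduction",
    "group_summaries",
    "anova_oneway",
    "welch_pairwise",
    "ComparisonResult",
    "GROUP_LABELS",
]

GROUP_LABELS = ("control", "RT2Gy", "RT5Gy", "FUS-HT", "FUS-HT+RT2Gy")


def tumor_volume(length_mm, width_mm):
    """Caliper volume V = ½·L·W² in mm³; requires 0 < width ≤ length."""
    L = np.asarray(length_mm, dtype=np.float64)
    W = np.asarray(width_mm, dtype=np.float64)
    if np.any(W <= 0) or np.any(L <= 0):
        raise ValueError("length and width must be positive")
    if np.any(W > L * (1 + 1e-12)):
        raise ValueError("width must not exceed length (orientation violation)")
    v = L * W**2 / 2
    return float(v) if np.isscalar(length_mm) and np.isscalar(width_mm) else v


def percent_reduction(mean_treated: float, mean_control: float) -> float:
    """Percent volume reduction of a treated arm relative to control."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_control - mean_treated) / mean_control


def group_summaries(records: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Per-group n / mean / SD of caliper volumes.

    ``records`` columns: animal_id, group, day, length_mm, width_mm.
    Returns one row per (group, day) with columns group, day, n,
    mean_volume_mm3, sd_volume_mm3 (SD is the sample SD, ddof=1; 0 for
    singleton groups).
    """
    required = {"animal_id", "group", "day", "length_mm", "width_mm"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records if day is None else records[records["day"] == day]
    if df.empty:
        raise ValueError("no records for the requested day")
    df = df.assign(volume_mm3=tumor_volume(df["length_mm"].to_numpy(),
                                           df["width_mm"].to_numpy()))
    out = (
        df.groupby(["group", "day"], sort=True)["volume_mm3"]
        .agg(n="size", mean_volume_mm3="mean",
             sd_volume_mm3=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out


def _volumes_by_group(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame, day: int | None = None
) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        df = groups if day is None else groups[groups["day"] == day]
        vols = tumor_volume(df["length_mm"].to_numpy(), df["width_mm"].to_numpy())
        return {
            g: np.asarray(vols[df["group"].to_numpy() == g], dtype=np.float64)
            for g in pd.unique(df["group"])
        }
    return {g: np.asarray(v, dtype=np.float64) for g, v in groups.items()}


def anova_oneway(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame, day: int | None = None
) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA on raw volumes → (F, p).

    Accepts either a mapping of group → volume list or a caliper record
    frame (volumes computed on the fly). The degenerate case of zero
    total variance returns (0, 1).
    """
    data = list(_volumes_by_group(groups, day).values())
    if len(data) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(v) < 2 for v in data):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*data)
    return float(f), float(p)


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise test with its multiplicity-adjusted p-value."""

    test: str
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool
    alpha: float = 0.05


def welch_pairwise(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    m: int | None = None,
    alpha: float = 0.05,
    day: int | None = None,
) -> list[ComparisonResult]:
    """Welch two-sample t-tests with Bonferroni correction.

    ``m`` is the Bonferroni multiplier (defaults to the number of
    comparisons performed); adjusted p = min(1, m·p). Degrees of freedom
    are Welch–Satterthwaite; p-values two-sided.
    """
    data = _volumes_by_group(groups, day)
    if m is None:
        m = len(comparisons)
    if m < 1:
        raise ValueError("correction count m must be at least 1")
    results: list[ComparisonResult] = []
    for a, b in comparisons:
        for g in (a, b):
            if g not in data:
                raise ValueError(f"unknown group {g!r}")
            if len(data[g]) < 2:
                raise ValueError(f"group {g!r} needs at least two observations")
        res = stats.ttest_ind(data[a], data[b], equal_var=False)
        p_adj = min(1.0, float(res.pvalue) * m)
        results.append(
            ComparisonResult(
                test="welch_t",
                group_a=a,
                group_b=b,
                statistic=float(res.statistic),
                df=float(res.df),
                p_raw=float(res.pvalue),
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
                alpha=alpha,
            )
        )
    return results
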