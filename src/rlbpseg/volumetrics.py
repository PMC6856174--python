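"""Volumetric group analysis: head-size correction and Cohen's d effect sizes.

Structure volumes scale with head size, so measured volumes are first
normalized by intracranial volume (ICV):

    corrected = measured * ICV_mean / ICV,

with ICV_mean the mean intracranial volume over the analysis cohort; all
volumes in cm^3.  Group separations are then quantified with Cohen's d
using the pooled standard deviation

    d = (m1 - m2) / sqrt((SD1^2 + SD2^2) / 2),

categorized by |d| as small (< 0.5), medium (0.5 - 0.8) or large (> 0.8);
the boundary values are assigned to the higher category.

:func:`group_effect_table` accepts either raw per-subject rows (columns
subject, group, side, method, volume_cm3, icv_cm3) or precomputed (mean,
sd) sufficient statistics per (group, side, method), so published summary
tables can be fed in directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EffectSize",
    "correct_volume",
    "cohens_d",
    "categorize",
    "group_effect_table",
]


@dataclass(frozen=True)
class EffectSize:
    d: float
    category: str  # "small" | "medium" | "large"


def correct_volume(measured: float, icv: float, icv_mean: float):
    """ICV-normalized volume ``measured * icv_mean / icv`` (cm^3).

    Accepts scalars or arrays (``icv`` elementwise positive).
    """
    icv_arr = np.asarray(icv, dtype=np.float64)
    if np.any(icv_arr <= 0):
        raise ValueError("ICV must be positive")
    out = np.asarray(measured, dtype=np.float64) * (float(icv_mean) / icv_arr)
    return float(out) if out.ndim == 0 else out


def categorize(d: float) -> str:
    """Effect-size category from |d|; 0.5 and 0.8 go to the higher class."""
    a = abs(d)
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def cohens_d(m1: float, sd1: float, m2: float, sd2: float) -> EffectSize:
    """Cohen's d with the pooled SD ``sqrt((sd1^2 + sd2^2) / 2)``.

    Antisymmetric in group order; raises if both SDs are zero.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if pooled == 0:
        raise ValueError("both group SDs are zero; effect size undefined")
    d = (m1 - m2) / pooled
    return EffectSize(float(d), categorize(d))


def _sufficient_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a table to (group, side, method) -> mean, sd of corrected volume.

    Raw per-subject tables are ICV-corrected first (ICV_mean over the unique
    subjects in the table); tables that already carry mean/sd columns are
    passed through.
    """
    if {"mean", "sd"}.issubset(table.columns):
        return table[["group", "side", "method", "mean", "sd"]].copy()
    required = {"subject", "group", "side", "method", "volume_cm3", "icv_cm3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"volume table is missing columns {sorted(missing)}")
    icv_mean = table.drop_duplicates("subject")["icv_cm3"].mean()
    corrected = correct_volume(
        table["volume_cm3"].to_numpy(), table["icv_cm3"].to_numpy(), icv_mean
    )
    work = table.assign(corrected=corrected)
    stats = (
        work.groupby(["group", "side", "method"])["corrected"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return stats


def group_effect_table(table: pd.DataFrame, pairs) -> pd.DataFrame:
    """Cohen's d per (group pair, side, method) from corrected volumes.

    ``pairs`` is an iterable of (group1, group2) tuples; d is computed as
    group1 minus group2.  Returns a frame with columns pair, side, method,
    d, category.
    """
    stats = _sufficient_stats(table)
    keyed = stats.set_index(["group", "side", "method"])
    rows = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in stats["group"].values:
                raise ValueError(f"group {g!r} not present in the volume table")
        for side in stats["side"].unique():
            for method in stats["method"].unique():
                try:
                    s1 = keyed.loc[(g1, side, method)]
                    s2 = keyed.loc[(g2, side, method)]
                except KeyError:
                    continue
                es = cohens_d(s1["mean"], s1["sd"], s2["mean"], s2["sd"])
                rows.append({
                    "pair": f"{g1}-{g2}", "side": side, "method": method,
                    "d": es.d, "category": es.category,
                })
    return pd.DataFrame(rows)
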