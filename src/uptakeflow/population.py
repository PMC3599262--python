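"""Condition-level summaries, quench/inhibition arithmetic and hypothesis tests.

MFI here means the population statistic of per-cell fluorescence intensity:
classic flow cytometry reports the median over >= 10,000 gated cells, the
imaging path the mean over >= 500 cells.  Trypan Blue (TB) quenching removes
extracellular fluorescence, so the post-TB / pre-TB MFI ratio estimates the
internalized fraction; uptake inhibition is the fractional MFI drop of a
treated condition relative to an untreated reference.  Group comparisons use
one-way ANOVA followed by Bonferroni-corrected pairwise post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

_STATISTICS = ("median", "mean")

# sample-size warnings mirroring typical acquisition practice
MIN_CELLS_IMAGING = 500
MIN_CELLS_FCM = 10000


@dataclass
class PopulationSummary:
    condition: str
    n_cells: int
    MFI: float
    mean_IS: float
    sd_IS: float
    statistic_used: str
    low_n_warning: bool


@dataclass
class QuenchResult:
    """Internalized fraction from MFI measured without and with Trypan Blue."""

    mfi_without_tb: float
    mfi_with_tb: float
    internalized_percent: float
    adsorbed_percent: float
    quench_efficiency: float
    capped: bool


@dataclass
class InhibitionResult:
    mfi_reference: float
    mfi_condition: float
    mfi_background: float
    inhibition_percent: float
    clipped: bool


def summarize_population(
    features: pd.DataFrame,
    condition: str | Sequence = "condition",
    statistic: str = "median",
    value_column: str = "I_total",
    is_column: str = "IS",
    min_cells: int = MIN_CELLS_IMAGING,
) -> pd.DataFrame:
    """Per-condition MFI and Internalization Score summary.

    ``condition`` names a column of ``features`` or supplies per-row labels.
    Rows flagged by QC (``included == False``) are excluded first.  Values
    are sorted before the median so the result is independent of input
    order.  A ``low_n_warning`` is raised when fewer than ``min_cells``
    events survive QC.
    """
    if statistic not in _STATISTICS:
        raise ValidationError(f"statistic must be one of {_STATISTICS}")
    df = features.copy()
    if isinstance(condition, str):
        if condition not in df.columns:
            raise ValidationError(f"no condition column {condition!r} in table")
        cond_col = condition
    else:
        if len(condition) != len(df):
            raise ValidationError("condition labels do not match table length")
        df = df.assign(_condition=list(condition))
        cond_col = "_condition"
    labels = pd.unique(df[cond_col])  # before QC, so emptied conditions error
    if "included" in df.columns:
        df = df[df["included"].astype(bool)]

    rows = []
    for label in labels:
        grp = df[df[cond_col] == label]
        values = np.sort(np.asarray(grp[value_column], dtype=float))
        if values.size == 0:
            raise ValidationError(f"condition {label!r} has no events after QC")
        mfi = float(np.median(values) if statistic == "median" else np.mean(values))
        if is_column in grp.columns:
            is_vals = np.asarray(grp[is_column], dtype=float)
            mean_is = float(np.mean(is_vals))
            sd_is = float(np.std(is_vals, ddof=1)) if is_vals.size > 1 else 0.0
        else:
            mean_is, sd_is = np.nan, np.nan
        rows.append(
            PopulationSummary(
                condition=str(label),
                n_cells=int(values.size),
                MFI=mfi,
                mean_IS=mean_is,
                sd_IS=sd_is,
                statistic_used=statistic,
                low_n_warning=bool(values.size < min_cells),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def quench_internalized_percent(
    mfi_without_tb: float,
    mfi_with_tb: float,
    quench_efficiency: float = 1.0,
) -> QuenchResult:
    """Internalized percentage from the TB-quench MFI pair.

    With perfect quenching (``quench_efficiency = 1``) the internalized
    percentage is simply ``100 * mfi_with_tb / mfi_without_tb`` — e.g. an MFI
    that drops by 25% after TB means 75% of the probe was internalized.  A
    quench efficiency q < 1 models dye that fails to extinguish part of the
    surface signal: internalized% = 100 * (r - (1 - q)) / q with r the MFI
    ratio.  Results are capped to [0, 100] with ``capped`` set when the raw
    value falls outside.
    """
    if mfi_without_tb <= 0:
        raise ValidationError("mfi_without_tb must be > 0")
    if mfi_with_tb < 0:
        raise ValidationError("mfi_with_tb must be >= 0")
    if not 0 < quench_efficiency <= 1:
        raise ValidationError("quench_efficiency must be in (0, 1]")
    r = mfi_with_tb / mfi_without_tb
    raw = 100.0 * (r - (1.0 - quench_efficiency)) / quench_efficiency
    capped = not 0.0 <= raw <= 100.0
    internalized = float(np.clip(raw, 0.0, 100.0))
    return QuenchResult(
        mfi_without_tb=mfi_without_tb,
        mfi_with_tb=mfi_with_tb,
        internalized_percent=internalized,
        adsorbed_percent=100.0 - internalized,
        quench_efficiency=quench_efficiency,
        capped=capped,
    )


def inhibition_percent(
    mfi_reference: float, mfi_condition: float, mfi_background: float = 0.0
) -> InhibitionResult:
    """Percent inhibition of uptake relative to an untreated reference.

    ``100 * (1 - (condition - background) / (reference - background))``,
    clipped to [0, 100] with a flag.  Zero when the condition equals the
    reference, 100 when it falls to the background level.
    """
    if mfi_background < 0:
        raise ValidationError("mfi_background must be >= 0")
    if mfi_reference <= mfi_background:
        raise ValidationError("mfi_reference must exceed mfi_background")
    raw = 100.0 * (
        1.0 - (mfi_condition - mfi_background) / (mfi_reference - mfi_background)
    )
    clipped = not 0.0 <= raw <= 100.0
    return InhibitionResult(
        mfi_reference=mfi_reference,
        mfi_condition=mfi_condition,
        mfi_background=mfi_background,
        inhibition_percent=float(np.clip(raw, 0.0, 100.0)),
        clipped=clipped,
    )


def anova_bonferroni(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA followed by Bonferroni-corrected pairwise post hoc tests.

    Pairwise comparisons use the pooled within-group mean square from the
    ANOVA (the classic Bonferroni t-test), with p_adj = min(1, p * m) over
    the m = k(k-1)/2 pairwise comparisons.  Zero-variance degenerate input
    is reported as p = 1 with a ``degenerate`` flag instead of NaN.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 values")
        arrays[label] = arr

    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    df_within = n_total - k
    grand = np.concatenate(list(arrays.values()))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ms_within = ss_within / df_within
    degenerate = np.ptp(grand) == 0 or ms_within == 0

    if np.ptp(grand) == 0:
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*arrays.values())
        if not np.isfinite(p_anova):
            p_anova = 1.0

    pairs = []
    m = k * (k - 1) // 2
    for a, b in combinations(arrays, 2):
        xa, xb = arrays[a], arrays[b]
        diff = xa.mean() - xb.mean()
        if ms_within == 0:
            p_raw = 1.0 if diff == 0 else 0.0
            t_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            se = np.sqrt(ms_within * (1 / xa.size + 1 / xb.size))
            t_stat = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t_stat), df_within)
        p_adj = min(1.0, p_raw * m)
        pairs.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_adj": float(p_adj),
                "significant": bool(p_adj < alpha),
            }
        )
    return {
        "anova": {
            "F": float(f_stat),
            "p": float(p_anova),
            "df_between": k - 1,
            "df_within": df_within,
            "degenerate": bool(degenerate),
        },
        "pairwise": pairs,
        "n_comparisons": m,
        "alpha": alpha,
    }
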