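"""Behavioral statistics of the simulated records.

Per-type summary tables (counts, percentages, SRT medians/means/STD/skew),
6-ms SRT histograms, attribute-effect analyses (median shift, Cohen's d,
Kruskal-Wallis, chi-square selection), and the anti-saccade difference curve
with its Voluntary Override Time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ANTI_TYPES, PRO_TYPES, SACCADE_TYPES
from .protocol import LEVELS, VARIED_ATTRIBUTES

#: behaviors with free-ranging SRT (express types are window-confined)
SHIFT_BEHAVIORS = ("regular_pro", "correct_anti", "regular_error")

TASK_OF_TYPE = {t: "pro" for t in PRO_TYPES}
TASK_OF_TYPE.update({t: "anti" for t in ANTI_TYPES})


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-type behavioral summary (the machine twin of the model's
    behavioral table).

    Percentages are per task: pro types over pro trials, anti types over
    anti trials.  SRT standard deviation uses the sample (n-1) denominator;
    skewness is the adjusted Fisher-Pearson estimator.
    """
    if records.empty:
        raise ValueError("empty record set")
    task_n = records.groupby("task").size()
    rows = []
    for ty in SACCADE_TYPES:
        g = records[records["saccade_type"] == ty]
        n = len(g)
        denom = task_n.get(TASK_OF_TYPE[ty], 0)
        srt = g["srt"].to_numpy(dtype=float)
        rows.append({
            "saccade_type": ty,
            "task": TASK_OF_TYPE[ty],
            "count": n,
            "percent": 100.0 * n / denom if denom else np.nan,
            "median_srt": float(np.median(srt)) if n else np.nan,
            "mean_srt": float(np.mean(srt)) if n else np.nan,
            "std_srt": float(np.std(srt, ddof=1)) if n > 1 else
            (0.0 if n == 1 else np.nan),
            "skewness": float(stats.skew(srt, bias=False))
            if n > 2 and np.ptp(srt) > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("saccade_type")


def srt_histogram(records: pd.DataFrame, bin_ms: float = 6.0,
                  t_max: float = 600.0) -> Dict[str, pd.DataFrame]:
    """Instantaneous and cumulative SRT histograms per saccade type.

    Bin edges are aligned at 0 ms; the cumulative curve is in percent of the
    type's task trials, so it saturates at the type's percentage.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    edges = np.arange(0.0, t_max + bin_ms, bin_ms)
    task_n = records.groupby("task").size()
    out = {}
    for ty in SACCADE_TYPES:
        g = records[records["saccade_type"] == ty]
        counts, _ = np.histogram(g["srt"].to_numpy(dtype=float), bins=edges)
        denom = task_n.get(TASK_OF_TYPE[ty], 0)
        pct = 100.0 * counts / denom if denom else np.full_like(counts, np.nan,
                                                               dtype=float)
        out[ty] = pd.DataFrame({
            "bin_left": edges[:-1], "bin_right": edges[1:],
            "count": counts, "percent": pct,
            "cumulative_percent": np.cumsum(pct),
        })
    return out


def median_shift(records: pd.DataFrame, attribute: str,
                 behaviors: Sequence[str] = SHIFT_BEHAVIORS) -> pd.Series:
    """Median SRT at the large level minus median SRT at the small level,
    per behavior."""
    if attribute not in VARIED_ATTRIBUTES:
        raise KeyError(f"unknown attribute {attribute!r}")
    out = {}
    for ty in behaviors:
        g = records[records["saccade_type"] == ty]
        small = g.loc[g[attribute] == "small", "srt"]
        large = g.loc[g[attribute] == "large", "srt"]
        if small.empty or large.empty:
            raise ValueError(f"empty subgroup for {attribute}/{ty}")
        out[ty] = float(large.median() - small.median())
    return pd.Series(out, name=attribute)


def cohens_d(shift: float, behavior_std: float) -> float:
    """Effect size: the median shift normalized by the behavior's full-SRT
    standard deviation."""
    if behavior_std <= 0:
        raise ValueError("behavior_std must be positive")
    return shift / behavior_std


def kruskal_wallis(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Rank-based H test (tie-corrected) across the small/medium/large
    subgroups; p from the chi-square approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def selection_chi_square(records: pd.DataFrame, attribute: str,
                         saccade_type: str,
                         levels: Sequence[str] = LEVELS,
                         normalize_to: Optional[float] = None
                         ) -> Tuple[float, float, pd.Series]:
    """Goodness-of-fit of the attribute's level distribution within one
    saccade type against uniform thirds.

    By default the raw level counts are tested.  With ``normalize_to`` the
    observed distribution is rescaled to that base (e.g. 100 to test the
    level *percentages*) before computing the statistic.  The normalized
    test is the one used for the selection-analysis significance
    classification: with tens of thousands of trials per behavior, a
    count-based test flags miniscule proportion differences, whereas the
    question of interest is whether a setting materially selects for a
    behavior.
    """
    g = records[records["saccade_type"] == saccade_type]
    if g.empty:
        raise ValueError(f"no records of type {saccade_type}")
    observed = np.array([(g[attribute] == lev).sum() for lev in levels],
                        dtype=float)
    props = pd.Series(observed / observed.sum(), index=list(levels),
                      name=f"{attribute}:{saccade_type}")
    if normalize_to is not None:
        observed = normalize_to * observed / observed.sum()
    chi2, p = stats.chisquare(observed)
    return float(chi2), float(p), props


def attribute_effects(records: pd.DataFrame) -> pd.DataFrame:
    """Per-attribute effect table: median shift, Cohen's d and
    Kruskal-Wallis for the three free-latency behaviors."""
    stds = {ty: records.loc[records["saccade_type"] == ty, "srt"]
            .std(ddof=1) for ty in SHIFT_BEHAVIORS}
    rows = []
    for attr in VARIED_ATTRIBUTES:
        shifts = median_shift(records, attr)
        row: Dict[str, float] = {"attribute": attr}
        for ty in SHIFT_BEHAVIORS:
            g = records[records["saccade_type"] == ty]
            groups = [g.loc[g[attr] == lev, "srt"].to_numpy()
                      for lev in LEVELS]
            h, p = kruskal_wallis(groups)
            row[f"{ty}_shift"] = shifts[ty]
            row[f"{ty}_d"] = cohens_d(shifts[ty], stds[ty])
            row[f"{ty}_kw_h"] = h
            row[f"{ty}_kw_p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute")


def selection_table(records: pd.DataFrame) -> pd.DataFrame:
    """Chi-square selection analysis for all attributes x saccade types:
    raw-count and percentage-normalized statistics side by side."""
    rows = []
    for ty in SACCADE_TYPES:
        for attr in VARIED_ATTRIBUTES:
            chi2, p, props = selection_chi_square(records, attr, ty)
            chi2_pct, p_pct, _ = selection_chi_square(records, attr, ty,
                                                      normalize_to=100.0)
            rows.append({"saccade_type": ty, "attribute": attr,
                         "chi2": chi2, "p": p,
                         "chi2_pct": chi2_pct, "p_pct": p_pct,
                         **{f"prop_{lev}": props[lev] for lev in LEVELS}})
    return pd.DataFrame(rows)


@dataclass
class DifferenceCurve:
    """Cumulative percent correct-anti minus cumulative percent direction
    error, on the 6-ms histogram grid (percent of anti-task trials)."""

    time: np.ndarray   # right edge of each bin, ms
    value: np.ndarray
    override_time: Optional[float] = None


def anti_difference_curve(records: pd.DataFrame, bin_ms: float = 6.0,
                          t_max: float = 600.0) -> DifferenceCurve:
    """Anti-saccade difference curve from stimulus appearance to
    ``t_max``."""
    anti = records[records["task"] == "anti"]
    if anti.empty:
        raise ValueError("no anti-task records")
    edges = np.arange(0.0, t_max + bin_ms, bin_ms)
    correct = anti.loc[anti["saccade_type"] == "correct_anti", "srt"]
    error = anti.loc[anti["saccade_type"].isin(
        ["regular_error", "express_error"]), "srt"]
    c, _ = np.histogram(correct.to_numpy(float), bins=edges)
    e, _ = np.histogram(error.to_numpy(float), bins=edges)
    diff = 100.0 * np.cumsum(c - e) / len(anti)
    curve = DifferenceCurve(time=edges[1:], value=diff)
    curve.override_time = voluntary_override_time(curve)
    return curve


def voluntary_override_time(curve: DifferenceCurve,
                            rise: float = 1.0) -> Optional[float]:
    """Time at which voluntary drive overcomes the automated drive.

    The first bin after the curve's global minimum whose value exceeds the
    immediately preceding bin's value by at least ``rise`` (percentage
    points); None if the curve never recovers that fast.
    """
    v = np.asarray(curve.value, dtype=float)
    if v.size < 2:
        return None
    lo = int(np.argmin(v))
    for b in range(lo + 1, v.size):
        if v[b] - v[b - 1] >= rise:
            return float(curve.time[b])
    return None


__all__ = [
    "SHIFT_BEHAVIORS", "TASK_OF_TYPE", "summarize", "srt_histogram",
    "median_shift", "cohens_d", "kruskal_wallis", "selection_chi_square",
    "attribute_effects", "selection_table", "DifferenceCurve",
    "anti_difference_curve", "voluntary_override_time",
]
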