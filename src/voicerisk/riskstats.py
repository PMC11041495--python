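"""Aggregation of attack outcomes and trend statistics.

The central question — does reidentification risk scale with the search
space? — is answered by correlating per-split false-acceptance counts with
the number of comparisons (or a set size) across many random splits, with a
two-tailed t test on the Pearson coefficient:

    t = r * sqrt(df / (1 - r^2)),  df = n - 2,

p-values from the exact Student t distribution.  Per-configuration summaries
report mean/SD of TA, FA, FAR and precision; because per-run precision is
undefined when a run accepts nothing, the precision mean excludes those runs
and the count of exclusions is reported.  The FA/TA ratio is the ratio of the
mean counts (the headline convention), alongside the mean of per-run
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attack import RiskSummary
from .exceptions import DegenerateDataError, ValidationError

__all__ = ["TrendResult", "fa_trend", "trend", "aggregate"]

_X_AXES = ("comparisons", "n_known", "n_unknown")


@dataclass(frozen=True)
class TrendResult:
    """Pearson correlation with its exact small-sample t test."""

    r: float
    n: int
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.df != self.n - 2:
            raise ValidationError("df must equal n - 2")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must lie in [0, 1]")


def trend(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Pearson r between two samples, with the two-tailed exact-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValidationError("x and y must have equal length")
    if n < 3:
        raise DegenerateDataError("a correlation trend needs n >= 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise DegenerateDataError("y is constant; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TrendResult(r=r, n=n, t=t, df=df, p=min(p, 1.0))


def fa_trend(
    summaries: Sequence[RiskSummary],
    x_axis: str = "comparisons",
) -> TrendResult:
    """Correlation between per-split FA counts and the search-space axis."""
    if x_axis not in _X_AXES:
        raise ValidationError(f"x_axis must be one of {_X_AXES}")
    x = [getattr(s, x_axis) for s in summaries]
    y = [s.fa for s in summaries]
    return trend(x, y)


def _ratio_of_means(mean_fa: float, mean_ta: float) -> float:
    if mean_ta > 0:
        return mean_fa / mean_ta
    return math.inf if mean_fa > 0 else math.nan


def aggregate(
    summaries: Sequence[RiskSummary],
    by: str = "group",
) -> pd.DataFrame:
    """Per-configuration summary table of attack outcomes.

    Groups summaries by ``descriptor[by]`` (falling back to the
    (n_known, n_unknown, n_overlap) triple when the key is absent) and
    reports one row per group: mean/SD of TA, FA, FAR; mean per-run precision
    over the runs where it is defined, with the number of excluded runs; and
    the FA/TA ratio of the mean counts.
    """
    if not summaries:
        raise DegenerateDataError("aggregate requires at least one summary")

    def key(s: RiskSummary):
        return s.descriptor.get(by, (s.n_known, s.n_unknown, s.n_overlap))

    groups: dict = {}
    for s in summaries:
        groups.setdefault(key(s), []).append(s)

    rows = []
    for group_key, members in groups.items():
        # sorting before reduction makes the output exactly permutation-
        # invariant (float summation order would otherwise leak through)
        ta = np.sort([s.ta for s in members]).astype(float)
        fa = np.sort([s.fa for s in members]).astype(float)
        far = np.sort([s.far for s in members]).astype(float)
        prec = np.sort([s.precision for s in members if s.precision is not None]).astype(float)
        comparisons = np.sort([s.comparisons for s in members]).astype(float)
        rows.append(
            {
                "group": group_key,
                "n_runs": len(members),
                "mean_comparisons": comparisons.mean(),
                "mean_ta": ta.mean(),
                "sd_ta": ta.std(ddof=1) if len(ta) > 1 else 0.0,
                "mean_fa": fa.mean(),
                "sd_fa": fa.std(ddof=1) if len(fa) > 1 else 0.0,
                "mean_far": far.mean(),
                "sd_far": far.std(ddof=1) if len(far) > 1 else 0.0,
                "mean_precision": prec.mean() if len(prec) else math.nan,
                "sd_precision": prec.std(ddof=1) if len(prec) > 1 else 0.0,
                "n_precision_undefined": len(members) - len(prec),
                "fa_ta_of_means": _ratio_of_means(fa.mean(), ta.mean()),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean_comparisons", kind="stable").reset_index(drop=True)
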