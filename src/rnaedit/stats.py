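"""Statistical primitives shared across the pipeline.

Welch's unequal-variance two-sample t-test (the group comparison used for
every differential readout), Pearson correlation, delta-delta-CT relative
expression, and fold/percent-change summaries.  Sample (n-1) variance is
used throughout; p-values are two-sided by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and standard error of the mean for one labeled group."""

    n: int
    mean: float
    sem: float
    label: str = ""

    @classmethod
    def from_values(cls, values: Sequence[float], label: str = "") -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 1:
            raise ValueError("group summary needs at least one value")
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        return cls(n=int(arr.size), mean=float(arr.mean()), sem=sem, label=label)


@dataclass(frozen=True)
class WelchResult:
    """Welch t statistic, Welch-Satterthwaite df, and two-sided p."""

    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(
    x: Sequence[float], y: Sequence[float], one_sided: bool = False
) -> WelchResult:
    """Two-sample t-test assuming unequal variances.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny) with Welch-Satterthwaite
    degrees of freedom.  When both variances are zero the test degenerates:
    equal means give t=0, p=1; unequal means give p=0, flagged.
    """
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size < 2 or ay.size < 2:
        raise ValueError("each group needs at least two observations")
    vx, vy = ax.var(ddof=1), ay.var(ddof=1)
    diff = ax.mean() - ay.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return WelchResult(t=0.0, df=float(ax.size + ay.size - 2), p=1.0)
        return WelchResult(
            t=math.copysign(math.inf, diff),
            df=float(ax.size + ay.size - 2),
            p=0.0,
            degenerate=True,
        )
    se2 = vx / ax.size + vy / ay.size
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (vx / ax.size) ** 2 / (ax.size - 1) + (vy / ay.size) ** 2 / (ay.size - 1)
    )
    tail = sps.t.sf(abs(t), df)
    p = tail if one_sided else 2.0 * tail
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation; returns ``(r, r_squared)``."""
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.size != ay.size:
        raise ValueError("x and y must have equal length")
    if ax.size < 3:
        raise ValueError("need at least three paired observations")
    if ax.var() == 0 or ay.var() == 0:
        raise ValueError("correlation undefined with zero variance")
    r = float(sps.pearsonr(ax, ay).statistic)
    return r, r * r


def ddct_relative_expression(
    ct_target: dict[str, float],
    ct_reference: dict[str, float],
    calibrator_samples: Sequence[str],
) -> dict[str, float]:
    """Relative expression by the delta-delta-CT method.

    Per sample, 2^-(CT_target - CT_reference); each value is then divided
    by the mean of that quantity over the calibrator group (e.g. all WT
    samples), so the calibrator-group mean of the output is exactly 1.
    Samples missing a reference CT are dropped with a log message.
    """
    import logging

    log = logging.getLogger(__name__)
    raw: dict[str, float] = {}
    for sample, ct in ct_target.items():
        if sample not in ct_reference:
            log.warning("ddct: dropping sample %s with no reference CT", sample)
            continue
        raw[sample] = 2.0 ** -(ct - ct_reference[sample])
    calibrators = [s for s in calibrator_samples if s in raw]
    if not calibrators:
        raise ValueError("no calibrator sample has both CT values")
    baseline = float(np.mean([raw[s] for s in calibrators]))
    return {s: v / baseline for s, v in raw.items()}


def fold_and_percent_change(
    group_a: GroupSummary, group_b: GroupSummary
) -> tuple[float, float]:
    """``(mean_b / mean_a, 100 * (mean_b / mean_a - 1))``.

    Unrounded; format with :func:`format_fold` / :func:`format_percent`
    for report style (fold to one decimal, percent to the nearest integer).
    """
    if group_a.mean <= 0:
        raise ValueError("fold change undefined for non-positive baseline mean")
    fold = group_b.mean / group_a.mean
    return fold, 100.0 * (fold - 1.0)


def format_fold(fold: float) -> float:
    return round(fold, 1)


def format_percent(percent: float) -> int:
    return round(percent)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
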