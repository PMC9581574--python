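"""Cross-animal signal-independence QC.

Pairwise Pearson correlations between hour-long traces are grouped into
three comparison categories:

* ``within_mouse_same_hour`` — left vs right channel of the same mouse,
  same hour (one pair per mouse per hour);
* ``between_mice_same_hour`` — channels of different mice recorded
  simultaneously;
* ``between_mice_different_hours`` — the same cross-mouse channel pairs
  re-paired at a +1 (circular) hour offset, giving a chance-level control
  with the same number of comparisons as the simultaneous category.

Cross-mouse pairs compare same-position channels (left-left and
right-right), which for 4 mice x 24 hours yields 96 / 288 / 288
comparisons in the three categories. Both the channel pairing and the
hour-offset rule are reconstructions: only the category counts are
documented, not the enumeration.

Category differences are assessed with a one-way ANOVA and Tukey's HSD
post hoc test.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError


class ComparisonCategory(str, Enum):
    WITHIN_MOUSE_SAME_HOUR = "within_mouse_same_hour"
    BETWEEN_MICE_SAME_HOUR = "between_mice_same_hour"
    BETWEEN_MICE_DIFFERENT_HOURS = "between_mice_different_hours"


class TracePair(NamedTuple):
    """One comparison: (mouse, channel-in-mouse, hour) on each side."""

    mouse_a: int
    channel_a: int
    hour_a: int
    mouse_b: int
    channel_b: int
    hour_b: int


def enumerate_comparisons(
    n_mice: int, n_hours: int, channels_per_mouse: int = 2
) -> dict[ComparisonCategory, list[TracePair]]:
    """Enumerate labeled trace pairs per comparison category.

    Self-comparisons and same-mouse/different-hour comparisons are
    excluded by construction.
    """
    if n_mice < 2:
        raise ParameterError("need at least 2 mice")
    if n_hours < 2:
        raise ParameterError("need at least 2 hours")
    within = [
        TracePair(m, 0, h, m, 1, h)
        for m in range(n_mice)
        for h in range(n_hours)
    ]
    between_same = [
        TracePair(ma, c, h, mb, c, h)
        for ma, mb in itertools.combinations(range(n_mice), 2)
        for c in range(channels_per_mouse)
        for h in range(n_hours)
    ]
    between_diff = [
        TracePair(p.mouse_a, p.channel_a, p.hour_a, p.mouse_b, p.channel_b,
                  (p.hour_a + 1) % n_hours)
        for p in between_same
    ]
    return {
        ComparisonCategory.WITHIN_MOUSE_SAME_HOUR: within,
        ComparisonCategory.BETWEEN_MICE_SAME_HOUR: between_same,
        ComparisonCategory.BETWEEN_MICE_DIFFERENT_HOURS: between_diff,
    }


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be 1-D vectors of equal length")
    if x.size < 2:
        raise ParameterError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ParameterError("correlation undefined for constant input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def empirical_cdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF: sorted values and cumulative fractions."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise ParameterError("ECDF of an empty sample is undefined")
    return v, np.arange(1, v.size + 1) / v.size


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between/within mean-square ratio)."""
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=float("inf"), df1=df1, df2=df2, p=0.0)
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p)


@dataclass(frozen=True)
class TukeyComparison:
    group_a: int
    group_b: int
    p: float
    significant: bool


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> list[TukeyComparison]:
    """Studentized-range pairwise comparisons of group means."""
    if len(groups) < 2:
        raise ParameterError("Tukey HSD needs at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs at least 2 values")
    if all(float(a.std()) == 0.0 for a in arrays) and len(
        {float(a.mean()) for a in arrays}
    ) == 1:
        # degenerate: identical constant groups -> nothing significant
        return [
            TukeyComparison(i, j, 1.0, False)
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
    res = stats.tukey_hsd(*arrays)
    return [
        TukeyComparison(i, j, float(res.pvalue[i, j]), bool(res.pvalue[i, j] < alpha))
        for i, j in itertools.combinations(range(len(arrays)), 2)
    ]


@dataclass
class CategoryStats:
    pairs: list[TracePair]
    correlations: np.ndarray

    @property
    def n(self) -> int:
        return int(self.correlations.size)

    @property
    def mean(self) -> float:
        return float(self.correlations.mean())

    @property
    def sem(self) -> float:
        return float(self.correlations.std(ddof=1) / np.sqrt(self.n))

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        return empirical_cdf(self.correlations)


@dataclass
class QcReport:
    """Full independence report: per-category correlations + ANOVA + Tukey."""

    categories: dict[ComparisonCategory, CategoryStats]
    anova: AnovaResult
    tukey: list[TukeyComparison]

    def to_dict(self) -> dict:
        order = list(ComparisonCategory)
        return {
            "categories": {
                cat.value: {
                    "n": cs.n,
                    "mean": cs.mean,
                    "sem": cs.sem,
                }
                for cat, cs in self.categories.items()
            },
            "anova": {
                "F": self.anova.F,
                "df_between": self.anova.df1,
                "df_within": self.anova.df2,
                "p": self.anova.p,
            },
            "tukey": [
                {
                    "pair": f"{order[t.group_a].value} vs {order[t.group_b].value}",
                    "p": t.p,
                    "significant": t.significant,
                }
                for t in self.tukey
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def correlations_frame(self) -> pd.DataFrame:
        rows = []
        for cat, cs in self.categories.items():
            for pair, r in zip(cs.pairs, cs.correlations):
                rows.append(
                    {
                        "category": cat.value,
                        "mouse_a": pair.mouse_a,
                        "channel_a": pair.channel_a,
                        "hour_a": pair.hour_a,
                        "mouse_b": pair.mouse_b,
                        "channel_b": pair.channel_b,
                        "hour_b": pair.hour_b,
                        "r": r,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "category", "mouse_a", "channel_a", "hour_a",
                "mouse_b", "channel_b", "hour_b", "r",
            ],
        )


def independence_report(traces: np.ndarray) -> QcReport:
    """Build the full QC report from an hour-segmented trace array.

    ``traces`` has shape ``[n_mice, channels_per_mouse, n_hours, n_samples]``;
    traces may be at any common rate (downsampled traces bound memory).
    """
    traces = np.asarray(traces, dtype=np.float64)
    if traces.ndim != 4:
        raise ParameterError(
            "traces must be [n_mice x channels x n_hours x n_samples]"
        )
    n_mice, n_ch, n_hours, _ = traces.shape
    if n_mice < 2:
        raise ParameterError("need at least 2 mice")
    if n_hours < 2:
        raise ParameterError(
            "need at least 2 hour-segments (different-hours category)"
        )
    comparisons = enumerate_comparisons(n_mice, n_hours, channels_per_mouse=n_ch)
    categories: dict[ComparisonCategory, CategoryStats] = {}
    for cat, pairs in comparisons.items():
        rs = np.array(
            [
                pearson_r(
                    traces[p.mouse_a, p.channel_a, p.hour_a],
                    traces[p.mouse_b, p.channel_b, p.hour_b],
                )
                for p in pairs
            ]
        )
        categories[cat] = CategoryStats(pairs=pairs, correlations=rs)
    groups = [categories[cat].correlations for cat in ComparisonCategory]
    return QcReport(
        categories=categories,
        anova=one_way_anova(groups),
        tukey=tukey_hsd(groups),
    )
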