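"""Three-group comparison of a network index with rank-sum tests and Bonferroni.

The three root-user groups are compared pairwise (3 unordered pairs) with the
two-sided Mann-Whitney-Wilcoxon test; raw p-values are multiplied by 3 and
capped at 1.  Missing (None/NaN) index values are dropped pairwise before
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GROUPS",
    "GroupedMetric",
    "GroupSummary",
    "PairResult",
    "ComparisonTable",
    "rank_sum_test",
    "bonferroni",
    "compare_groups",
]

GROUPS = ("ACE", "NON_ACE_1", "NON_ACE_2")
EXACT_MAX_N = 25  # exact enumeration below this combined size (tie-free only)


def _clean(values: Sequence[float | None]) -> np.ndarray:
    out = [v for v in values if v is not None and not math.isnan(v)]
    return np.asarray(out, dtype=float)


def rank_sum_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U statistic, p-value).

    Exact null enumeration when the combined sample is small (<= 25) and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test requires both samples non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int = 3) -> list[float]:
    """Multiply each p-value by the family size, capping at 1."""
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, m * p))
    return out


@dataclass(frozen=True)
class GroupedMetric:
    """One metric's defined values per group; missing values already excluded."""

    metric_name: str
    groups: Mapping[str, Sequence[float]]

    @classmethod
    def from_values(
        cls, metric_name: str, raw_groups: Mapping[str, Sequence[float | None]]
    ) -> "GroupedMetric":
        """Build from per-group lists that may contain None/NaN placeholders."""
        return cls(
            metric_name=metric_name,
            groups={g: list(_clean(v)) for g, v in raw_groups.items()},
        )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float | None
    sd: float | None
    median: float | None


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    statistic: float | None
    p_raw: float | None
    p_corrected: float | None


@dataclass(frozen=True)
class ComparisonTable:
    metric_name: str
    summaries: tuple[GroupSummary, ...]
    pairs: tuple[PairResult, ...]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "groups": [vars(s) for s in self.summaries],
            "pairs": [vars(p) for p in self.pairs],
        }


def _summary(group: str, values: np.ndarray) -> GroupSummary:
    if len(values) == 0:
        return GroupSummary(group=group, n=0, mean=None, sd=None, median=None)
    return GroupSummary(
        group=group,
        n=len(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else None,
        median=float(np.median(values)),
    )


def compare_groups(
    gm: GroupedMetric, group_order: Sequence[str] = GROUPS, m: int = 3
) -> ComparisonTable:
    """All pairwise rank-sum tests with family-size-``m`` Bonferroni correction.

    An untestable pair (an empty group) is reported with None entries; the
    other pairs are still tested and corrected with the same family size.
    """
    cleaned = {g: _clean(gm.groups.get(g, [])) for g in group_order}
    if sum(len(v) > 0 for v in cleaned.values()) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    summaries = tuple(_summary(g, cleaned[g]) for g in group_order)
    pairs = []
    for ga, gb in combinations(group_order, 2):
        if len(cleaned[ga]) and len(cleaned[gb]):
            stat, p = rank_sum_test(cleaned[ga], cleaned[gb])
            p_corr = bonferroni([p], m=m)[0]
        else:
            stat = p = p_corr = None
        pairs.append(
            PairResult(
                group_a=ga, group_b=gb, statistic=stat, p_raw=p, p_corrected=p_corr
            )
        )
    return ComparisonTable(
        metric_name=gm.metric_name, summaries=summaries, pairs=tuple(pairs)
    )
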