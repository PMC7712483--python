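"""Cohort statistics: 1-in-N incidences, group summaries, and Wilcoxon
rank-sum comparisons.

Conventions match the screening program's reporting: incidence denominators
round half-up to the nearest integer; medians use the midpoint convention
(mean of the two central order statistics for even n); quartiles use linear
interpolation; the rank-sum test uses mid-ranks for ties, exact enumeration
for small samples and a tie-corrected, continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import norm, rankdata

from .diagnosis import DiagnosisLabel
from .errors import ConsistencyError, DomainError, EmptyGroupError

#: Largest pooled sample size for which the exact enumeration is used.
EXACT_ENUMERATION_LIMIT = 12


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Incidence:
    """A '1:N' incidence: one case per ``denominator`` newborns screened."""

    cases: int
    total_screened: int
    denominator: int

    @property
    def text(self) -> str:
        return f"1:{self.denominator:,}"

    def __str__(self) -> str:
        return self.text


def incidence(cases: int, total_screened: int) -> Incidence:
    """Incidence of ``cases`` among ``total_screened``, denominator rounded
    half-up to the nearest integer (exact integer arithmetic, no float)."""
    if cases <= 0:
        raise DomainError(f"incidence undefined for cases={cases}")
    if total_screened < cases:
        raise DomainError(
            f"total_screened ({total_screened}) < cases ({cases})"
        )
    denominator = (2 * total_screened + cases) // (2 * cases)
    return Incidence(cases, total_screened, denominator)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    minimum: float
    maximum: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def __str__(self) -> str:
        return f"n={self.n}, median {self.median:g} (min {self.minimum:g}, max {self.maximum:g})"


def _clean(values: Iterable[float | None]) -> np.ndarray:
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    return arr[np.isfinite(arr)]


def group_summary(values: Iterable[float | None]) -> GroupSummary:
    """Median/min/max/quartiles of the non-missing values."""
    arr = _clean(values)
    if arr.size == 0:
        raise EmptyGroupError("no non-missing values in group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return GroupSummary(
        n=int(arr.size),
        median=float(med),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        q1=float(q1),
        q3=float(q3),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum result; ``statistic`` is the rank-sum of
    the first group (mid-ranks for ties)."""

    statistic: float
    p_two_sided: float
    method: str
    n1: int
    n2: int


def _exact_two_sided(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-sided p by full enumeration of the C(n, n1) assignments of
    the pooled mid-ranks to the first group (doubling convention, capped)."""
    n = ranks.size
    total = math.comb(n, n1)
    count_le = 0
    count_ge = 0
    # tolerance guards float equality of mid-rank sums
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            count_le += 1
        if w >= w_obs - eps:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(1.0, p)


def rank_sum_test(
    a: Iterable[float | None], b: Iterable[float | None]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two independent groups.

    Missing values are excluded.  With pooled size ≤ 12 the null
    distribution is enumerated exactly over all rank assignments; otherwise
    a normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    x = _clean(a)
    y = _clean(b)
    if x.size == 0 or y.size == 0:
        raise EmptyGroupError("rank-sum test requires at least one value per group")
    n1, n2 = int(x.size), int(y.size)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())

    if n <= EXACT_ENUMERATION_LIMIT:
        p = _exact_two_sided(ranks, n1, w)
        return RankSumResult(w, p, "exact_enumeration", n1, n2)

    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all values identical: no evidence either way
        return RankSumResult(w, 1.0, "normal_approximation", n1, n2)
    diff = w - mu
    # continuity correction shrinks |diff| by 0.5
    z = (abs(diff) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return RankSumResult(w, p, "normal_approximation", n1, n2)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

#: Composite groupings reported alongside the single labels.
COMPOSITES: dict[str, tuple[DiagnosisLabel, ...]] = {
    "IOPD+LOPD": (DiagnosisLabel.IOPD, DiagnosisLabel.LOPD),
    "IOPD+LOPD+suspected_LOPD": (
        DiagnosisLabel.IOPD,
        DiagnosisLabel.LOPD,
        DiagnosisLabel.SUSPECTED_LOPD,
    ),
}


@dataclass(frozen=True)
class CohortSummary:
    total_screened: int
    counts: dict[DiagnosisLabel, int]
    incidences: dict[str, Incidence] = field(default_factory=dict)
    positive_rate_percent: float = 0.0

    @property
    def total_positive(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "total_screened": self.total_screened,
            "total_positive": self.total_positive,
            "positive_rate_percent": self.positive_rate_percent,
            "counts": {k.value: v for k, v in self.counts.items()},
            "incidences": {k: v.text for k, v in self.incidences.items()},
        }

    def to_markdown(self) -> str:
        rows = ["| Category | n | Incidence |", "| --- | --- | --- |"]
        for label in DiagnosisLabel:
            n = self.counts.get(label, 0)
            inc = self.incidences.get(label.value)
            rows.append(f"| {label.value} | {n} | {inc.text if inc else '—'} |")
        for name in COMPOSITES:
            inc = self.incidences.get(name)
            if inc is not None:
                rows.append(f"| {name} | {inc.cases} | {inc.text} |")
        rows.append(
            f"\nTotal newborns screened: {self.total_screened:,}; "
            f"total positive: {self.total_positive} "
            f"({self.positive_rate_percent:.2f}%)."
        )
        return "\n".join(rows)


def cohort_report(
    labels_or_counts: Iterable[DiagnosisLabel] | Mapping[DiagnosisLabel, int],
    total_screened: int,
) -> CohortSummary:
    """Category counts, 1:N incidences (single labels and composites), and
    the positive rate as a percentage rounded to two decimals."""
    if isinstance(labels_or_counts, Mapping):
        counts = {DiagnosisLabel(k): int(v) for k, v in labels_or_counts.items()}
    else:
        counts = {}
        for label in labels_or_counts:
            label = DiagnosisLabel(label)
            counts[label] = counts.get(label, 0) + 1
    counts = {label: counts.get(label, 0) for label in DiagnosisLabel}
    total_positive = sum(counts.values())
    if total_screened < total_positive:
        raise ConsistencyError(
            f"total_screened ({total_screened}) < total positive ({total_positive})"
        )

    incidences: dict[str, Incidence] = {}
    for label, n in counts.items():
        if n > 0:
            incidences[label.value] = incidence(n, total_screened)
    for name, members in COMPOSITES.items():
        n = sum(counts[m] for m in members)
        if n > 0:
            incidences[name] = incidence(n, total_screened)

    rate = (
        round(100.0 * total_positive / total_screened, 2) if total_screened else 0.0
    )
    return CohortSummary(total_screened, counts, incidences, rate)
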