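"""Threshold Average Precision (TAP-k) retrieval evaluation.

Average precision for a query q with T_q relevant records in the database is

    AP(q, E0) = (1/T_q) * sum over relevant ranks m with score <= E0 of p(m)

where p(m) is the precision at rank m. Irrelevant records retrieved below
the cutoff E0 do not enter AP, so AP alone cannot penalise a tool that pads
the head of its list with false positives. TAP fixes this by adding one
extra precision term measured *at the cutoff* and renormalising:

    TAP(q, E0) = (1/(T_q + 1)) * [ p(E0) + sum over relevant m <= E0 of p(m) ]

with p(E0) the precision at the rank of the last record (relevant or not)
scoring at or below E0, and p(E0) = 0 when nothing scores below E0. TAP is
1.0 exactly when every relevant record and nothing else precedes the
cutoff, and 0.0 when no relevant record does.

The cutoff itself is chosen from the data: for a tolerance parameter k, E0
is the largest score such that the median number of irrelevant records per
query at or below E0 is at most k. One threshold is shared by all queries.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .relevance import RelevanceJudgment

__all__ = [
    "JudgedRecord",
    "RankedRetrieval",
    "TapThreshold",
    "TapResult",
    "ComparisonResult",
    "precision_at",
    "average_precision",
    "select_threshold",
    "tap",
    "evaluate",
    "compare",
    "build_retrievals",
    "DEFAULT_K",
]

DEFAULT_K = (1, 3, 5, 20)


@dataclass(frozen=True)
class JudgedRecord:
    """One judged record in a ranked list: its score and relevancy."""

    score: float
    relevant: bool


@dataclass
class RankedRetrieval:
    """A query's judged records in rank order plus its T_q.

    ``records`` must be sorted ascending by score (rank order for E-values);
    ``t_q`` is the total number of relevant records in the database for the
    query, which is at least the number retrieved.
    """

    query_id: str
    records: list[JudgedRecord]
    t_q: int

    def __post_init__(self) -> None:
        for a, b in zip(self.records, self.records[1:]):
            if a.score > b.score:
                raise ValueError(
                    f"{self.query_id}: records not in rank order "
                    f"({a.score} before {b.score})"
                )
        retrieved_relevant = sum(r.relevant for r in self.records)
        if self.t_q < retrieved_relevant:
            raise ValueError(
                f"{self.query_id}: T_q={self.t_q} smaller than the "
                f"{retrieved_relevant} relevant records retrieved"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scores(self) -> list[float]:
        return [r.score for r in self.records]

    def cutoff_rank(self, e0: float) -> int:
        """Rank of the last record (any relevance) with score <= e0; 0 if none."""
        return bisect_right(self.scores, e0)


@dataclass(frozen=True)
class TapThreshold:
    """The shared cutoff for one value of k."""

    k: int
    e0: float


@dataclass
class TapResult:
    """Per-query TAP scores at one k, with the threshold and summaries."""

    k: int
    e0: float
    scores: dict[str, float]
    ap: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.scores.values())))

    @property
    def query_ids(self) -> list[str]:
        return list(self.scores)


def precision_at(retrieval: RankedRetrieval, m: int) -> float:
    """Precision of the record at rank m: relevant among ranks 1..m over m."""
    if not 1 <= m <= len(retrieval):
        raise ValueError(
            f"rank {m} out of range 1..{len(retrieval)} for {retrieval.query_id}"
        )
    return sum(r.relevant for r in retrieval.records[:m]) / m


def _relevant_precision_sum(retrieval: RankedRetrieval, e0: float, all_ranks: bool) -> float:
    """Sum of p(m) as used by both AP and TAP.

    Standard reading (default): sum precision at the relevant ranks at or
    below the cutoff. Literal all-ranks reading: sum precision at every rank
    from 1 to the last relevant rank at or below the cutoff.
    """
    cutoff = retrieval.cutoff_rank(e0)
    relevant_ranks = [
        m for m, record in enumerate(retrieval.records[:cutoff], start=1) if record.relevant
    ]
    if not relevant_ranks:
        return 0.0
    if all_ranks:
        return sum(precision_at(retrieval, m) for m in range(1, relevant_ranks[-1] + 1))
    return sum(precision_at(retrieval, m) for m in relevant_ranks)


def average_precision(
    retrieval: RankedRetrieval,
    e0: float = math.inf,
    all_ranks: bool = False,
) -> float:
    """Average precision truncated at the score cutoff e0.

    0.0 when no relevant record scores at or below e0.
    """
    if retrieval.t_q < 1:
        raise ValueError(f"{retrieval.query_id}: average precision requires T_q >= 1")
    return _relevant_precision_sum(retrieval, e0, all_ranks) / retrieval.t_q


def _lower_median(values: np.ndarray) -> float:
    """Median taking the lower of the two middle values for even counts."""
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def select_threshold(
    retrievals: Sequence[RankedRetrieval],
    k: int,
) -> TapThreshold:
    """Choose the shared cutoff E0 for a given k.

    E0 is the largest score among all retrieved records such that the median
    over queries of the number of irrelevant records scoring <= E0 is at
    most k.  If even the smallest retrieved score admits too many irrelevant
    records, E0 is placed just below the smallest score (empty cutoff); E0
    is non-decreasing in k.
    """
    if not retrievals:
        raise ValueError("select_threshold requires at least one retrieval")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    all_scores = np.concatenate(
        [np.asarray(r.scores, dtype=float) for r in retrievals]
        or [np.empty(0)]
    )
    if all_scores.size == 0:
        return TapThreshold(k, 0.0)
    candidates = np.unique(all_scores)
    # counts[i, j] = number of irrelevant records of query i scoring <= candidates[j]
    counts = np.vstack(
        [
            np.searchsorted(
                np.sort([r.score for r in retrieval.records if not r.relevant]),
                candidates,
                side="right",
            )
            for retrieval in retrievals
        ]
    )
    medians = np.sort(counts, axis=0)[(len(retrievals) - 1) // 2]
    admissible = np.nonzero(medians <= k)[0]
    if admissible.size == 0:
        return TapThreshold(k, math.nextafter(float(candidates[0]), -math.inf))
    return TapThreshold(k, float(candidates[admissible[-1]]))


def tap(
    retrieval: RankedRetrieval,
    threshold: TapThreshold | float,
    all_ranks: bool = False,
) -> float:
    """TAP score of one retrieval at a given threshold; in [0, 1]."""
    if retrieval.t_q < 1:
        raise ValueError(f"{retrieval.query_id}: TAP requires T_q >= 1")
    e0 = threshold.e0 if isinstance(threshold, TapThreshold) else threshold
    cutoff = retrieval.cutoff_rank(e0)
    p_e0 = precision_at(retrieval, cutoff) if cutoff >= 1 else 0.0
    total = p_e0 + _relevant_precision_sum(retrieval, e0, all_ranks)
    return total / (retrieval.t_q + 1)


def evaluate(
    retrievals: Sequence[RankedRetrieval],
    k_values: Iterable[int] = DEFAULT_K,
    all_ranks: bool = False,
) -> dict[int, TapResult]:
    """TAP-k over a retrieval set: one shared threshold per k, then per-query
    TAP scores and their mean.

    Queries with T_q = 0 cannot be scored and are excluded with a warning
    (they cannot arise from a benchmark built by this toolkit, where every
    DA has >= 2 members and the query is its own relevant record).
    """
    scorable = []
    for retrieval in retrievals:
        if retrieval.t_q == 0:
            warnings.warn(
                f"query {retrieval.query_id} has T_q=0 and is excluded from TAP",
                stacklevel=2,
            )
        else:
            scorable.append(retrieval)
    if not scorable:
        raise ValueError("no scorable retrievals (all have T_q=0)")
    results: dict[int, TapResult] = {}
    for k in k_values:
        threshold = select_threshold(scorable, k)
        results[k] = TapResult(
            k=k,
            e0=threshold.e0,
            scores={r.query_id: tap(r, threshold, all_ranks) for r in scorable},
            ap={r.query_id: average_precision(r, threshold.e0, all_ranks) for r in scorable},
        )
    return results


@dataclass
class ComparisonResult:
    """Tool-vs-tool comparison of per-query score lists.

    ``differences`` (a - b), ``pct_equal``, ``mean_diff`` and ``sd_diff``
    are paired statistics and require equal-length lists; the one-sided
    Wilcoxon-Mann-Whitney rank-sum test treats the two lists as samples and
    asks whether a's scores are stochastically greater (or less) than b's.
    """

    differences: list[float] | None
    pct_equal: float | None
    mean_diff: float | None
    sd_diff: float | None
    statistic: float
    p_value: float
    alternative: str


def compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "greater",
) -> ComparisonResult:
    """Compare two score distributions (e.g. per-query TAP-k of two tools).

    The p-value comes from a one-sided Wilcoxon-Mann-Whitney test with the
    normal approximation, tie correction and continuity correction.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare requires non-empty score lists")
    if a.size == b.size:
        diffs = a - b
        differences = diffs.tolist()
        pct_equal = float(100.0 * np.mean(diffs == 0.0))
        mean_diff = float(np.mean(diffs))
        sd_diff = float(np.std(diffs, ddof=1)) if a.size > 1 else 0.0
    else:
        differences = pct_equal = mean_diff = sd_diff = None
    result = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return ComparisonResult(
        differences=differences,
        pct_equal=pct_equal,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        alternative=alternative,
    )


def build_retrievals(
    judged: Mapping[str, Sequence[RelevanceJudgment]],
    t_q: Mapping[str, int] | Mapping[str, set[str]],
) -> list[RankedRetrieval]:
    """Assemble ranked retrievals from judged hits and per-query T_q.

    ``t_q`` maps query id to either the count of relevant records or the
    relevant id set itself.
    """
    retrievals = []
    for query_id, verdicts in judged.items():
        total = t_q[query_id]
        count = total if isinstance(total, int) else len(total)
        retrievals.append(
            RankedRetrieval(
                query_id=query_id,
                records=[JudgedRecord(v.hit.score, v.relevant) for v in verdicts],
                t_q=count,
            )
        )
    return retrievals
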