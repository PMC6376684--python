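"""Relevancy judgment of retrieved hits.

A retrieved target is relevant to a query iff

1. the target's collapsed domain architecture contains the query's collapsed
   architecture as an ordered subsequence (the tool recovered the query's
   full domain structure), and
2. the alignment reported by the tool covers at least half of the annotated
   domain residues — otherwise the tool merely made a lucky guess and did
   not guide the researcher to the right portion of the protein.

Architecture is checked first; the machine-readable reason records which
test failed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .architectures import (
    DomainAnnotation,
    ProteinRecord,
    architecture_of,
    contains_architecture,
)

__all__ = [
    "ARCHITECTURE_MATCH",
    "ARCHITECTURE_MISMATCH",
    "COVERAGE_FAIL",
    "SearchHit",
    "CoverageConfig",
    "RelevanceJudgment",
    "relevant_set",
    "domain_coverage",
    "judge",
    "judge_hits",
    "write_judgments",
    "read_judgments",
]

ARCHITECTURE_MATCH = "architecture_match"
ARCHITECTURE_MISMATCH = "architecture_mismatch"
COVERAGE_FAIL = "coverage_fail"

Interval = tuple[int, int]


@dataclass(frozen=True)
class SearchHit:
    """One scored query→target match.

    ``score`` is the tool's statistical score (an E-value: lower is better).
    Interval lists are 1-based inclusive aligned spans; when a pair has
    multiple HSPs, ``query_intervals[i]`` and ``target_intervals[i]`` come
    from the same HSP, the score is the best (minimum) E-value, and coverage
    uses the union of all spans.
    """

    query_id: str
    target_id: str
    score: float
    query_intervals: tuple[Interval, ...] = ()
    target_intervals: tuple[Interval, ...] = ()
    bits: float | None = None

    def __post_init__(self) -> None:
        if not (self.score >= 0 and math.isfinite(self.score)):
            raise ValueError(
                f"{self.query_id}->{self.target_id}: score must be a finite "
                f"non-negative E-value, got {self.score}"
            )
        for start, end in (*self.query_intervals, *self.target_intervals):
            if start > end:
                raise ValueError(
                    f"{self.query_id}->{self.target_id}: malformed interval "
                    f"({start}, {end})"
                )
        object.__setattr__(self, "query_intervals", tuple(map(tuple, self.query_intervals)))
        object.__setattr__(self, "target_intervals", tuple(map(tuple, self.target_intervals)))


@dataclass(frozen=True)
class CoverageConfig:
    """Coverage rule: required fraction and which sequence's domains anchor it.

    ``basis`` is ``target`` (default: the retrieved protein is what the
    researcher inspects), ``query``, or ``both`` (both sides must reach the
    threshold). The comparison is inclusive: coverage == threshold passes.
    """

    threshold: float = 0.5
    basis: str = "target"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"coverage threshold must be in [0,1], got {self.threshold}")
        if self.basis not in ("target", "query", "both"):
            raise ValueError(f"coverage basis must be target/query/both, got {self.basis!r}")


@dataclass(frozen=True)
class RelevanceJudgment:
    """Verdict for one hit, with the reason and the measured coverage.

    ``coverage`` is None when the architecture test already failed (coverage
    is then never measured).
    """

    hit: SearchHit
    relevant: bool
    reason: str
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.relevant != (self.reason == ARCHITECTURE_MATCH):
            raise ValueError("relevant must hold exactly when reason is architecture_match")


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of closed integer intervals (adjacent intervals merge)."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def domain_coverage(
    hit: SearchHit,
    annotations: Sequence[DomainAnnotation],
    basis: str = "target",
) -> float:
    """Fraction of annotated-domain residues covered by the hit's alignment.

    The numerator counts residues inside the union of the hit's aligned
    intervals on the basis sequence that also lie inside any annotated
    domain; the denominator is the total number of annotated domain
    residues. Aggregate over all domains, not per-domain.
    """
    if not annotations:
        raise ValueError("coverage is undefined for a sequence with no annotations")
    if basis == "target":
        aligned = _merge_intervals(hit.target_intervals)
    elif basis == "query":
        aligned = _merge_intervals(hit.query_intervals)
    else:
        raise ValueError(f"coverage basis must be 'target' or 'query', got {basis!r}")
    domains = _merge_intervals((a.start, a.end) for a in annotations)
    total = sum(end - start + 1 for start, end in domains)
    covered = 0
    for d_start, d_end in domains:
        for a_start, a_end in aligned:
            lo, hi = max(d_start, a_start), min(d_end, a_end)
            if lo <= hi:
                covered += hi - lo + 1
    return covered / total


def relevant_set(
    query: ProteinRecord,
    targets: Iterable[ProteinRecord],
    policy: str = "subsequence",
) -> set[str]:
    """All target ids whose collapsed DA contains the query's collapsed DA.

    The size of this set is the query's T_q. The query itself belongs to the
    target database and is therefore included (containment is reflexive).
    """
    if query.n_domains == 0:
        raise ValueError(f"query {query.id} has no domain annotations")
    query_da = architecture_of(query)
    ids: set[str] = set()
    for target in targets:
        if target.n_domains == 0:
            continue
        if contains_architecture(query_da, architecture_of(target), policy=policy):
            ids.add(target.id)
    return ids


def judge(
    hit: SearchHit,
    query: ProteinRecord,
    target: ProteinRecord,
    config: CoverageConfig = CoverageConfig(),
    policy: str = "subsequence",
) -> RelevanceJudgment:
    """Judge one hit: architecture containment first, then domain coverage."""
    query_da = architecture_of(query)
    target_da = architecture_of(target)
    if not contains_architecture(query_da, target_da, policy=policy):
        return RelevanceJudgment(hit, False, ARCHITECTURE_MISMATCH, None)
    if config.basis == "both":
        coverage = min(
            domain_coverage(hit, target.annotations, "target"),
            domain_coverage(hit, query.annotations, "query"),
        )
    else:
        basis_record = target if config.basis == "target" else query
        coverage = domain_coverage(hit, basis_record.annotations, config.basis)
    if coverage >= config.threshold:
        return RelevanceJudgment(hit, True, ARCHITECTURE_MATCH, coverage)
    return RelevanceJudgment(hit, False, COVERAGE_FAIL, coverage)


def judge_hits(
    hits_by_query: Mapping[str, Sequence[SearchHit]],
    queries_by_id: Mapping[str, ProteinRecord],
    targets_by_id: Mapping[str, ProteinRecord],
    config: CoverageConfig = CoverageConfig(),
    policy: str = "subsequence",
) -> dict[str, list[RelevanceJudgment]]:
    """Judge every hit of every query, preserving rank order.

    Targets missing from the annotation tables (or carrying no annotations)
    cannot contain the query's architecture and are judged irrelevant with
    reason ``architecture_mismatch``.
    """
    judged: dict[str, list[RelevanceJudgment]] = {}
    for query_id, hits in hits_by_query.items():
        query = queries_by_id.get(query_id)
        if query is None:
            raise KeyError(f"hits reference unknown query {query_id!r}")
        verdicts: list[RelevanceJudgment] = []
        for hit in hits:
            target = targets_by_id.get(hit.target_id)
            if target is None or target.n_domains == 0:
                verdicts.append(RelevanceJudgment(hit, False, ARCHITECTURE_MISMATCH, None))
            else:
                verdicts.append(judge(hit, query, target, config, policy))
        judged[query_id] = verdicts
    return judged


# ---------------------------------------------------------------------------
# judged-hits flat format: query_id  target_id  score  relevant  reason  coverage


def write_judgments(
    judged: Mapping[str, Sequence[RelevanceJudgment]],
    path: str | Path,
) -> None:
    from .benchmark_builder import atomic_write

    with atomic_write(Path(path)) as handle:
        handle.write("# query_id\ttarget_id\tscore\trelevant\treason\tcoverage\n")
        for query_id, verdicts in judged.items():
            for verdict in verdicts:
                hit = verdict.hit
                coverage = "NA" if verdict.coverage is None else repr(verdict.coverage)
                handle.write(
                    f"{query_id}\t{hit.target_id}\t{hit.score!r}\t"
                    f"{int(verdict.relevant)}\t{verdict.reason}\t{coverage}\n"
                )


def read_judgments(path: str | Path) -> dict[str, list[RelevanceJudgment]]:
    """Read a judged-hits file. Hits carry no intervals after the round trip
    (coverage has already been measured)."""
    path = Path(path)
    judged: dict[str, list[RelevanceJudgment]] = {}
    with open(path) as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(row)}"
                )
            query_id, target_id, score, relevant, reason, coverage = row
            hit = SearchHit(query_id, target_id, float(score))
            judged.setdefault(query_id, []).append(
                RelevanceJudgment(
                    hit,
                    bool(int(relevant)),
                    reason,
                    None if coverage == "NA" else float(coverage),
                )
            )
    return judged
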