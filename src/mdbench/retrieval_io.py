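"""Parsers for search-tool output and ranked hit tables.

Supported inputs are the BLAST tabular formats (``-outfmt 6`` and the
commented ``-outfmt 7``) and HMMER's per-domain table (``--domtblout``).
Rows belonging to the same query–target pair (multiple HSPs / multiple
domain hits) are merged into a single :class:`~mdbench.relevance.SearchHit`
whose score is the best (minimum) E-value and whose interval lists keep
every reported span, so the coverage criterion sees the union of the
alignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .relevance import SearchHit

__all__ = [
    "ParseError",
    "HitTable",
    "parse_blast_tabular",
    "parse_hmmer_domtbl",
    "write_blast_tabular",
    "rank",
]


class ParseError(ValueError):
    """Malformed search-tool output; the message names the line."""


class HitTable:
    """Per-query ranked lists of hits, ascending by score with stable ties."""

    def __init__(self, hits_by_query: Mapping[str, Sequence[SearchHit]]) -> None:
        self._hits = {q: list(hits) for q, hits in hits_by_query.items()}
        for query_id, hits in self._hits.items():
            for a, b in zip(hits, hits[1:]):
                if a.score > b.score:
                    raise ValueError(
                        f"hits for {query_id} are not sorted by score; use rank()"
                    )

    @property
    def query_ids(self) -> list[str]:
        return list(self._hits)

    def __getitem__(self, query_id: str) -> list[SearchHit]:
        return self._hits[query_id]

    def __contains__(self, query_id: str) -> bool:
        return query_id in self._hits

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self) -> Iterator[str]:
        return iter(self._hits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        return self._hits == other._hits

    @property
    def n_hits(self) -> int:
        return sum(len(hits) for hits in self._hits.values())

    def items(self):
        return self._hits.items()


class _PairAccumulator:
    """Merges rows for one query-target pair in first-appearance order."""

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], dict] = {}

    def add(
        self,
        query_id: str,
        target_id: str,
        score: float,
        query_interval: tuple[int, int],
        target_interval: tuple[int, int],
        bits: float,
    ) -> None:
        key = (query_id, target_id)
        entry = self._pairs.get(key)
        if entry is None:
            self._pairs[key] = {
                "score": score,
                "bits": bits,
                "q": [query_interval],
                "t": [target_interval],
            }
        else:
            entry["score"] = min(entry["score"], score)
            entry["bits"] = max(entry["bits"], bits)
            entry["q"].append(query_interval)
            entry["t"].append(target_interval)

    def table(self, tie_policy: str = "input") -> HitTable:
        grouped: dict[str, list[SearchHit]] = {}
        for (query_id, target_id), entry in self._pairs.items():
            grouped.setdefault(query_id, []).append(
                SearchHit(
                    query_id=query_id,
                    target_id=target_id,
                    score=entry["score"],
                    query_intervals=tuple(entry["q"]),
                    target_intervals=tuple(entry["t"]),
                    bits=entry["bits"],
                )
            )
        return rank(grouped, tie_policy)


def _lines(source: str | Path | IO[str]) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from enumerate(handle, start=1)
    else:
        yield from enumerate(source, start=1)


def _source_name(source) -> str:
    if isinstance(source, (str, Path)):
        return str(source)
    return getattr(source, "name", "<stream>")


def parse_blast_tabular(
    source: str | Path | IO[str],
    dialect: str = "outfmt6",
    tie_policy: str = "input",
) -> HitTable:
    """Parse BLAST tabular output (12 standard columns).

    ``outfmt7`` differs from ``outfmt6`` only by interspersed ``#`` comment
    lines; the same rows through either dialect give an identical table.
    Subject coordinates are normalised to (min, max).
    """
    if dialect not in ("outfmt6", "outfmt7"):
        raise ValueError(f"unknown BLAST dialect {dialect!r}")
    name = _source_name(source)
    acc = _PairAccumulator()
    for lineno, line in _lines(source):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if dialect == "outfmt7":
                continue
            raise ParseError(f"{name}: line {lineno}: unexpected comment in outfmt6")
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"{name}: line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            bits = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"{name}: line {lineno}: {exc}") from exc
        acc.add(
            fields[0],
            fields[1],
            evalue,
            (min(qstart, qend), max(qstart, qend)),
            (min(sstart, send), max(sstart, send)),
            bits,
        )
    return acc.table(tie_policy)


def parse_hmmer_domtbl(
    source: str | Path | IO[str],
    tie_policy: str = "input",
) -> HitTable:
    """Parse HMMER ``--domtblout`` output.

    In an hmmsearch against the target database the profile is built from
    the benchmark query, so the domtblout "query" column is the benchmark
    query and the "target" column is the retrieved sequence.  Per row, the
    hmm coordinates become query intervals and the ali coordinates become
    target intervals; the full-sequence E-value is the pair's score and rows
    for one pair are merged.
    """
    name = _source_name(source)
    acc = _PairAccumulator()
    for lineno, line in _lines(source):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 23:
            raise ParseError(
                f"{name}: line {lineno}: truncated domtblout row "
                f"({len(fields)} columns, expected >= 23)"
            )
        try:
            evalue = float(fields[6])
            bits = float(fields[7])
            hmm_from, hmm_to = int(fields[15]), int(fields[16])
            ali_from, ali_to = int(fields[17]), int(fields[18])
        except ValueError as exc:
            raise ParseError(f"{name}: line {lineno}: {exc}") from exc
        acc.add(
            fields[3],  # query (profile) name
            fields[0],  # target sequence name
            evalue,
            (hmm_from, hmm_to),
            (ali_from, ali_to),
            bits,
        )
    return acc.table(tie_policy)


def write_blast_tabular(table: HitTable, destination: str | Path | IO[str]) -> None:
    """Write a hit table as BLAST ``-outfmt 6`` rows, one row per HSP.

    Alignment-statistics columns that the table does not model (pident,
    mismatch, gapopen) are written as neutral placeholders; scores are
    written with full float precision so parse→write→parse is the identity.
    """

    def _write(handle: IO[str]) -> None:
        for query_id in table.query_ids:
            for hit in table[query_id]:
                bits = 0.0 if hit.bits is None else hit.bits
                for (qs, qe), (ts, te) in zip(hit.query_intervals, hit.target_intervals):
                    handle.write(
                        f"{hit.query_id}\t{hit.target_id}\t100.0\t{qe - qs + 1}\t0\t0\t"
                        f"{qs}\t{qe}\t{ts}\t{te}\t{hit.score!r}\t{bits!r}\n"
                    )

    if isinstance(destination, (str, Path)):
        from .benchmark_builder import atomic_write

        with atomic_write(Path(destination)) as handle:
            _write(handle)
    else:
        _write(destination)


def rank(
    hits_by_query: Mapping[str, Iterable[SearchHit]] | HitTable,
    tie_policy: str = "input",
) -> HitTable:
    """Stable ascending sort by score within each query; idempotent.

    ``tie_policy`` "input" keeps the tools' own order for equal E-values
    (tools emit best-first); "bits" breaks E-value ties by descending bit
    score before falling back to input order.
    """
    if tie_policy not in ("input", "bits"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    items = hits_by_query.items() if not isinstance(hits_by_query, HitTable) else hits_by_query.items()
    ranked: dict[str, list[SearchHit]] = {}
    for query_id, hits in items:
        hits = list(hits)
        if tie_policy == "bits":
            key = lambda h: (h.score, -(h.bits if h.bits is not None else 0.0))
        else:
            key = lambda h: h.score
        ranked[query_id] = sorted(hits, key=key)
    return HitTable(ranked)
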