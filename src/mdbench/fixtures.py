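"""Seeded synthetic worlds: proteins with controllable domain architectures
and mock ranked retrievals with controllable score separation.

The generator emulates the inputs a multi-domain retrieval benchmark is
curated from — Pfam-style domain annotations over a phylogenetically broad
protein set — and the output a search tool would produce against it.  It
makes no attempt at biologically realistic residue content: sequences are
random amino-acid strings, since every operation in the toolkit depends
only on annotations, lengths and scores.

Retrieval realism is ordinal: E-values are log-uniform and the separation
between relevant and irrelevant hits is a configurable offset in log10
units ("signal"), which is all a rank-based metric can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .architectures import KINGDOMS, ProteinRecord, DomainAnnotation
from .benchmark_builder import (
    BenchmarkBundle,
    BuilderConfig,
    build_benchmark,
    write_benchmark,
)
from .relevance import SearchHit
from .retrieval_io import HitTable, rank, write_blast_tabular

__all__ = [
    "FixtureSpec",
    "generate_proteins",
    "generate_benchmark",
    "generate_retrievals",
    "simulate",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults describe a small but structurally faithful benchmark: each
    architecture has 2-5 distinct domains of 40-200 residues separated by
    short linkers, 2-6 member sequences spanning at least two kingdoms, and
    a quarter of domain instances appear as adjacent repeats so collapsing
    is always exercised.  ``retrieval_signal`` is the mean log10 E-value
    advantage of relevant over irrelevant hits (0 = indistinguishable).
    """

    n_architectures: int = 20
    domain_alphabet_size: int = 12
    architecture_length_range: tuple[int, int] = (2, 5)
    members_per_da_range: tuple[int, int] = (2, 6)
    domain_length_range: tuple[int, int] = (40, 200)
    linker_length_range: tuple[int, int] = (5, 60)
    kingdom_weights: dict[str, float] = field(
        default_factory=lambda: {"Eukarya": 0.45, "Bacteria": 0.45, "Archaea": 0.10}
    )
    adjacent_repeat_prob: float = 0.25
    retrieval_signal: float = 4.0
    irrelevant_per_query_range: tuple[int, int] = (4, 12)
    alignment_coverage: float = 0.9
    irrelevant_log10e_range: tuple[float, float] = (-5.0, 2.0)
    seed: int = 0
    forced_architectures: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "architecture_length_range",
            "members_per_da_range",
            "domain_length_range",
            "linker_length_range",
            "irrelevant_per_query_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-empty range, got ({lo}, {hi})")
        if self.architecture_length_range[0] < 2:
            raise ValueError("architectures must have at least 2 domains")
        if not np.isclose(sum(self.kingdom_weights.values()), 1.0):
            raise ValueError("kingdom weights must sum to 1")
        if not set(self.kingdom_weights) <= set(KINGDOMS):
            raise ValueError(f"kingdom weights must be over {KINGDOMS}")


def _n_collapsed_vectors(alphabet: int, length: int) -> int:
    """Number of distinct collapsed vectors of a given length."""
    return alphabet * (alphabet - 1) ** (length - 1)


def _sample_architectures(
    spec: FixtureSpec, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    lo, hi = spec.architecture_length_range
    capacity = sum(
        _n_collapsed_vectors(spec.domain_alphabet_size, n) for n in range(lo, hi + 1)
    )
    if capacity < spec.n_architectures:
        raise ValueError(
            f"alphabet of {spec.domain_alphabet_size} supports only {capacity} "
            f"distinct architectures of length {lo}-{hi}; "
            f"{spec.n_architectures} requested"
        )
    alphabet = [f"PF{i:05d}" for i in range(1, spec.domain_alphabet_size + 1)]
    chosen: list[tuple[str, ...]] = list(spec.forced_architectures)
    seen = set(chosen)
    while len(chosen) < spec.n_architectures:
        length = int(rng.integers(lo, hi + 1))
        arch = [alphabet[int(rng.integers(len(alphabet)))]]
        while len(arch) < length:
            nxt = alphabet[int(rng.integers(len(alphabet)))]
            if nxt != arch[-1]:
                arch.append(nxt)
        key = tuple(arch)
        if key not in seen:
            seen.add(key)
            chosen.append(key)
    return chosen[: max(spec.n_architectures, len(spec.forced_architectures))]


def _instantiate_member(
    seq_id: str,
    architecture: Sequence[str],
    spec: FixtureSpec,
    rng: np.random.Generator,
    allow_repeats: bool,
) -> ProteinRecord:
    # expand the collapsed architecture into a concrete annotation run,
    # optionally duplicating domains adjacently (collapses back to the DA)
    labels: list[str] = []
    for domain in architecture:
        copies = 1
        if allow_repeats and rng.random() < spec.adjacent_repeat_prob:
            copies = int(rng.integers(2, 4))
        labels.extend([domain] * copies)
    annotations: list[DomainAnnotation] = []
    pos = 1 + int(rng.integers(*_inclusive(spec.linker_length_range)))
    for label in labels:
        length = int(rng.integers(*_inclusive(spec.domain_length_range)))
        annotations.append(DomainAnnotation(seq_id, label, pos, pos + length - 1))
        pos += length + int(rng.integers(*_inclusive(spec.linker_length_range)))
    total = annotations[-1].end + int(rng.integers(*_inclusive(spec.linker_length_range)))
    residues = "".join(rng.choice(AMINO_ACIDS, size=total))
    return ProteinRecord(id=seq_id, residues=residues, annotations=annotations)


def _inclusive(bounds: tuple[int, int]) -> tuple[int, int]:
    return bounds[0], bounds[1] + 1


def generate_proteins(spec: FixtureSpec) -> list[ProteinRecord]:
    """Generate the annotated protein set of a synthetic world.

    Architectures are drawn without replacement; each gets 2+ member
    sequences.  The first member of each architecture carries no adjacent
    repeats (bounding its length well under the query-length cap) and the
    first two members are guaranteed to come from different kingdoms, so
    under default builder settings every generated architecture survives the
    cascade and yields a query.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    architectures = _sample_architectures(spec, rng)
    kingdoms = list(spec.kingdom_weights)
    weights = np.array([spec.kingdom_weights[k] for k in kingdoms])
    proteins: list[ProteinRecord] = []
    counter = 1
    for arch in architectures:
        n_members = int(rng.integers(*_inclusive(spec.members_per_da_range)))
        member_kingdoms = [
            kingdoms[int(i)] for i in rng.choice(len(kingdoms), size=n_members, p=weights)
        ]
        if len(set(member_kingdoms[:2])) < 2:
            others = [k for k in kingdoms if k != member_kingdoms[0]]
            member_kingdoms[1] = others[int(rng.integers(len(others)))]
        for j in range(n_members):
            record = _instantiate_member(
                f"SYN{counter:05d}", arch, spec, rng, allow_repeats=(j > 0)
            )
            record.kingdom = member_kingdoms[j]
            proteins.append(record)
            counter += 1
    return proteins


def generate_benchmark(
    spec: FixtureSpec, config: BuilderConfig | None = None
) -> BenchmarkBundle:
    """Generate proteins and run the full builder cascade on them."""
    proteins = generate_proteins(spec)
    config = config or BuilderConfig(rng_seed=spec.seed)
    return build_benchmark(proteins, config=config)


def _aligned_intervals(
    annotations: Sequence[DomainAnnotation], fraction: float
) -> tuple[tuple[int, int], ...]:
    """Spans covering ~``fraction`` of each annotated domain, from its start."""
    intervals = []
    for ann in annotations:
        covered = max(0, round(fraction * ann.length))
        if covered:
            intervals.append((ann.start, ann.start + covered - 1))
    return tuple(intervals)


def generate_retrievals(
    bundle: BenchmarkBundle,
    spec: FixtureSpec,
    signal: float | None = None,
    seed: int | None = None,
    coverage: float | None = None,
) -> HitTable:
    """Mock a search tool's ranked output over a benchmark.

    Every relevant target of every query is retrieved with a log10 E-value
    drawn ``signal`` units below the irrelevant background; a random handful
    of irrelevant targets per query fills out the list.  Relevant hits carry
    alignments covering ``coverage`` of the annotated domain residues on
    both sequences, so the coverage criterion can be exercised in either
    direction; irrelevant hits get arbitrary spans.
    """
    signal = spec.retrieval_signal if signal is None else signal
    coverage = spec.alignment_coverage if coverage is None else coverage
    rng = np.random.default_rng([spec.seed if seed is None else seed, 1])
    targets_by_id = bundle.targets_by_id
    all_ids = [p.id for p in bundle.targets]
    lo, hi = spec.irrelevant_log10e_range
    hits_by_query: dict[str, list[SearchHit]] = {}
    for record, _arch in bundle.queries:
        relevant_ids = sorted(bundle.relevant[record.id])
        irrelevant_pool = [t for t in all_ids if t not in bundle.relevant[record.id]]
        n_irrelevant = min(
            len(irrelevant_pool),
            int(rng.integers(*_inclusive(spec.irrelevant_per_query_range))),
        )
        picked = (
            [irrelevant_pool[int(i)] for i in rng.choice(len(irrelevant_pool), size=n_irrelevant, replace=False)]
            if n_irrelevant
            else []
        )
        hits: list[SearchHit] = []
        for target_id in relevant_ids:
            target = targets_by_id[target_id]
            log10e = rng.uniform(lo, hi) - signal
            hits.append(
                SearchHit(
                    query_id=record.id,
                    target_id=target_id,
                    score=10.0 ** log10e,
                    query_intervals=_aligned_intervals(record.annotations, coverage),
                    target_intervals=_aligned_intervals(target.annotations, coverage),
                    bits=0.0,
                )
            )
        for target_id in picked:
            target = targets_by_id[target_id]
            log10e = rng.uniform(lo, hi)
            span_end = max(1, len(target) // 2)
            hits.append(
                SearchHit(
                    query_id=record.id,
                    target_id=target_id,
                    score=10.0 ** log10e,
                    query_intervals=((1, max(1, len(record) // 2)),),
                    target_intervals=((1, span_end),),
                    bits=0.0,
                )
            )
        hits_by_query[record.id] = hits
    return rank(hits_by_query)


def simulate(
    spec: FixtureSpec,
    directory: str | Path,
    signal_a: float | None = None,
    signal_b: float = 1.0,
    config: BuilderConfig | None = None,
) -> BenchmarkBundle:
    """Emit a complete benchmark directory plus two mock tool hit files.

    ``tool_a.tsv`` uses the spec's full retrieval signal (or ``signal_a``),
    ``tool_b.tsv`` a weaker one, so the evaluation and comparison pipeline
    can run end to end on purely synthetic data.
    """
    directory = Path(directory)
    bundle = generate_benchmark(spec, config)
    write_benchmark(bundle, directory)
    table_a = generate_retrievals(bundle, spec, signal=signal_a, seed=spec.seed + 1)
    table_b = generate_retrievals(bundle, spec, signal=signal_b, seed=spec.seed + 2)
    write_blast_tabular(table_a, directory / "tool_a.tsv")
    write_blast_tabular(table_b, directory / "tool_b.tsv")
    return bundle
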