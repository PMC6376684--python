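"""Benchmark construction: the filter cascade from an annotated protein set
to a retrieval benchmark.

The cascade mirrors how a multi-domain retrieval benchmark is curated from a
Pfam-style annotated collection:

1. drop sequences with overlapping domain annotations (each residue must
   belong to at most one domain);
2. form the target database from everything that remains, single- and
   multi-domain alike;
3. partition out the multi-domain sequences and catalog their collapsed
   domain architectures (DAs);
4. keep only DAs with at least ``min_members`` member sequences and at least
   one member short enough to serve as a query (``max_query_length``);
5. optionally keep only DAs spanning more than one kingdom of life;
6. pick one random eligible query per surviving DA, order queries by DA
   index, and alternate them into Training (odd ranks) and Test (even ranks).

Every stage conserves items (kept + removed = input) and appends an audit
record, so the cascade is fully accountable.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architectures import (
    KINGDOMS,
    ArchitectureCatalog,
    CatalogEntry,
    DomainAnnotation,
    DomainArchitecture,
    ProteinRecord,
    architecture_of,
    build_catalog,
    contains_architecture,
    has_overlapping_annotations,
)

__all__ = [
    "BuilderConfig",
    "AuditRecord",
    "BenchmarkBundle",
    "PartitionResult",
    "detect_overlaps",
    "filter_overlapping",
    "partition_by_domain_count",
    "filter_architectures",
    "filter_multikingdom",
    "select_queries",
    "split_train_test",
    "build_benchmark",
    "write_benchmark",
    "read_benchmark",
    "read_fasta",
    "read_domains_tsv",
    "read_kingdoms_tsv",
    "assemble_proteins",
]

TRAINING = "Training"
TEST = "Test"


@dataclass
class BuilderConfig:
    """Tunable parameters of the filter cascade.

    ``max_query_length`` caps query size (residues) to keep search times
    reasonable; ``min_members`` requires each DA to have enough members for
    retrieval analysis to be meaningful; ``require_multikingdom`` enforces
    phylogenetic breadth; ``count_collapsed`` controls whether multi-domain
    status is decided before (False, default) or after collapsing adjacent
    repeats; ``containment_policy`` is forwarded to architecture containment.
    """

    max_query_length: int = 1800
    min_members: int = 2
    require_multikingdom: bool = True
    rng_seed: int = 0
    count_collapsed: bool = False
    containment_policy: str = "subsequence"

    def __post_init__(self) -> None:
        if self.max_query_length <= 0:
            raise ValueError("max_query_length must be positive")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")


class AuditRecord(NamedTuple):
    stage: str
    kept: int
    removed: int


class PartitionResult(NamedTuple):
    single_domain: list[ProteinRecord]
    multi_domain: list[ProteinRecord]
    unannotated: list[ProteinRecord]


@dataclass
class BenchmarkBundle:
    """A complete benchmark: targets, queries, split, catalog, relevancy.

    ``targets`` include the queries; ``queries`` are ordered by DA index;
    ``relevant`` maps each query id to the full set of relevant target ids
    (the query itself included), whose size is the query's T_q.
    """

    targets: list[ProteinRecord]
    queries: list[tuple[ProteinRecord, DomainArchitecture]]
    split: dict[str, str]
    catalog: ArchitectureCatalog
    relevant: dict[str, set[str]]
    audit: list[AuditRecord] = field(default_factory=list)

    @property
    def query_ids(self) -> list[str]:
        return [record.id for record, _ in self.queries]

    @property
    def targets_by_id(self) -> dict[str, ProteinRecord]:
        return {record.id: record for record in self.targets}

    def t_q(self, query_id: str) -> int:
        return len(self.relevant[query_id])

    def __eq__(self, other: object) -> bool:
        # audit is provenance, not content: bundles are equal when the
        # benchmark itself (targets, queries, split, catalog, relevancy) is.
        if not isinstance(other, BenchmarkBundle):
            return NotImplemented
        return (
            self.targets == other.targets
            and self.queries == other.queries
            and self.split == other.split
            and self.catalog == other.catalog
            and self.relevant == other.relevant
        )


# ---------------------------------------------------------------------------
# filter cascade


def detect_overlaps(protein: ProteinRecord) -> bool:
    """True iff some residue of the protein carries >= 2 domain annotations."""
    return has_overlapping_annotations(protein)


def filter_overlapping(
    proteins: Iterable[ProteinRecord],
    audit: list[AuditRecord] | None = None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split proteins into (kept, removed) by overlapping-annotation status."""
    kept: list[ProteinRecord] = []
    removed: list[ProteinRecord] = []
    for protein in proteins:
        (removed if detect_overlaps(protein) else kept).append(protein)
    if audit is not None:
        audit.append(AuditRecord("overlap_filter", len(kept), len(removed)))
    return kept, removed


def partition_by_domain_count(
    proteins: Iterable[ProteinRecord],
    count_collapsed: bool = False,
    audit: list[AuditRecord] | None = None,
) -> PartitionResult:
    """Partition proteins into single-domain, multi-domain and unannotated.

    By default multi-domain means >= 2 raw annotations; with
    ``count_collapsed`` a protein annotated A,A counts as single-domain.
    """
    single: list[ProteinRecord] = []
    multi: list[ProteinRecord] = []
    unannotated: list[ProteinRecord] = []
    for protein in proteins:
        if protein.n_domains == 0:
            unannotated.append(protein)
            continue
        count = (
            len(architecture_of(protein)) if count_collapsed else protein.n_domains
        )
        (multi if count >= 2 else single).append(protein)
    if audit is not None:
        audit.append(
            AuditRecord(
                "multi_domain_partition", len(multi), len(single) + len(unannotated)
            )
        )
    return PartitionResult(single, multi, unannotated)


def filter_architectures(
    catalog: ArchitectureCatalog,
    lengths: Mapping[str, int],
    config: BuilderConfig,
    audit: list[AuditRecord] | None = None,
) -> ArchitectureCatalog:
    """Keep DAs with >= min_members members and >= 1 query-length member.

    Original catalog indices are preserved, so DA labels are stable across
    filtering.
    """
    kept: list[CatalogEntry] = []
    removed = 0
    for entry in catalog:
        enough_members = len(entry.member_ids) >= config.min_members
        has_short = any(
            lengths[m] <= config.max_query_length for m in entry.member_ids
        )
        if enough_members and has_short:
            kept.append(entry)
        else:
            removed += 1
    if audit is not None:
        audit.append(AuditRecord("architecture_filter", len(kept), removed))
    return ArchitectureCatalog(kept)


def filter_multikingdom(
    catalog: ArchitectureCatalog,
    kingdom_map: Mapping[str, str],
    audit: list[AuditRecord] | None = None,
) -> ArchitectureCatalog:
    """Keep DAs whose members span >= 2 distinct kingdoms of life.

    Members without a kingdom label are ignored for the kingdom count (and
    reported through a dedicated audit line).
    """
    if not kingdom_map:
        raise ValueError("multikingdom filter requires a non-empty kingdom map")
    kept: list[CatalogEntry] = []
    removed = 0
    unlabeled = 0
    for entry in catalog:
        kingdoms = set()
        for member in entry.member_ids:
            kingdom = kingdom_map.get(member)
            if kingdom is None:
                unlabeled += 1
            else:
                kingdoms.add(kingdom)
        if len(kingdoms) >= 2:
            kept.append(entry)
        else:
            removed += 1
    if audit is not None:
        audit.append(AuditRecord("multikingdom_filter", len(kept), removed))
        if unlabeled:
            audit.append(AuditRecord("multikingdom_unlabeled_members", 0, unlabeled))
    return ArchitectureCatalog(kept)


def select_queries(
    catalog: ArchitectureCatalog,
    proteins_by_id: Mapping[str, ProteinRecord],
    config: BuilderConfig,
) -> list[tuple[ProteinRecord, DomainArchitecture]]:
    """Choose one representative query per DA, uniformly among members with
    length <= max_query_length; output ordered by ascending DA index.

    Each DA draws from its own generator seeded with (rng_seed, DA index),
    so adding or removing a DA never perturbs the choice made for another.
    """
    queries: list[tuple[ProteinRecord, DomainArchitecture]] = []
    entries = sorted(catalog, key=lambda e: e.architecture.index)
    for entry in entries:
        eligible = [
            m
            for m in entry.member_ids
            if len(proteins_by_id[m]) <= config.max_query_length
        ]
        if not eligible:
            raise ValueError(
                f"DA {entry.architecture.label} has no member of length "
                f"<= {config.max_query_length}; run filter_architectures first"
            )
        rng = np.random.default_rng([config.rng_seed, entry.architecture.index])
        chosen = eligible[int(rng.integers(len(eligible)))]
        queries.append((proteins_by_id[chosen], entry.architecture))
    return queries


def split_train_test(
    queries: Sequence[tuple[ProteinRecord, DomainArchitecture]],
) -> dict[str, str]:
    """Alternate queries (ordered by DA index) into Training/Test.

    1-based rank: odd ranks go to Training, even ranks to Test, so the two
    halves differ in size by at most one.
    """
    return {
        record.id: (TRAINING if rank % 2 == 1 else TEST)
        for rank, (record, _) in enumerate(queries, start=1)
    }


def _relevant_sets(
    queries: Sequence[tuple[ProteinRecord, DomainArchitecture]],
    targets: Sequence[ProteinRecord],
    policy: str,
) -> dict[str, set[str]]:
    """Full relevant set per query over the whole target database."""
    by_arch: dict[tuple[str, ...], list[str]] = {}
    for target in targets:
        if target.n_domains == 0:
            continue
        key = architecture_of(target).domains
        by_arch.setdefault(key, []).append(target.id)
    relevant: dict[str, set[str]] = {}
    for record, arch in queries:
        ids: set[str] = set()
        for key, members in by_arch.items():
            if contains_architecture(arch.domains, key, policy=policy):
                ids.update(members)
        relevant[record.id] = ids
    return relevant


def build_benchmark(
    proteins: Sequence[ProteinRecord],
    kingdom_map: Mapping[str, str] | None = None,
    config: BuilderConfig | None = None,
) -> BenchmarkBundle:
    """Run the full cascade and assemble a benchmark bundle.

    ``kingdom_map`` may be omitted when the records carry kingdom labels
    themselves; it is required when ``require_multikingdom`` is set and no
    labels are available.
    """
    config = config or BuilderConfig()
    if kingdom_map is None:
        kingdom_map = {p.id: p.kingdom for p in proteins if p.kingdom is not None}

    audit: list[AuditRecord] = []
    targets, _removed = filter_overlapping(proteins, audit)
    partition = partition_by_domain_count(targets, config.count_collapsed, audit)

    catalog = build_catalog(partition.multi_domain)
    audit.append(AuditRecord("distinct_architectures", len(catalog), 0))
    lengths = {p.id: len(p) for p in partition.multi_domain}
    catalog = filter_architectures(catalog, lengths, config, audit)
    if config.require_multikingdom:
        catalog = filter_multikingdom(catalog, kingdom_map, audit)

    proteins_by_id = {p.id: p for p in targets}
    queries = select_queries(catalog, proteins_by_id, config)
    audit.append(AuditRecord("queries_selected", len(queries), 0))
    split = split_train_test(queries)
    relevant = _relevant_sets(queries, targets, config.containment_policy)

    for record in targets:
        if record.kingdom is None and record.id in kingdom_map:
            record.kingdom = kingdom_map[record.id]

    return BenchmarkBundle(
        targets=list(targets),
        queries=queries,
        split=split,
        catalog=catalog,
        relevant=relevant,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# flat-file benchmark format
#
# targets.fasta   all target sequences (queries included)
# domains.tsv     seq_id  domain_id  start  end      (1-based inclusive)
# kingdoms.tsv    seq_id  kingdom
# catalog.tsv     index  label  domains(comma)  members(comma)
# queries.tsv     query_id  da_label  split
# relevant.tsv    query_id  target_id
# audit.tsv       stage  kept  removed


@contextmanager
def atomic_write(path: Path) -> Iterator:
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_benchmark(bundle: BenchmarkBundle, directory: str | Path) -> None:
    """Serialise a bundle to flat text files under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with atomic_write(directory / "targets.fasta") as handle:
        SeqIO.write(
            (
                SeqRecord(Seq(p.residues), id=p.id, description="")
                for p in bundle.targets
            ),
            handle,
            "fasta",
        )
    with atomic_write(directory / "domains.tsv") as handle:
        handle.write("# seq_id\tdomain_id\tstart\tend\n")
        for protein in bundle.targets:
            for ann in protein.annotations:
                handle.write(
                    f"{ann.sequence_id}\t{ann.domain_id}\t{ann.start}\t{ann.end}\n"
                )
    with atomic_write(directory / "kingdoms.tsv") as handle:
        handle.write("# seq_id\tkingdom\n")
        for protein in bundle.targets:
            if protein.kingdom is not None:
                handle.write(f"{protein.id}\t{protein.kingdom}\n")
    with atomic_write(directory / "catalog.tsv") as handle:
        handle.write("# index\tlabel\tdomains\tmembers\n")
        for entry in bundle.catalog:
            arch = entry.architecture
            handle.write(
                f"{arch.index}\t{arch.label}\t{','.join(arch.domains)}\t"
                f"{','.join(entry.member_ids)}\n"
            )
    with atomic_write(directory / "queries.tsv") as handle:
        handle.write("# query_id\tda_label\tsplit\n")
        for record, arch in bundle.queries:
            handle.write(f"{record.id}\t{arch.label}\t{bundle.split[record.id]}\n")
    with atomic_write(directory / "relevant.tsv") as handle:
        handle.write("# query_id\ttarget_id\n")
        for record, _ in bundle.queries:
            for target_id in sorted(bundle.relevant[record.id]):
                handle.write(f"{record.id}\t{target_id}\n")
    with atomic_write(directory / "audit.tsv") as handle:
        handle.write("# stage\tkept\tremoved\n")
        for record in bundle.audit:
            handle.write(f"{record.stage}\t{record.kept}\t{record.removed}\n")


def _tsv_rows(path: Path, n_columns: int) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_columns} "
                    f"tab-separated columns, got {len(fields)}"
                )
            yield lineno, fields


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id → residues mapping; duplicate ids error."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def read_domains_tsv(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read the 4-column domain annotation table, grouped by sequence id."""
    path = Path(path)
    annotations: dict[str, list[DomainAnnotation]] = {}
    for lineno, (seq_id, domain_id, start, end) in _tsv_rows(path, 4):
        try:
            ann = DomainAnnotation(seq_id, domain_id, int(start), int(end))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        annotations.setdefault(seq_id, []).append(ann)
    return annotations


def read_kingdoms_tsv(path: str | Path) -> dict[str, str]:
    """Read the 2-column seq_id → kingdom table."""
    path = Path(path)
    kingdoms: dict[str, str] = {}
    for lineno, (seq_id, kingdom) in _tsv_rows(path, 2):
        if kingdom not in KINGDOMS:
            raise ValueError(
                f"{path}: line {lineno}: unknown kingdom {kingdom!r} "
                f"(expected one of {', '.join(KINGDOMS)})"
            )
        kingdoms[seq_id] = kingdom
    return kingdoms


def assemble_proteins(
    sequences: Mapping[str, str],
    annotations: Mapping[str, list[DomainAnnotation]],
    kingdoms: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Join sequences, annotations and kingdom labels into protein records."""
    kingdoms = kingdoms or {}
    return [
        ProteinRecord(
            id=seq_id,
            residues=residues,
            annotations=list(annotations.get(seq_id, [])),
            kingdom=kingdoms.get(seq_id),
        )
        for seq_id, residues in sequences.items()
    ]


def read_benchmark(directory: str | Path) -> BenchmarkBundle:
    """Read a benchmark directory written by :func:`write_benchmark`.

    The round trip is the identity on every bundle field except the audit
    trail, which records the construction run, not the benchmark.
    """
    directory = Path(directory)
    sequences = read_fasta(directory / "targets.fasta")
    annotations = read_domains_tsv(directory / "domains.tsv")
    kingdoms = read_kingdoms_tsv(directory / "kingdoms.tsv")
    targets = assemble_proteins(sequences, annotations, kingdoms)
    targets_by_id = {p.id: p for p in targets}

    entries: list[CatalogEntry] = []
    path = directory / "catalog.tsv"
    for lineno, (index, _label, domains, members) in _tsv_rows(path, 4):
        try:
            arch = DomainArchitecture(tuple(domains.split(",")), int(index))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        entries.append(CatalogEntry(arch, members.split(",")))
    catalog = ArchitectureCatalog(entries)

    queries: list[tuple[ProteinRecord, DomainArchitecture]] = []
    split: dict[str, str] = {}
    path = directory / "queries.tsv"
    for lineno, (query_id, da_label, assignment) in _tsv_rows(path, 3):
        if query_id not in targets_by_id:
            raise ValueError(f"{path}: line {lineno}: unknown query id {query_id!r}")
        entry = catalog.by_label(da_label)
        if entry is None:
            raise ValueError(f"{path}: line {lineno}: unknown DA label {da_label!r}")
        if assignment not in (TRAINING, TEST):
            raise ValueError(f"{path}: line {lineno}: bad split {assignment!r}")
        queries.append((targets_by_id[query_id], entry.architecture))
        split[query_id] = assignment

    relevant: dict[str, set[str]] = {record.id: set() for record, _ in queries}
    path = directory / "relevant.tsv"
    for lineno, (query_id, target_id) in _tsv_rows(path, 2):
        if query_id not in relevant:
            raise ValueError(f"{path}: line {lineno}: unknown query id {query_id!r}")
        relevant[query_id].add(target_id)

    audit: list[AuditRecord] = []
    audit_path = directory / "audit.tsv"
    if audit_path.exists():
        for _lineno, (stage, kept, removed) in _tsv_rows(audit_path, 3):
            audit.append(AuditRecord(stage, int(kept), int(removed)))

    return BenchmarkBundle(
        targets=targets,
        queries=queries,
        split=split,
        catalog=catalog,
        relevant=relevant,
        audit=audit,
    )
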