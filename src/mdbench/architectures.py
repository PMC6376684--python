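"""Domain architectures: collapsed domain vectors, catalogs, and containment.

A protein's *domain architecture* (DA) is the N- to C-terminal order of its
annotated domains after collapsing each maximal run of identical adjacent
labels into a single instance.  Two proteins share a relevancy relationship
when the target's DA contains the query's DA as an ordered subsequence:
the retrieved protein must carry every query domain, in the query's order,
though not its multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Iterator, Sequence

__all__ = [
    "KINGDOMS",
    "DomainAnnotation",
    "ProteinRecord",
    "DomainArchitecture",
    "CatalogEntry",
    "ArchitectureCatalog",
    "OverlappingDomainsError",
    "collapse_adjacent",
    "architecture_of",
    "has_overlapping_annotations",
    "build_catalog",
    "contains_architecture",
]

#: Recognised kingdom-of-life labels used for phylogenetic-breadth filtering.
KINGDOMS = ("Eukarya", "Bacteria", "Archaea")


class OverlappingDomainsError(ValueError):
    """A protein with overlapping domain annotations reached an operation
    that requires each residue to belong to at most one domain; the protein
    must be filtered out first."""


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain instance: a closed residue interval on a sequence.

    Coordinates are 1-based inclusive, as in Pfam-style annotation tables.
    """

    sequence_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(
                f"domain {self.domain_id} on {self.sequence_id}: "
                f"start must be >= 1, got {self.start}"
            )
        if self.start > self.end:
            raise ValueError(
                f"domain {self.domain_id} on {self.sequence_id}: "
                f"start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        """Number of residues in the annotated interval."""
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """A protein sequence with ordered domain annotations.

    ``annotations`` are kept sorted ascending by start position; unsorted
    input is sorted, not rejected.  ``kingdom`` is an optional coarse
    taxonomic label (one of :data:`KINGDOMS`).
    """

    id: str
    residues: str
    annotations: list[DomainAnnotation] = field(default_factory=list)
    kingdom: str | None = None

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.sequence_id != self.id:
                raise ValueError(
                    f"annotation for {ann.sequence_id!r} attached to protein {self.id!r}"
                )
            if self.residues and ann.end > len(self.residues):
                raise ValueError(
                    f"{self.id}: domain {ann.domain_id} ends at {ann.end} "
                    f"but sequence has {len(self.residues)} residues"
                )
        if self.kingdom is not None and self.kingdom not in KINGDOMS:
            raise ValueError(f"{self.id}: unknown kingdom {self.kingdom!r}")
        self.annotations = sorted(self.annotations, key=lambda a: (a.start, a.end))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def domain_ids(self) -> list[str]:
        """Domain identifiers in ascending start order (uncollapsed)."""
        return [a.domain_id for a in self.annotations]

    @property
    def n_domains(self) -> int:
        """Raw (pre-collapse) annotation count."""
        return len(self.annotations)


@dataclass(frozen=True)
class DomainArchitecture:
    """A collapsed, ordered vector of domain identifiers.

    The collapsed form is an invariant: no two adjacent entries are equal.
    ``index`` is the catalog number assigned at first occurrence; the label
    renders it in the conventional zero-padded form (index 101 → "da00101").
    """

    domains: tuple[str, ...]
    index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        for a, b in zip(self.domains, self.domains[1:]):
            if a == b:
                raise ValueError(
                    f"architecture {self.domains} is not collapsed "
                    f"(adjacent repeat of {a!r}); use collapse_adjacent()"
                )
        if self.index is not None and self.index < 1:
            raise ValueError(f"architecture index must be >= 1, got {self.index}")

    @property
    def label(self) -> str | None:
        """Zero-padded catalog label, e.g. ``da00101``; None if unindexed."""
        return None if self.index is None else f"da{self.index:05d}"

    def with_index(self, index: int) -> "DomainArchitecture":
        return DomainArchitecture(self.domains, index)

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self) -> Iterator[str]:
        return iter(self.domains)


def collapse_adjacent(domains: Sequence[str]) -> DomainArchitecture:
    """Collapse maximal runs of identical adjacent domain labels.

    A protein annotated ``d1, d2, d2, d2, d3, d2`` has architecture
    ``(d1, d2, d3, d2)``: repeats are dropped only when adjacent, so domain
    order — including later re-occurrences — is preserved.  Idempotent.
    """
    return DomainArchitecture(tuple(label for label, _run in groupby(domains)))


def has_overlapping_annotations(protein: ProteinRecord) -> bool:
    """True iff some residue lies inside two or more (closed) domain intervals."""
    max_end = 0
    for ann in protein.annotations:  # sorted by start
        if ann.start <= max_end:
            return True
        max_end = max(max_end, ann.end)
    return False


def architecture_of(protein: ProteinRecord) -> DomainArchitecture:
    """Derive a protein's collapsed domain architecture.

    Raises :class:`OverlappingDomainsError` for proteins with overlapping
    annotations — evaluation assumes each residue belongs to at most one
    domain, so such sequences must be filtered out upstream.
    """
    if has_overlapping_annotations(protein):
        raise OverlappingDomainsError(
            f"{protein.id}: overlapping domain annotations; "
            "filter the protein out before deriving its architecture"
        )
    return collapse_adjacent(protein.domain_ids)


@dataclass
class CatalogEntry:
    """One distinct architecture and the ids of the sequences carrying it."""

    architecture: DomainArchitecture
    member_ids: list[str]


class ArchitectureCatalog:
    """Ordered collection of distinct architectures with ascending indices.

    Entries appear in assignment order; each distinct collapsed vector occurs
    exactly once and every member id belongs to exactly one entry.
    """

    def __init__(self, entries: Iterable[CatalogEntry] = ()) -> None:
        self._entries: list[CatalogEntry] = list(entries)
        self._by_domains: dict[tuple[str, ...], CatalogEntry] = {}
        self._entry_of_member: dict[str, CatalogEntry] = {}
        prev_index = 0
        for entry in self._entries:
            key = entry.architecture.domains
            if key in self._by_domains:
                raise ValueError(f"duplicate architecture {key} in catalog")
            if entry.architecture.index is None:
                raise ValueError(f"catalog entry {key} has no index")
            if entry.architecture.index <= prev_index:
                raise ValueError("catalog indices must be strictly ascending")
            prev_index = entry.architecture.index
            self._by_domains[key] = entry
            for member in entry.member_ids:
                if member in self._entry_of_member:
                    raise ValueError(f"sequence {member} appears in two entries")
                self._entry_of_member[member] = entry

    @property
    def entries(self) -> list[CatalogEntry]:
        return list(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArchitectureCatalog):
            return NotImplemented
        return [(e.architecture, e.member_ids) for e in self._entries] == [
            (e.architecture, e.member_ids) for e in other._entries
        ]

    @property
    def member_ids(self) -> list[str]:
        return list(self._entry_of_member)

    def index_of(self, architecture: DomainArchitecture | Sequence[str]) -> int | None:
        """Catalog index of a collapsed domain vector, or None if absent."""
        key = tuple(architecture)
        entry = self._by_domains.get(key)
        return None if entry is None else entry.architecture.index

    def entry_for(self, architecture: DomainArchitecture | Sequence[str]) -> CatalogEntry | None:
        return self._by_domains.get(tuple(architecture))

    def entry_of_member(self, sequence_id: str) -> CatalogEntry | None:
        return self._entry_of_member.get(sequence_id)

    def by_label(self, label: str) -> CatalogEntry | None:
        for entry in self._entries:
            if entry.architecture.label == label:
                return entry
        return None


def build_catalog(proteins: Iterable[ProteinRecord]) -> ArchitectureCatalog:
    """Index the distinct architectures of a protein collection.

    Proteins are stably sorted by collapsed-domain count (ties keep input
    order) and indices 1, 2, 3, … are assigned at the first occurrence of
    each architecture, so smaller architectures receive smaller numbers.
    """
    derived = [(protein, architecture_of(protein)) for protein in proteins]
    ordered = sorted(derived, key=lambda pair: len(pair[1]))  # stable
    entries: dict[tuple[str, ...], CatalogEntry] = {}
    for protein, arch in ordered:
        key = arch.domains
        if key not in entries:
            entries[key] = CatalogEntry(arch.with_index(len(entries) + 1), [])
        entries[key].member_ids.append(protein.id)
    return ArchitectureCatalog(entries.values())


def contains_architecture(
    query_da: DomainArchitecture | Sequence[str],
    target_da: DomainArchitecture | Sequence[str],
    policy: str = "subsequence",
) -> bool:
    """Decide whether the target architecture contains the query architecture.

    With the default ``subsequence`` policy the query's domains must appear
    in the target in the same N- to C-terminal order, not necessarily
    adjacent.  The stricter ``substring`` policy additionally requires the
    query domains to be contiguous within the target.  Both relations are
    reflexive and transitive but asymmetric in general: (HAMP, MCPsignal)
    is contained in (CHASE3, HAMP, MCPsignal), not the reverse.
    """
    query = tuple(query_da)
    target = tuple(target_da)
    if policy == "subsequence":
        it = iter(target)
        return all(domain in it for domain in query)
    if policy == "substring":
        if not query:
            return True
        n, m = len(target), len(query)
        return any(target[i : i + m] == query for i in range(n - m + 1))
    raise ValueError(f"unknown containment policy {policy!r}")
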