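# Methods

## Domain architectures and relevancy

A protein's domain architecture (DA) is the ordered vector of its domain
identifiers, read N- to C-terminal from annotations sorted by start
position, with every maximal run of identical adjacent labels collapsed to
a single instance. Collapsing is idempotent and order-preserving: a protein
annotated `d1,d2,d2,d2,d3,d2` has DA `(d1,d2,d3,d2)` — later
re-occurrences of a domain are kept, only adjacent repeats merge. The
toolkit never infers domains; annotations are inputs.

Relevancy of a retrieved target to a query is decided in two stages:

1. **Architecture containment.** The query's collapsed DA must appear in
   the target's collapsed DA in the same order. By default containment is
   an ordered *subsequence* test (intervening domains in the target are
   allowed); a stricter contiguous *substring* policy is available via
   `policy="substring"`. The subsequence reading was chosen because the
   relevancy rule constrains which domains appear and in what order, not
   their adjacency; both published worked examples are consistent with
   either reading, which is why the policy is a single switch rather than
   a hard-coded choice. Containment is reflexive and transitive, so a
   query is always relevant to itself; it is asymmetric in general —
   `(HAMP, MCPsignal)` is contained in `(CHASE3, HAMP, MCPsignal)` but not
   vice versa, and the architecture `BIR-UBA-CARD-RING` (after collapsing
   `BIR-BIR-BIR-…`) is not contained in `BIR-UBA-RING`.
2. **Domain coverage.** The alignment reported by the tool must cover at
   least 50% (inclusive) of the annotated domain residues — a tool that
   ranks the right protein via the wrong region has guessed, not
   retrieved. Coverage is aggregate over all domain residues (not
   per-domain), computed as |union of aligned intervals ∩ union of domain
   intervals| / |union of domain intervals| on 1-based closed intervals.
   Which sequence anchors the measurement is configurable: `target`
   (default — the retrieved protein is what a researcher inspects),
   `query`, or `both` (the minimum of the two must pass). When a
   query–target pair has several HSPs, the pair's score is the minimum
   E-value and coverage uses all reported intervals.

Architecture is checked first; each judgment carries a machine-readable
reason (`architecture_match`, `architecture_mismatch`, `coverage_fail`).
The relevant set of a query — every database target whose DA contains the
query's DA — defines T_q; since the target database includes the queries,
the query itself is always counted.

## Benchmark construction

The cascade, in order, with an audit record (`stage, kept, removed`)
appended at every step:

1. Remove sequences in which any residue carries two or more domain
   annotations (closed-interval intersection); every downstream measure
   assumes one domain per residue. Everything that survives — single- and
   multi-domain, even unannotated — forms the target database.
2. Partition out the multi-domain sequences. By default a sequence is
   multi-domain when it has ≥ 2 raw annotations, i.e. a protein annotated
   `A,A` counts as multi-domain; `count_collapsed=True` switches to
   counting after collapsing. The pre-collapse default follows the cascade
   order (partition first, DA assignment after), and both behaviours are
   exposed because annotation counts alone cannot settle the question.
3. Catalog the distinct DAs: sequences stably sorted by collapsed-domain
   count (ties keep input order), indices 1, 2, 3, … assigned at first
   occurrence, rendered as `da%05d` labels. Indices survive later
   filtering, so labels are stable identifiers.
4. Keep DAs with at least `min_members` (default 2) member sequences and
   at least one member of length ≤ `max_query_length` (default 1800
   residues, a cap that keeps search runtimes practical).
5. Optionally (default on) keep only DAs whose members span ≥ 2 kingdoms
   of life (Eukarya/Bacteria/Archaea), for phylogenetic breadth. Kingdom
   labels come from an input table — never from an online taxonomy
   service — and members without labels are ignored for the span but
   counted in the audit.
6. Choose one query per surviving DA, uniformly among members within the
   length cap. Each DA draws from its own generator seeded with
   `(rng_seed, DA index)`, so inserting or removing a DA never perturbs
   any other DA's choice.
7. Order queries by DA index and alternate them: odd 1-based ranks →
   Training, even → Test.

Zero-annotation sequences stay in the target database (they are legitimate
decoys) but can never become queries. The whole build is deterministic
under `rng_seed`, and the benchmark round-trips through flat text files
(FASTA + TSVs) with write→read identity on everything except the audit
trail.

## TAP-k

Definitions are in the README. Numerical conventions:

- **Precision sum.** The sum Σ p(m) runs over the *relevant* ranks at or
  below the cutoff — the standard text-retrieval average precision. This
  reading is required for the 1.0 endpoint: with T_q relevant records at
  ranks 1..T_q and the cutoff at rank T_q, each p(m) = 1 and
  p(E₀) = 1, giving (T_q + 1)/(T_q + 1) = 1 exactly. The literal
  all-ranks-up-to-the-last-relevant reading is available with
  `all_ranks=True` for comparison.
- **p(E₀)** is the precision at the rank of the last record of *any*
  relevance scoring ≤ E₀, and 0 when no record does.
- **Threshold selection.** Candidate cutoffs are the retrieved scores
  themselves. The per-query statistic is the count of irrelevant records
  scoring ≤ the candidate; the median over queries is the *lower* median
  for even query counts (the conservative choice — it admits fewer
  irrelevant records), and the condition is median ≤ k. E₀ is the largest
  admissible candidate. When even the smallest candidate fails, E₀ is
  placed one float below the smallest score, which makes every TAP score 0;
  if that smallest score is 0.0 this lands on a denormal just below zero,
  a deliberate trade of the E₀ ≥ 0 convention for a sentinel-free
  interface. E₀ is non-decreasing in k.
- **Score ties** keep input order (search tools emit best-first); an
  optional tie policy breaks equal E-values by descending bit score.
- **Exact 1.0 and the threshold.** Because E₀ is chosen to admit up to k
  irrelevant records for the median query, a tool with perfect score
  separation still scores below 1.0 whenever irrelevant records were
  retrieved at all: the cutoff deliberately reaches past the last relevant
  record. TAP-k = 1.0 therefore characterises retrievals with no
  irrelevant record below the cutoff, not merely well-separated ones.
- Queries with T_q = 0 cannot arise from a benchmark built here (every DA
  has ≥ 2 members and the query counts itself); if supplied externally
  they are excluded from evaluation with a warning.

Tool comparison reports paired differences (a − b), the percentage of
exactly equal pairs, mean and standard deviation of the differences, and a
one-sided Wilcoxon–Mann–Whitney p-value (normal approximation with tie and
continuity corrections, via `scipy.stats.mannwhitneyu`); the test treats
the two per-query score lists as samples from two populations.

## Synthetic worlds

The fixture generator emulates the *structure* of curated multi-domain
benchmarks, not their biology:

- Architectures are drawn without replacement from Pfam-like labels
  (`PF00001`, …), 2–5 domains each by default; each gets 2–6 member
  sequences. Domains are 40–200 residues with 5–60 residue linkers;
  residue content is uniform random over the 20 amino acids, which is
  irrelevant to every operation in the toolkit (only annotations, lengths
  and scores matter).
- A quarter of domain instances (default) are expanded into adjacent
  repeats, so collapsing is always exercised; the first member of each
  architecture carries no repeats, bounding its length well under the
  1800-residue query cap.
- Kingdoms are sampled per member (45/45/10 Eukarya/Bacteria/Archaea by
  default) with the first two members of each architecture forced to
  differ, emulating the phylogenetic breadth a curated benchmark selects
  for; as a consequence every generated architecture survives the default
  cascade and yields exactly one query.
- Mock retrievals: every relevant target is retrieved; E-values are
  log-uniform over [1e−5, 1e2] for irrelevant hits, with relevant hits
  shifted down by `retrieval_signal` decades (default 4). Alignments cover
  a configurable fraction of the annotated domain residues on both sides
  (default 0.9; set 0.4 to make every architecture-matching hit fail the
  coverage criterion). 4–12 irrelevant targets pad each query's list.

What passing tests on these worlds do show: the cascade's bookkeeping, the
exactness of the relevancy logic and the metric, and the evaluation
pipeline's ability to recover a known ordering difference between two
tools. What they cannot show: behaviour under real homology structure —
correlated E-values, partial-domain alignments, compositional bias, or
annotation error in real databases.

## Problem sizes

The shipped test suite uses worlds of 10–100 architectures. The
discrimination check uses 100 queries with tool signals of 4.0 vs 1.5
decades; the null calibration of the comparison test runs 200 replicates
of a 30-query world at zero signal and expects the 5%-level rejection rate
in [2%, 9%]. The acceptance script scores two single-query retrievals (3
and 28 records); their TAP values are analytically exact, so the small
size is the point, not a concession.

## Known limitations

- The builder holds the protein set in memory; fine for 10⁵–10⁶ sequences
  with typical annotation density, not engineered beyond that.
- Relevant-set computation compares each query DA against each distinct
  target DA; with Q queries and D distinct DAs it is O(Q·D·L) in domain
  count L. Benchmarks with ~10³ queries and ~10⁴ DAs are comfortable.
- The exact tie and median conventions of other TAP implementations vary;
  the conventions above are documented and configurable where they bite
  (tie policy, containment policy, coverage basis, all-ranks AP), but no
  bug-for-bug compatibility with any particular implementation is claimed.
- BLAST XML/pairwise formats are out of scope; use tabular output.
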