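# Methods

## Detection model

A CRISPR array fragment inside a read is modeled as
`DR' – spacer – DR' (– spacer – DR' …)`, where each `DR'` is a copy of a
known query direct repeat within Levenshtein distance `d_max` (insertions,
deletions, substitutions; unit cost). Detection is reference-guided: it
finds arrays only for DRs the user supplies, in exchange for sensitivity on
shallow or fragmented metagenomes where de novo repeat discovery fails.

The engine computes, for each (query, strand) pair passing a fast
edit-distance pre-filter, the semi-global DP vector
`D[j] = min_i Lev(read[i:j], q)` (one vectorized recurrence per query
character; the in-row dependency is resolved as a running minimum of
`t[j'] + (j − j')`). Every end position with `D[j] ≤ d_max` becomes a
candidate with its minimum-edit, shortest span; overlapping candidates of
one (query, strand) collapse to the best by (edits, span length, start),
which prevents one degenerate repeat from spawning shadow matches. Across
queries, matches are chained into a maximal non-overlapping set greedily in
priority order (fewer edits, then longer span, then leftmost, then query
id); this greedy provably selects the lexicographically best maximal
non-overlapping subset under that order, which is what the exhaustive
subset oracle in the tests checks. Spacers are called only between
*consecutive* chained matches of the *same* query and strand: a DR triplet
yields two spacers (the array reading), and chimeric cross-query flanks are
rejected because a mixed-taxon query set gives them no biological reading.
Minus-strand spacers are reverse-complemented on extraction so all output
follows the query's orientation.

`N` is a legal read symbol but never matches anything, including another
`N` — a low-quality base can consume edit budget but cannot create
evidence. Coordinates everywhere are 0-based, half-open.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `d_max` | 3 | edits | study range 0–3; 3 is the sensitive end |
| `min_spacer` | 26 | bp | lower end of the empirical spacer range |
| `max_spacer` | 60 | bp | maximum allowed distance between detected repeats |
| `dr_len_range` | 23–47 | bp | advisory; out-of-range queries warn, not fail |
| `both_strands` | true | — | arrays occur on either strand; disable for strict single-strand replication |

Whether the original tooling searched reverse complements is not recorded;
both behaviors are exposed and the default is the biologically complete one.

## Non-redundancy and clustering

Detection first collapses exact duplicate spacer sequences (hash
semantics, provenance retained), then a separate clustering step collapses
near-duplicates: greedy, longest-first, first-fit to the earliest
representative at identity ≥ 0.9. Identity is the number of identical
aligned positions in the best global alignment (match +1, mismatch −1, gap
−2 linear; ties broken toward more identities) divided by the shorter
sequence's length — the CD-HIT convention, stated explicitly here because
the convention is otherwise implicit in a tool name. The guarantee is the
clustering semantics, not CD-HIT's word-filter heuristics; on 26–60 bp
spacers the exact DP is cheap. Strand-insensitive by default, matching
nucleotide CD-HIT usage on unoriented metagenomic spacers.

## Spacer-to-virus alignment and E-values

Spacers are short (26–60 bp) and protospacers are expected near-exact, so
the built-in aligner is ungapped: every exact 11-mer shared between a
spacer orientation and a subject nucleates its diagonal, and the
maximal-scoring ungapped segment on that diagonal is kept per (spacer,
subject, strand, diagonal). Scoring is +1/−2. The E-value is
`E = K·m·n·exp(−λS)` with `m` the spacer length and `n` the *summed*
library length (database-style search space — results depend on this
choice, so it is fixed and documented). λ is solved at import from Karlin's
equation `¼e^λ + ¾e^(−2λ) = 1` (λ ≈ 1.33); K uses the standard published
value 0.621 for this scoring pair. The default cutoff is E ≤ 10⁻³.
Bit-for-bit parity with NCBI BLAST is a non-goal; a 12-column tabular
reader accepts genuine BLAST output (1-based inclusive coordinates,
`sstart > send` encoding the minus strand) for exact replication studies.

Network edges carry the host-taxon label of the DR query that detected the
spacer — never anything inferred from the virus side — and "unknown" when
the query is unannotated. Output is SIF plus node/edge attribute TSVs
(round-trippable), with an optional GraphML mirror.

## k-mer usage signatures

Profiles are overlapping-window frequencies over `{A,C,G,T}^k`, k ∈ {2, 3},
windows containing `N` excluded so each profile remains a proper
distribution; counting is forward-strand (the distance measure is
strand-naive; a both-strands option exists, off by default). The virus–host
distance is the summed squared per-word frequency difference. Group
summaries report mean ± 2·SE (SE = sd/√n, 0 for singletons) after
collapsing duplicate (group, virus, host) rows, so each group summarizes a
non-redundant virus list. The functions take exactly the sequences given —
multi-replicon genomes are never auto-concatenated; pass the replicon you
mean (e.g., chromosome 1 of a two-chromosome halophile).

## Synthetic metagenome generator

The generator emulates the pipeline's target regime: single-end
pyrosequencing-era reads with lengths from a truncated normal (mean 480 bp,
sd 40, floor 100 bp — bracketing the 429–523 bp average read lengths of the
runs this method targets), a library of 100 random viral genomes of
5–50 kb, 50 array reads on 950 background reads, spacers of 26–50 bp
excised from the viruses, and 29 random DR queries of 23–47 bp labeled with
synthetic host taxa (the size of a realistic multi-taxon query set).

Design choices that make the truth manifest exact rather than approximate:

- **Exactly-e edits.** Each DR copy is mutated to distance *exactly* e
  (e drawn uniformly in [0, `dr_mutation_edits`]), verified and re-sampled
  otherwise, so detectability at every budget is knowable a priori.
- **Unambiguous planting.** After assembly, each copy's span is audited to
  be the strict best occurrence among all overlapping candidate spans
  within ±6 bp of its boundaries (edit-edge effects can otherwise shift the
  optimal span and hence the extracted spacer by a base); ambiguous
  plantings are redrawn. The audit uses a library edit-distance routine,
  not the detection DP, so end-to-end recall tests are not circular.
- **Repeat-free background.** Background reads and array flanks are
  rejection-sampled to contain no DR occurrence within 3 edits on either
  strand, giving precision a clean denominator.
- **Distant queries.** Simulated DR queries are mutually distant and far
  from their own reverse complements, so each planted array has a unique
  owning query. Real DR sets from closely related taxa can violate this;
  with near-duplicate queries a spacer may be attributed to a sister DR,
  which the exact-recall guarantee does not cover.

Every artifact is a pure function of (parameters, seed). The truth manifest
has one row per planted spacer (array reads with multiple spacers emit
multiple rows). Scoring: a planting is recovered when a detected spacer has
exactly its residues and traces by provenance to its read; the recall
denominator at budget *d* is the plantings whose geometry is admissible and
whose flanking copies both carry ≤ *d* edits; with zero detections,
precision is reported as 1.0 with an explicit flag.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: pyrosequencing homopolymer errors (edits are
injected only into DR copies), community abundance structure, genuine viral
sequence composition, paired ends, and quality variation. The generator
validates the machinery's correctness under the stated model, not its field
sensitivity.

## Problem sizes and numerical choices

The acceptance run and end-to-end tests use 1,000 reads / 50 array reads /
100 viruses — large enough that every stage (recruitment, chaining,
dedup, clustering, seeding, extension, E-value filtering) is exercised with
mixed edit loads on both strands, small enough to run comfortably on a
laptop. Ties everywhere are broken deterministically (documented orderings
on matches, chains, cluster scan order, diagonal segments), so identical
inputs give byte-identical outputs. Degenerate inputs: empty read sets,
empty clusters, and empty networks are errors or valid empty files exactly
as each function documents; spacers shorter than the seed length warn and
yield no hits.

## Known limitations

- Spacers at a read's edge (only one flanking DR copy) are invisible by
  construction; the method needs both flanks in one read.
- The greedy chain is globally optimal only under its stated priority
  order; pathological overlapping repeat structures could admit other
  defensible readings.
- The built-in aligner's E-values are calibrated for its own ungapped
  scoring; they are comparable across runs of this package, not across
  BLAST versions.
- Clustering is O(n²) in distinct spacers; intended for the thousands, not
  millions.
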