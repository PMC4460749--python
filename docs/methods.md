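# Methods

## Model and procedure

The assembler reconstructs a genome from short shotgun reads by a hybrid of
overlap–layout–consensus and de Bruijn-style condensation.  Its central
object is the **seed**: an l-mer pattern over `{A,C,G,T,n}` together with
the list of reads aligned under it (`(seq_id, offset, strand)` triples,
each carrying its window string) and a link to the following seed.  A read
cluster is represented as a **seeds chain** — an ordered, initially
non-overlapping tiling of seeds on the cluster center's coordinate line —
and the **seeds graph** connects seeds by chain adjacency and by cross-chain
suffix–prefix overlaps longer than `q`.

The pipeline is deterministic given the RNG seed and proceeds in five
phases: (1) both-strand k-mer grouping with the abundance filter
`1 < CountSeqs ≤ t`; (2) greedy clustering around uniformly random centers,
one read belonging to exactly one cluster; (3) seed/chain merging and graph
construction; (4) mate-pair repeat resolution; (5) contig extraction and
scaffolding.

Alignment is gap-free throughout: reads are placed by integer shifts and
validated by per-window Hamming comparisons.  This matches the
substitution-dominated error profile of the targeted instruments and keeps
every placement checkable by direct string comparison.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `k`  | 11      | indexing k-mer length; small enough that overlapping reads nearly always share a k-mer |
| `l`  | 20      | seed length (`k < l`); chosen so 4^l far exceeds twice any target genome size, making seeds near-unique outside repeats |
| `t`  | 100     | maximum distinct reads sharing a retained k-mer; above it a k-mer is treated as repeat-borne and dropped |
| `e`  | 3       | strict per-window mismatch bound (`< e`) for cluster admission and seed membership |
| `h`  | 0.5     | minimum fraction of a member's bases under its chain's seed windows; below it the member is evicted and returned to the pool |
| `q`  | 14      | strict minimum suffix–prefix overlap (`> q`) for a graph edge; at `l = 20` this keeps the spurious-match probability per seed pair below 4^−15 |
| `insert_size` | 180 bp | mate-pair fragment length; drives repeat resolution and scaffolding |
| `insert_tol` | 0.2 | relative tolerance when testing a path length against the insert |
| `min_links` | 3 | mate pairs required to join two contigs in a scaffold |
| `min_contig_length` | 100 bp | contigs shorter than this are suppressed |
| `branch_support` | 3 | reads on a second allele at which extension beyond the center stops (see below) |

`t`, `e`, `h` and `q` are genuinely free parameters of the method and are
exposed in the CLI and YAML config; the defaults above are used everywhere
in the tests.

## Design choices

**Offset coding.**  A reverse-strand k-mer occurrence at offset `o` of the
reverse-complemented read is coded `−(o+1)`, which keeps offset 0
unambiguous and makes the coding bijective.

**Shift reconciliation.**  A candidate sharing several k-mers with the
center may imply conflicting placements; the majority shift wins, ties
break toward smaller |shift| and then the forward strand.

**Window admission.**  A candidate joins the cluster only via a window it
*fully* covers with fewer than `e` mismatches against the center.
Partial-window comparisons would admit reads on the strength of a single
shared k-mer (a 4^−11 coincidence is common at genome scale) and let their
overhangs contaminate the cluster; full 20-column validation makes
coincidental admission essentially impossible.

**l-mer extension.**  The k-mer window is extended symmetrically —
`ceil((l−k)/2)` left, remainder right — clamped to the read bounds.

**Extension beyond the center and branch stop.**  Outside the center's
span there is no arbiter read, so windows are built from member-vs-member
column consensus (majority base, `n` on residual disagreement, same `e`
bound per member).  Extension stops when a column shows a second allele
supported by at least `branch_support` fully-covering reads: such a column
means two genomic contexts (the flanks of a repeat) have been merged into
one cluster, and extending by majority vote would pick a flank arbitrarily,
producing a chimeric chain.  Stopping leaves the decision to the graph
stage, where mate pairs carry the information needed to make it.  A lone
disagreeing read (a sequencing error) does not stop extension.

**Seed merging.**  "Same pattern" includes wildcard-compatible patterns by
default (`merge_mode: wildcard`), since `n` columns exist precisely to
absorb errors; merged columns are re-derived from the pooled member
windows and the smallest seed id survives.  `merge_mode: strict` restricts
merging to byte-identical patterns.

**Chain fusing.**  Chains sharing at least two consecutive seeds are laid
on a common coordinate fixed by the shared run; a one-seed share is left to
overlap edges.  Fused chains may contain overlapping windows (negative
next-distances); inconsistent layouts are left unmerged with a warning.

**Overlap edges and strands.**  All ordered cross-chain seed pairs are
scanned for exact (wildcard-aware) suffix–prefix overlaps; each pair is
additionally tested against the reverse complement and recorded with an
orientation flag, which two-strand data requires because cluster
orientation follows the (random) center read.  Plain patterns are matched
through prefix/suffix hash indexes over the `q+1..l−1` lengths; wildcard
patterns fall back to the naive scan.  A brute-force all-pairs scan is kept
in the test suite as the oracle for this index.

**Where overlap edges are traversable.**  Contig extraction works on an
oriented expansion of the graph (nodes `(seed, ±1)`, every edge present in
both senses).  Overlap edges are traversed only where they join chain
tails; an overlap hit against a chain's interior restates sequence the
chain already spells (two clusters covering the same locus at a compatible
phase) and treating it as a branch would cut both chains into fragments.
Interior hits therefore remain in the graph but do not break or extend
paths.

**Contigs.**  Maximal paths whose interior nodes have in- and out-degree
one are emitted (a unitig-style realization of Euler-path extraction — on
the mate-pair-resolved components the two coincide), splicing seed patterns
with wildcards resolved by member majority, chain gaps filled from the
cluster consensus, and overlap duplications dropped.  Reverse-complement
twin paths are deduplicated.  No contig spans a branch.

**Repeat resolution.**  Rule (a): a linear run of nodes with matching
in/out fan (the shared interior of an X) is duplicated when mate pairs pair
every entry with a distinct exit; reads are reassigned to the copy whose
flank they or their mates touch.  Rule (b): among parallel paths between a
shared source and sink spanned by mate pairs, interior nodes of paths whose
length violates `insert_size ± insert_tol` are removed when exactly one
path conforms.  Rules iterate to a fixed point, capped at 10 rounds;
contradictory evidence (no conforming path, ambiguous pairing) leaves the
graph intact with a logged warning.  Repeats longer than both the cluster
span and the insert are untouched by construction.

**Scaffolding.**  Mate pairs whose ends land in different contigs are
bundled by the pair of contig ends they join; bundles of at least
`min_links` pairs become links, applied greedily by descending weight while
rejecting occupied ends and cycles.  Gap estimates are the median of
(insert − end overhangs) and may be negative; rendered scaffolds separate
parts by `max(gap, 1)` Ns.

## The simulator

`simulate_genome` draws i.i.d. uniform bases and plants exact repeat copies
at non-overlapping random positions; `simulate_reads` draws fragments of
Normal(insert, sd) length (truncated to ≥ read length) uniformly from a
linear genome, emitting a forward 5' read and a reverse-complemented 3'
read per fragment with i.i.d. substitution errors, and records ground-truth
offsets and strands.  It emulates the target regime — 101 bp pairs, 180 bp
inserts, substitution-only errors — and deliberately omits indels, quality
values, coverage bias, chimeric fragments and adapter artifacts.  Passing
tests on this generator therefore demonstrate the algorithmic contracts
(partitioning, soundness, exactness, repeat handling) under the stated
noise model, not robustness to every artifact of real libraries.

Problem sizes used by the tests and the acceptance script — 10 kb genomes
at 25–40× (roughly 1,000–4,000 reads) — are the package's chosen
desk-scale versions of the instrument regime; all statistics are computed
fresh at run time from the seeded simulator.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open.  Reads containing `N` are kept, but
k-mer/l-mer windows spanning an `N` are skipped.  Quality strings are
parsed and discarded.  Consensus ties yield `N`; a read shorter than `k`
indexes nothing; a center shorter than `l` yields a seedless singleton
chain; an empty graph yields no contigs; contigs without links become
singleton scaffolds.  `n50` follows the weighted-median definition
(largest L with pieces ≥ L holding half the total).  Chain TSV, k-mer TSV
and edge-list formats are documented in `seedsgraph/serialize.py`; staged
CLI execution reproduces the monolithic run byte-for-byte.

## Known limitations

- Seed windows tile at the phase of each cluster's center, so two chains
  covering the same locus share seeds only when their centers agree modulo
  `l`; cross-chain overlap edges require phase offsets within `l − q − 1`
  positions.  Contigs are therefore cluster-scale (hundreds of bp at these
  coverages) and long-range contiguity is carried by scaffolds.  This is
  intrinsic to the seeds-graph design, which trades contig length for a
  drastically smaller graph.
- For the same reason, a repeat copy's two flanks generally end up in
  different chains; the assembler guarantees that every repeat junction is
  covered by an exact, non-chimeric contig (the branch-stop rule prevents
  flank mixing), but a single contig spanning flank–repeat–flank
  additionally requires phase-compatible overlap edges.
- Repeat resolution assumes the shared run is clean (no external edges
  into its interior) and that mate evidence yields a perfect entry/exit
  matching; anything less is conservatively left intact.
- Gap-free alignment cannot place reads across indels; indel-rich data
  would fragment clusters.
- The all-pairs overlap scan is quadratic in the number of seeds in its
  oracle form; the hashed index keeps the default path near-linear, but
  wildcard-dense pattern sets degrade toward the naive scan.
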