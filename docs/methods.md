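# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data used to validate them, and the
design decisions taken where the underlying procedure admitted more than
one reasonable formalization.

## Coordinate conventions

All internal intervals, and PAF and BED on disk, are 0-based half-open.
AGP is emitted 1-based inclusive, as the format requires; conversion
happens only at (de)serialization. FASTA input is uppercase-normalized and
any character outside `{A,C,G,T,N}` becomes `N` (counted, never dropped),
so sequence length is conserved through every stage — several invariants
below rely on that.

## Contig curation

Two draft assemblies of the same reads rarely make the same misjoin, so a
region of one assembly not covered by any alignment to the other is
evidence of a join unique to it. "Discrepancy" is formalized as a maximal
internal alignment-coverage gap on a contig longer than
`coverage_tolerance` (default 100 bp), *partner-agnostic*: alignments to
any companion contig count as coverage, and gaps up to the tolerance are
bridged. One split is placed at the midpoint of each such gap — the
midpoint is unbiased given no finer signal. Uncovered contig *ends* are not
discrepancies; alignment end effects would otherwise shatter every
terminus.

Zero-coverage splitting re-maps the long reads — and 500 bp end-pairs cut
from each read of length ≥ 1 kb, which contribute span evidence across
repeats — and splits at internal runs of zero depth of length
≥ `min_zero_run` (default 1: any truly uncovered base splits). Runs
touching a contig end become trim reports instead of splits. Coverage from
reads and from end-pairs is combined by summing depth
(`combine_profiles`); a base must be covered by neither source to trigger
a split. Whether the two sources should instead each independently cover
every base (an intersection rule, producing more splits) is exposed by
keeping the profiles separate until the caller combines them.

Read rescue flags reads whose mapped fraction — the length of the union of
their query intervals across all alignments, divided by read length — is
strictly below `max_mapped_fraction` (default 0.10). A read at exactly the
threshold is not rescued; unmapped reads are.

## Reference-guided scaffolding

The scaffolder re-implements the *role* of a synteny-block scaffolder with
a transparent weighted-anchor model:

1. **Anchor blocks.** Contig-to-reference alignments at mapping quality ≥
   `min_mapq` (default 30) sharing (contig, chromosome, strand) are
   chained when successive query and reference gaps are both ≤
   `max_chain_gap` (default 100 kb) and reference order is collinear for
   the strand. Blocks spanning < `min_block` (default 5 kb) of the contig
   are dropped as repeat noise. Block weight is the summed PAF match count.
2. **Placement.** Chromosome = argmax of summed weight (ties to the
   lexicographically smallest name, so plans are total-ordered and
   byte-reproducible); orientation = strand-weight majority (tie → `+`);
   ordering key = weight-weighted median of block reference midpoints —
   the median is robust to a minority of repeat-induced stray anchors.
   The ratio of runner-up to chosen chromosome weight is reported as
   `ambiguity` ∈ [0, 1].
3. **Ordering and gaps.** Per chromosome, contigs sort by ordering key
   (ties: longer contig first, then id). The gap between neighbours is the
   reference distance between their facing anchors minus the unaligned
   contig tails that will occupy part of it, floored at `min_gap`
   (default 100 bp). Reference projection is the only gap signal available
   without additional data; the floor keeps a sentinel `N` run between
   every join so downstream tools can see the boundary.
4. **Multiple references** are applied sequentially, closest first.
   Contigs placed with ambiguity ≤ `max_ambiguity` (default 0.8) are
   withheld from later references; a later reference can only add
   placements, never move or remove one. How conflicts between references
   *should* be arbitrated is genuinely open; strict precedence is the
   simplest rule whose outcome is independent of later inputs.
5. **Conflict detection** against a prior scaffold plan: adjacent
   alignments (in contig order) hitting different scaffolds, or the same
   scaffold with a target jump > `max_jump` (default 1 Mb), split the
   contig at the midpoint between the two alignments — provided each side
   carries ≥ `min_side` (default 50 kb) aligned bases, so alignment dust
   cannot split real joins.

## Gap closing

Reads overlapping a 20 kb window around each scaffold gap — and around
each scaffold terminus, which is a gap to its neighbour that has simply not
been found yet — are extracted per window (a read may serve several
windows) and locally assembled. The local assembler is a greedy
end-overlap assembler: candidate suffix–prefix overlaps between two
sequences (any relative orientation) are proposed by shared 15-mers —
a k-mer at left-position *p* and right-position *q* implies an overlap of
`len(left) − p + q`; candidates need ≥ 3 supporting k-mers — and verified
longest-first by global edit-distance alignment (edlib), bounded by the
identity threshold so rejection is linear-time. A merge needs overlap ≥
`min_overlap` (1 kb) at identity ≥ `min_identity` (0.95, sized for the
98–99 % accuracy of consensus-grade contig ends); sequences contained in
another are absorbed. The pair with the longest acceptable overlap merges
first (ties: identity, then lexicographic ids), so results are
deterministic. The assembler is deliberately desk-scale; any external
assembler's contigs can be passed to `close_gaps` as patches instead.

Closure tries, per gap: (1) a **patch** overlapping the left flank's 3′
end and the right flank's 5′ end each by ≥ `min_overlap` — the patch's
inter-flank sequence replaces the gap; (2) a direct **stitch** of the two
flanks. Junction bases are taken from the left flank by convention —
deterministic, and consensus across flanks belongs to polishing, which is
out of scope. Both searches look at the outermost `max_search` (100 kb)
bases of each flank. Closure merges components and never splits, so contig
N50 is non-decreasing, and a second invocation on the output closes
nothing (idempotence; both properties are tested).

Pseudo-read chunking tiles a contig into `chunk_length` (250 kb) pieces
every `step` (200 kb), respecting the 256 kb read cap of the target
assembler; the 50 kb (20 %) overlap is this package's choice and keeps
every junction inside at least one chunk.

## Rearrangement classification

Input is assembly-to-reference PAF from a whole-genome mapper, filtered to
mapping quality ≥ 60 — the most uniquely placed alignments. Split
neighbouring alignments are re-chained (same chromosome and strand, query
and reference gaps ≤ `max_chain_gap`, reference order collinear).
`max_chain_gap` defaults to 300 kb, equal to `min_event_size`, so an
alignment break smaller than a countable event can never fragment a chain
into two spurious events; the two scales move together if reconfigured.

Per query scaffold, chains spanning < `min_event_size` of the query are
ignored entirely, then:

* **f (fusion/fission)** — one event per adjacent chain pair on different
  reference chromosomes. Fusions and fissions are one class: the same
  junction, read in opposite directions.
* **dominant context** — the chromosome, then strand, carrying the
  majority of chain weight.
* **i (inversion)** — one event per maximal run of chains opposite to the
  dominant strand with query span ≥ `min_event_size`. A scaffold that is
  entirely reverse-complemented relative to the reference has dominant
  strand `−` and therefore zero inversions — global orientation is
  arbitrary.
* **t (intra-chromosomal translocation)** — on the dominant
  chromosome/strand, the weight-maximal strictly monotone subsequence of
  reference starts (increasing for `+`, decreasing for `−`; O(n²) dynamic
  program, exact) defines the collinear backbone; every excluded chain is
  one event.

A segment that is both displaced and inverted is counted once as t and
once as i: the two signals are independent under these definitions, and
merging them would require breakpoint reasoning below the resolution this
counter aims at.

## Assembly statistics

N50 is the smallest length L such that sequences ≥ L sum to ≥ 50 % of the
assembly; the top-*n* fraction is the share of *ungapped* (non-N) bases in
the *n* largest scaffolds, with *n* the haploid chromosome number.
Contig-level metrics derive from splitting scaffolds at `N` runs ≥
`min_gap_run` (default 10 — short enough to catch every planned gap, long
enough to ignore isolated ambiguous bases).

## Synthetic data and what the tests show

The generator draws i.i.d. uniform bases (configurable GC), so the
synthetic genomes are repeat-free; planted-event recovery and scaffolding
recovery on them demonstrate the *logic* is exact when anchors are
unambiguous, not performance on repeat-rich real genomes. Reads carry
i.i.d. per-base substitution/insertion/deletion errors — no homopolymer or
chimera model — which suffices to exercise identity thresholds.

The sample genome is maintained as a piecewise-rigid segment map onto the
reference: inversions flip a segment in place, translocations excise and
reinsert a segment 1 Mb downstream (length conserved), fusions concatenate
the two largest chromosomes, fissions split one. Event loci are placed
≥ 1 Mb from chromosome ends and each other, so events never interact, and
exact truth alignments (PAF, mapq 60) are emitted by composing contig
provenance with the segment map. Fragmentation can be told to keep
breakpoints out of event loci (± 400 kb in the validation harnesses): a
contig boundary inside an event locus splits the event's alignment
signature across two query sequences, where per-query classification
cannot — and should not — count it exactly once. Whole-genome validation
uses a 30 Mb, 4-chromosome genome with ~1 Mb contigs: large enough that
every event has ≥ 300 kb flanks inside one contig, small enough that the
full suite runs in about two minutes.

Degenerate inputs are defined, not special-cased: empty alignment sets
place nothing; a contig with no anchors is reported unplaced; zero-length
event lists produce an identity sample; `nxx` and `assembly_report` reject
empty collections loudly.

## Known limitations

* Gap estimates inherit reference structure; a reference insertion
  inflates the planned gap.
* The greedy assembler is quadratic in window read count and intended for
  gap-window scale, not genome scale.
* Curated contig fragments need external re-mapping before re-scaffolding;
  the pipeline leaves them unplaced if only the original alignments exist.
* No consensus polishing, no Hi-C/optical-map integration, no diploidy in
  the simulator.
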