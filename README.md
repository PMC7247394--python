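# chromoscaf

Chromosome-scale assembly tooling for long-read draft genomes: contig
curation, reference-guided scaffolding, gap closing, and large-scale
rearrangement counting — as a tested Python library with a thin CLI.

Long-read assemblers produce contigs that are accurate locally but fall
short of chromosome scale, and occasionally contain misjoins. This package
implements the computational stages that turn such contigs into chromosome
scaffolds, using one or more (possibly diverged) reference genomes as an
ordering guide, with all alignments supplied as PAF from any external
mapper — or generated internally, with exact ground truth, by the
synthetic-genome module.

## What it does

1. **Curation** (`chromoscaf curate`) — split contigs where two
   independently produced draft assemblies disagree (an alignment-coverage
   gap larger than a tolerance), and where re-mapped long reads — plus
   500 bp end-pairs cut from each read — leave regions at zero coverage.
   Reads whose mapped fraction is below 10 % of their length are flagged
   for re-assembly rescue.
2. **Scaffolding** (`chromoscaf scaffold`) — chain contig-to-reference
   alignments into anchor blocks, assign each contig to the chromosome with
   the majority of its anchor weight, orient it by strand majority, order
   contigs by the weighted median of their anchor positions, and estimate
   inter-contig gaps from projected reference distance. Multiple references
   are consumed in precedence order (closest first); a later reference never
   moves a contig placed by an earlier one.
3. **Gap closing** (`chromoscaf gapfill` / `chromoscaf stitch`) — extract
   reads mapping within 20 kb windows around every scaffold gap and
   terminus, locally assemble each window with a greedy end-overlap
   assembler (edit-distance verified), and close gaps either with a patch
   contig spanning both flanks or by directly stitching overlapping
   neighbouring contig ends. Contigs longer than an assembler's read cap
   (256 kb) can be chunked into overlapping pseudo-reads.
4. **Rearrangement counting** (`chromoscaf svstats`) — filter
   assembly-to-reference PAF to mapping quality 60, re-chain split
   neighbouring alignments, and count large (>300 kb) discrepancies per
   scaffold: inter-chromosomal fusions/fissions (f), intra-chromosomal
   translocations (t, chains excluded from the weight-maximal collinear
   subsequence), and inversions (i, runs aligned opposite to the
   scaffold's dominant strand). Dot-plot coordinates are exported as TSV.
5. **Statistics** (`chromoscaf stats`) — N50/L50, ungapped length, and the
   top-*n* fraction: the share of assembled bases in the *n* largest
   scaffolds, with *n* the haploid chromosome number — the standard measure
   of chromosome-scale completeness.
6. **Simulation** (`chromoscaf simulate`) — a multi-chromosome reference, a
   sample genome derived from it by planting ≥300 kb inversions,
   translocations and fusions, fragmentation into shuffled and randomly
   oriented contigs with recorded provenance, noisy reads, and exact truth
   alignments in PAF — so every stage is testable without downloads.

## Worked example

Simulate a 30 Mb four-chromosome genome with one 700 kb inversion, one
700 kb intra-chromosomal translocation and one chromosome fusion, fragment
it into ~1 Mb contigs, then scaffold and analyse:

```sh
chromoscaf simulate --seed 11 -o demo
chromoscaf scaffold --contigs demo/contigs.fasta \
    --ref-paf demo/contigs_on_ref.paf -o demo/scaf
chromoscaf svstats --paf demo/contigs_on_ref.paf -o demo/sv
chromoscaf stats --fasta demo/scaf/scaffolds.fasta --top-n 4
```

which prints:

```
simulated 28 contigs from 3 chromosomes
scaffold: 4 scaffolds, 24 gaps, 0 unplaced
f=1 t=1 i=1
n_sequences     4
total_length    30002400
ungapped_length 30000000
n50     7600700
l50     2
contig_count    28
contig_n50      1182287
top_n   4
top_n_fraction  1.000000
gap_count       24
gap_bases       2400
```

The sample genome has 3 chromosomes because the fusion joined two of the
reference's 4; scaffolding against the reference still recovers all 4
reference chromosomes with every contig placed (`top_n_fraction 1.0`), and
the rearrangement counter reports exactly the planted events: one
fusion/fission (f), one intra-chromosomal translocation (t), one inversion
(i). Each 100 bp `N` run in the scaffolds is an estimated gap between
neighbouring contigs (24 gaps × 100 bp = 2 400 gap bases).

The full pipeline (curation → scaffolding → gap filling → statistics) runs
from a single config file:

```sh
chromoscaf init-config pipeline.ini   # edit input paths
chromoscaf pipeline --config pipeline.ini -o out
```

## Library layout

| module | contents |
| --- | --- |
| `chromoscaf.io_formats` | FASTA/PAF/AGP/BED readers and writers, strict dialects, gzip transparent |
| `chromoscaf.curation` | coverage profiles, zero-coverage and reconciliation splitting, read rescue |
| `chromoscaf.refscaffold` | anchor chaining, placement, ordering, gap estimation, conflict detection |
| `chromoscaf.gapclose` | gap windows, pseudo-reads, greedy overlap assembly, patching and stitching |
| `chromoscaf.svclassify` | MQ filtering, chaining, f/t/i event classification, dot-plot export |
| `chromoscaf.metrics` | Nxx, ungapped length, top-n fraction, assembly reports |
| `chromoscaf.synthetic` | reference/sample simulation, planted events, truth alignments |
| `chromoscaf.pipeline`, `chromoscaf.cli`, `chromoscaf.config` | orchestration, CLI, configuration |

See `docs/methods.md` for the models, parameter semantics and design
decisions.
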