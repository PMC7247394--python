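import pytest

from chromoscaf import synthetic
from chromoscaf.io_formats import PafAlignment, SequenceRecord
from chromoscaf.refscaffold import (
    AnchorBlock,
    ContigPlacement,
    build_anchor_blocks,
    detect_scaffold_conflicts,
    order_and_gap,
    place_contigs,
    plan_to_sequences,
    scaffold_multi_reference,
)


def aln(q, qlen, qs, qe, t, tlen, ts, te, mapq=60, strand="+", matches=None):
    span = qe - qs
    m = matches if matches is not None else min(span, te - ts)
    return PafAlignment(q, qlen, qs, qe, strand, t, tlen, ts, te, m,
                        max(span, te - ts), mapq)


class TestAnchorBlocks:
    def test_chaining_within_gap(self):
        alns = [
            aln("c", 100000, 0, 20000, "chr1", 1_000_000, 0, 20000, matches=19000),
            aln("c", 100000, 30000, 50000, "chr1", 1_000_000, 32000, 52000, matches=18000),
        ]
        (block,) = build_anchor_blocks(alns)
        assert block.n_members == 2
        assert block.weight == 37000
        assert (block.contig_start, block.contig_end) == (0, 50000)

    def test_opposite_strands_never_merge(self):
        alns = [
            aln("c", 100000, 0, 20000, "chr1", 1_000_000, 0, 20000),
            aln("c", 100000, 30000, 50000, "chr1", 1_000_000, 32000, 52000, strand="-"),
        ]
        assert len(build_anchor_blocks(alns)) == 2

    def test_low_mapq_dropped(self):
        alns = [aln("c", 100000, 0, 20000, "chr1", 1_000_000, 0, 20000, mapq=20)]
        assert build_anchor_blocks(alns, min_mapq=30) == []

    def test_short_block_dropped(self):
        alns = [aln("c", 100000, 0, 3000, "chr1", 1_000_000, 0, 3000)]
        assert build_anchor_blocks(alns, min_block=5000) == []


class TestPlacement:
    def blk(self, cid, ref, weight, strand="+", mid=500_000):
        half = 1000
        return AnchorBlock(cid, 0, max(weight, 5000), ref, mid - half, mid + half,
                           strand, weight)

    def test_majority_chromosome_and_ambiguity(self):
        blocks = [self.blk("c", "chr1", 800), self.blk("c", "chr2", 200)]
        (p,) = place_contigs(blocks)
        assert p.ref_name == "chr1"
        assert p.ambiguity == pytest.approx(0.25)

    def test_strand_majority(self):
        blocks = [self.blk("c", "chr1", 300, "+"), self.blk("c", "chr1", 700, "-")]
        (p,) = place_contigs(blocks)
        assert p.orientation == "-"

    def test_tie_breaks_lexicographic_with_full_ambiguity(self):
        blocks = [self.blk("c", "chr2", 500), self.blk("c", "chr1", 500)]
        (p,) = place_contigs(blocks)
        assert p.ref_name == "chr1"
        assert p.ambiguity == pytest.approx(1.0)


class TestOrderAndGap:
    def test_reference_projected_gap(self):
        blocks = [
            AnchorBlock("A", 0, 200000, "chr1", 900_000, 1_100_000, "+", 200000),
            AnchorBlock("B", 0, 200000, "chr1", 1_900_000, 2_100_000, "+", 200000),
        ]
        placements = place_contigs(blocks)
        plan = order_and_gap(placements, blocks, {"A": 200000, "B": 200000})
        (scaf,) = plan.scaffolds
        assert [c.contig_id for c in scaf.components] == ["A", "B"]
        assert scaf.gaps == [800_000]

    def test_negative_projection_floors_at_min_gap(self):
        blocks = [
            AnchorBlock("A", 0, 200000, "chr1", 900_000, 1_100_000, "+", 200000),
            AnchorBlock("B", 0, 200000, "chr1", 1_050_000, 1_250_000, "+", 200000),
        ]
        placements = place_contigs(blocks)
        plan = order_and_gap(placements, blocks, {"A": 200000, "B": 200000})
        assert plan.scaffolds[0].gaps == [100]

    def test_single_contig_scaffold(self):
        blocks = [AnchorBlock("A", 0, 100000, "chrZ", 0, 100000, "+", 100000)]
        plan = order_and_gap(place_contigs(blocks), blocks, {"A": 100000})
        (scaf,) = plan.scaffolds
        assert scaf.scaffold_id == "scaffold_chrZ"
        assert scaf.gaps == []

    def test_unanchored_contig_unplaced(self):
        blocks = [AnchorBlock("A", 0, 100000, "chr1", 0, 100000, "+", 100000)]
        plan = order_and_gap(place_contigs(blocks), blocks, {"A": 100000, "B": 5000})
        assert plan.unplaced == ["B"]

    def test_unaligned_tails_shrink_gap(self):
        # A has a 50 kb unaligned right tail that projects into the gap
        blocks = [
            AnchorBlock("A", 0, 150000, "chr1", 900_000, 1_050_000, "+", 150000),
            AnchorBlock("B", 0, 200000, "chr1", 1_900_000, 2_100_000, "+", 200000),
        ]
        placements = place_contigs(blocks)
        plan = order_and_gap(placements, blocks, {"A": 200000, "B": 200000})
        assert plan.scaffolds[0].gaps == [850_000 - 50_000]


class TestConflicts:
    def test_inter_scaffold_junction(self):
        alns = [
            aln("c", 1_000_000, 0, 600_000, "scf1", 10_000_000, 0, 600_000),
            aln("c", 1_000_000, 600_000, 1_000_000, "scf2", 10_000_000, 0, 400_000),
        ]
        (s,) = detect_scaffold_conflicts(alns)
        assert (s.position, s.reason) == (600_000, "scaffold_conflict")

    def test_intra_scaffold_jump(self):
        alns = [
            aln("c", 1_000_000, 0, 600_000, "scf1", 10_000_000, 0, 600_000),
            aln("c", 1_000_000, 600_000, 1_000_000, "scf1", 10_000_000,
                5_600_000, 6_000_000),
        ]
        assert len(detect_scaffold_conflicts(alns, max_jump=1_000_000)) == 1

    def test_clean_collinear_contig(self):
        alns = [
            aln("c", 1_000_000, 0, 600_000, "scf1", 10_000_000, 0, 600_000),
            aln("c", 1_000_000, 600_000, 1_000_000, "scf1", 10_000_000,
                600_000, 1_000_000),
        ]
        assert detect_scaffold_conflicts(alns) == []

    def test_small_side_ignored(self):
        alns = [
            aln("c", 1_000_000, 0, 30_000, "scf1", 10_000_000, 0, 30_000),
            aln("c", 1_000_000, 30_000, 1_000_000, "scf2", 10_000_000, 0, 970_000),
        ]
        assert detect_scaffold_conflicts(alns, min_side=50_000) == []


class TestPlanToSequences:
    def test_reverse_complement_and_gap(self):
        from chromoscaf.refscaffold import Scaffold, ScaffoldComponent, ScaffoldPlan

        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("c1", "+"), ScaffoldComponent("c2", "-")],
                      [3])],
            [],
            {"c1": 5, "c2": 4},
        )
        (seq,) = plan_to_sequences(
            plan, [SequenceRecord("c1", "AAAAA"), SequenceRecord("c2", "AACC")]
        )
        assert seq.sequence == "AAAAANNNGGTT"
        assert len(seq.sequence) == 12

    def test_only_unplaced_passthrough(self):
        from chromoscaf.refscaffold import ScaffoldPlan

        plan = ScaffoldPlan([], ["a", "b"], {"a": 4, "b": 4})
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "TTTT")]
        assert plan_to_sequences(plan, recs) == recs

    def test_non_n_bases_conserved(self, rng):
        from chromoscaf.refscaffold import Scaffold, ScaffoldComponent, ScaffoldPlan
        from conftest import make_sequence

        seqs = [SequenceRecord(f"c{i}", make_sequence(rng, 50)) for i in range(4)]
        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent(s.id, o) for s, o in
                            zip(seqs[:3], "+-+")], [10, 20])],
            [seqs[3].id],
            {s.id: 50 for s in seqs},
        )
        out = plan_to_sequences(plan, seqs)
        total_in = sum(len(s.sequence) for s in seqs)
        total_out = sum(len(s.sequence) - s.sequence.count("N") for s in out)
        assert total_out == total_in


class TestRecoveryAndDeterminism:
    def build(self, seed):
        ref = synthetic.simulate_reference([2_000_000, 1_500_000], seed=seed)
        sample, truth = synthetic.plant_rearrangements(ref, [], seed=seed)
        contigs, prov = synthetic.fragment_into_contigs(
            sample, target_n50=150_000, min_len=20_000, seed=seed, truth=truth
        )
        ref_lengths = {r.id: len(r.sequence) for r in ref}
        paf = synthetic.truth_alignments(prov, truth.segment_maps, ref_lengths)
        return ref, contigs, prov, paf

    def test_truth_alignment_recovery(self):
        ref, contigs, prov, paf = self.build(3)
        lengths = {c.id: len(c.sequence) for c in contigs}
        blocks = build_anchor_blocks(paf)
        plan = order_and_gap(place_contigs(blocks), blocks, lengths)
        for scaf in plan.scaffolds:
            chrom = scaf.scaffold_id.removeprefix("scaffold_")
            expected = sorted(
                ((cid, p) for cid, p in prov.items() if p[0] == chrom),
                key=lambda kv: kv[1][1],
            )
            got = [(c.contig_id, c.orientation) for c in scaf.components]
            assert got == [(cid, p[3]) for cid, p in expected]
        seqs = plan_to_sequences(plan, contigs)
        by_id = {r.id: r for r in ref}
        for s in seqs:
            chrom = s.id.removeprefix("scaffold_")
            assert s.sequence.replace("N", "") == by_id[chrom].sequence

    def test_byte_identical_plans(self):
        _, contigs, _, paf = self.build(4)
        lengths = {c.id: len(c.sequence) for c in contigs}
        plans = []
        for _ in range(2):
            blocks = build_anchor_blocks(paf)
            plans.append(order_and_gap(place_contigs(blocks), blocks, lengths))
        a, b = plans
        assert [s.components for s in a.scaffolds] == [s.components for s in b.scaffolds]
        assert [s.gaps for s in a.scaffolds] == [s.gaps for s in b.scaffolds]

    def test_multi_reference_never_unplaces_earlier(self):
        _, contigs, _, paf = self.build(5)
        lengths = {c.id: len(c.sequence) for c in contigs}
        # second (diverged) reference sees only half the contigs
        half = {a.query_name for a in paf if int(a.query_name.split("_")[1]) % 2 == 0}
        paf2 = [a for a in paf if a.query_name in half]
        single = scaffold_multi_reference([paf], lengths)
        double = scaffold_multi_reference([paf, paf2], lengths)
        placed_single = {c.contig_id for s in single.scaffolds for c in s.components}
        placed_double = {c.contig_id for s in double.scaffolds for c in s.components}
        assert placed_single <= placed_double
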