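import numpy as np
import pytest

from chromoscaf.gapclose import (
    chunk_pseudo_reads,
    close_gaps,
    extract_gap_windows,
    greedy_overlap_assemble,
    stitch_gap,
    suffix_prefix_overlap,
)
from chromoscaf.io_formats import PafAlignment, SequenceRecord, reverse_complement
from chromoscaf.refscaffold import Scaffold, ScaffoldComponent, ScaffoldPlan
from conftest import make_sequence


def read_aln(rid, scaffold, slen, ts, te):
    span = te - ts
    return PafAlignment(rid, span, 0, span, "+", scaffold, slen, ts, te,
                        span, span, 60)


class TestGapWindows:
    def make_plan(self):
        return ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("c1", "+"), ScaffoldComponent("c2", "+")],
                      [100])],
            [],
            {"c1": 10_000, "c2": 89_900},  # gap at [10000, 10100), length 100000
        )

    def test_read_in_window_included(self):
        plan = self.make_plan()
        windows = extract_gap_windows(plan, [read_aln("r", "s", 100_000, 25_000, 26_000)])
        gap = next(w for w in windows if w.gap_id == "s.gap0")
        assert (gap.window_start, gap.window_end) == (0, 30_100)
        assert gap.read_ids == {"r"}

    def test_distant_read_excluded(self):
        plan = self.make_plan()
        windows = extract_gap_windows(plan, [read_aln("r", "s", 100_000, 50_000, 51_000)])
        gap = next(w for w in windows if w.gap_id == "s.gap0")
        assert gap.read_ids == set()

    def test_gapless_scaffold_has_two_terminal_windows(self):
        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("c", "+")], [])], [], {"c": 100_000}
        )
        windows = extract_gap_windows(plan, [])
        assert {(w.gap_id, w.window_start, w.window_end) for w in windows} == {
            ("s.start", 0, 20_000),
            ("s.end", 80_000, 100_000),
        }


class TestPseudoReads:
    def test_three_chunk_tiling(self):
        contig = SequenceRecord("c", "A" * 600_000)
        chunks = chunk_pseudo_reads(contig)
        spans = [tuple(map(int, c.id.split(":")[1].split("-"))) for c in chunks]
        assert spans == [(0, 250_000), (200_000, 450_000), (400_000, 600_000)]

    def test_short_contig_single_chunk(self):
        contig = SequenceRecord("c", "A" * 100_000)
        (chunk,) = chunk_pseudo_reads(contig)
        assert chunk.sequence == contig.sequence

    def test_read_cap_enforced(self):
        with pytest.raises(ValueError):
            chunk_pseudo_reads(SequenceRecord("c", "A" * 10), chunk_length=300_000)

    @pytest.mark.parametrize("n", [1, 99_999, 250_000, 250_001, 777_777])
    def test_union_covers_contig_and_overlaps_are_constant(self, n):
        contig = SequenceRecord("c", "A" * n)
        chunks = chunk_pseudo_reads(contig)
        spans = [tuple(map(int, c.id.split(":")[1].split("-"))) for c in chunks]
        assert spans[0][0] == 0 and spans[-1][1] == n
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 <= e1  # no holes
            assert e1 - s2 == 50_000  # chunk_length - step
        covered = set()
        for s, e in spans:
            covered.update((s, e) for _ in (0,))
        total = 0
        last = 0
        for s, e in spans:
            total += e - max(s, last)
            last = e
        assert total == n


class TestOverlapPrimitives:
    def test_exact_overlap_found(self, rng):
        genome = make_sequence(rng, 6000)
        left = SequenceRecord("l", genome[:4000])
        right = SequenceRecord("r", genome[2000:])
        merge = stitch_gap(left, right)
        assert merge is not None
        assert merge.overlap_length == 2000
        assert merge.identity == 1.0
        assert merge.merged_length == 4000 + 4000 - 2000

    def test_below_min_overlap_rejected(self, rng):
        genome = make_sequence(rng, 6000)
        left = SequenceRecord("l", genome[:3250])
        right = SequenceRecord("r", genome[2750:])
        assert stitch_gap(left, right, min_overlap=1000) is None

    def test_low_identity_rejected(self, rng):
        genome = make_sequence(rng, 6000)
        left = genome[:4000]
        right = list(genome[2000:])
        # mutate 10% of the 2000-base junction inside the right flank
        positions = rng.choice(2000, 200, replace=False)
        for p in positions:
            right[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[right[p]]
        merge = stitch_gap(
            SequenceRecord("l", left), SequenceRecord("r", "".join(right)),
            min_identity=0.95,
        )
        assert merge is None

    def test_merged_length_identity(self, rng):
        genome = make_sequence(rng, 9000)
        left = SequenceRecord("l", genome[:5000])
        right = SequenceRecord("r", genome[3500:])
        merge = stitch_gap(left, right)
        assert merge is not None
        assert merge.merged_length == len(left.sequence) + len(right.sequence) - merge.overlap_length


class TestGreedyAssembly:
    def tile(self, rng, n=20_000, read_len=4000, step=2000):
        genome = make_sequence(rng, n)
        reads = []
        s = 0
        i = 0
        while True:
            e = min(s + read_len, n)
            reads.append(SequenceRecord(f"r{i:02d}", genome[s:e]))
            if e >= n:
                break
            s += step
            i += 1
        return genome, reads

    def test_exact_tiling_reconstructs(self, rng):
        genome, reads = self.tile(rng)
        out = greedy_overlap_assemble(reads, min_overlap=1000)
        assert len(out) == 1
        assert out[0].sequence in (genome, reverse_complement(genome))

    def test_disjoint_reads_stay_separate(self, rng):
        a = SequenceRecord("a", make_sequence(rng, 3000))
        b = SequenceRecord("b", make_sequence(rng, 3000))
        out = greedy_overlap_assemble([a, b], min_overlap=1000)
        assert sorted(r.sequence for r in out) == sorted([a.sequence, b.sequence])

    def test_strand_symmetry(self, rng):
        genome, reads = self.tile(rng)
        reads[3] = SequenceRecord(reads[3].id, reverse_complement(reads[3].sequence))
        out = greedy_overlap_assemble(reads, min_overlap=1000)
        assert len(out) == 1
        assert out[0].sequence in (genome, reverse_complement(genome))

    def test_contained_read_absorbed(self, rng):
        genome = make_sequence(rng, 8000)
        reads = [
            SequenceRecord("big", genome),
            SequenceRecord("small", genome[2000:4000]),
        ]
        out = greedy_overlap_assemble(reads, min_overlap=1000)
        assert [r.sequence for r in out] == [genome]


class TestCloseGaps:
    def fixture(self, rng, gap=500, overlap=2000):
        genome = make_sequence(rng, 12_000)
        left = SequenceRecord("L", genome[:6000])
        right = SequenceRecord("R", genome[6000 - overlap:])
        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("L", "+"), ScaffoldComponent("R", "+")],
                      [gap])],
            [],
            {"L": len(left.sequence), "R": len(right.sequence)},
        )
        return genome, plan, [left, right]

    def test_stitchable_gap_arithmetic(self, rng):
        genome, plan, contigs = self.fixture(rng)
        old_len = plan.scaffold_length(plan.scaffolds[0])
        new_plan, seqs, reports = close_gaps(plan, contigs)
        assert [r.outcome for r in reports] == ["stitched"]
        assert new_plan.gap_count == 0
        assert len(new_plan.scaffolds[0].components) == 1
        new_len = new_plan.scaffold_length(new_plan.scaffolds[0])
        assert old_len - new_len == 500 + 2000  # planned gap + overlap
        assert seqs[0].sequence == genome

    def test_unclosable_gap_stays_open(self, rng):
        left = SequenceRecord("L", make_sequence(rng, 5000))
        right = SequenceRecord("R", make_sequence(rng, 5000))
        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("L", "+"), ScaffoldComponent("R", "+")],
                      [300])],
            [], {"L": 5000, "R": 5000},
        )
        new_plan, _, reports = close_gaps(plan, [left, right])
        assert [r.outcome for r in reports] == ["open"]
        assert new_plan.gap_count == 1
        assert [c.contig_id for c in new_plan.scaffolds[0].components] == ["L", "R"]

    def test_patch_closure_recovers_truth(self, rng):
        genome = make_sequence(rng, 20_000)
        left = SequenceRecord("L", genome[:8000])
        right = SequenceRecord("R", genome[12_000:])
        patch = SequenceRecord("patch", genome[3000:17_000])
        plan = ScaffoldPlan(
            [Scaffold("s", [ScaffoldComponent("L", "+"), ScaffoldComponent("R", "+")],
                      [4000])],
            [], {"L": 8000, "R": 8000},
        )
        new_plan, seqs, reports = close_gaps(plan, [left, right], [patch])
        assert [r.outcome for r in reports] == ["patched"]
        assert seqs[0].sequence == genome

    def test_idempotence(self, rng):
        genome, plan, contigs = self.fixture(rng)
        p1, s1, _ = close_gaps(plan, contigs)
        p2, s2, reports2 = close_gaps(p1, s1)
        assert all(r.outcome == "open" for r in reports2)
        assert [r.sequence for r in s2] == [r.sequence for r in s1]
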