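import numpy as np
import pytest

from chromoscaf.io_formats import reverse_complement
from chromoscaf.metrics import nxx
from chromoscaf.synthetic import (
    Segment,
    _invert,
    fragment_into_contigs,
    plant_rearrangements,
    reads_truth_paf,
    simulate_reads,
    simulate_reference,
    truth_alignments,
)


class TestReference:
    def test_deterministic(self):
        a = simulate_reference([1000], seed=7)
        b = simulate_reference([1000], seed=7)
        assert a[0].sequence == b[0].sequence

    def test_gc_within_binomial_bound(self):
        (rec,) = simulate_reference([100_000], gc=0.5, seed=1)
        gc = sum(rec.sequence.count(b) for b in "GC") / 100_000
        sd = (0.5 * 0.5 / 100_000) ** 0.5
        assert abs(gc - 0.5) < 3 * sd

    def test_exact_lengths_and_names(self):
        recs = simulate_reference([10, 20], seed=0)
        assert [(r.id, len(r.sequence)) for r in recs] == [("chr1", 10), ("chr2", 20)]

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference([10], gc=1.5)


class TestPlanting:
    def genome(self, seed=0):
        return simulate_reference([6_000_000, 5_000_000], seed=seed)

    def test_inversions_conserve_length(self):
        ref = self.genome()
        sample, truth = plant_rearrangements(
            ref, [("inversion", 400_000), ("inversion", 400_000)], seed=1
        )
        assert sum(len(r.sequence) for r in sample) == sum(
            len(r.sequence) for r in ref
        )
        assert [e.size for e in truth.planted_events] == [400_000, 400_000]

    def test_fusion_concatenates(self):
        ref = self.genome()
        sample, truth = plant_rearrangements(ref, [("fusion", 0)], seed=1)
        assert len(sample) == len(ref) - 1
        assert sum(len(r.sequence) for r in sample) == sum(len(r.sequence) for r in ref)

    def test_fission_splits(self):
        ref = self.genome()
        sample, truth = plant_rearrangements(ref, [("fission", 0)], seed=1)
        assert len(sample) == len(ref) + 1
        assert sum(len(r.sequence) for r in sample) == sum(len(r.sequence) for r in ref)

    def test_inversion_is_involution(self):
        segs = [Segment("chr1", 0, 1000, "+")]
        _invert(segs, 200, 700)
        _invert(segs, 200, 700)
        # merged back to an identity map over [0, 1000)
        assert all(s.strand == "+" for s in segs)
        bounds = []
        for s in segs:
            bounds.append((s.ref_start, s.ref_end))
        assert bounds == sorted(bounds)
        assert bounds[0][0] == 0 and bounds[-1][1] == 1000

    def test_translocation_conserves_length_and_content(self):
        ref = self.genome()
        sample, truth = plant_rearrangements(
            ref, [("intra_translocation", 500_000)], seed=2
        )
        by_id = {r.id: r for r in ref}
        for rec in sample:
            assert sorted(rec.sequence) == sorted(by_id[rec.id].sequence)


class TestFragmentation:
    def test_explicit_breakpoints(self):
        ref = simulate_reference([5_000_000], seed=0)
        contigs, prov = fragment_into_contigs(
            ref, breakpoints={"chr1": [1_000_000 * k for k in range(1, 5)]}, seed=0
        )
        assert sorted(len(c.sequence) for c in contigs) == [1_000_000] * 5

    def test_provenance_reconstructs_genome(self):
        ref = simulate_reference([500_000], seed=3)
        contigs, prov = fragment_into_contigs(ref, target_n50=60_000,
                                              min_len=5_000, seed=3)
        by_id = {c.id: c for c in contigs}
        pieces = sorted(prov.items(), key=lambda kv: kv[1][1])
        rebuilt = "".join(
            by_id[cid].sequence if strand == "+"
            else reverse_complement(by_id[cid].sequence)
            for cid, (chrom, s, e, strand) in pieces
        )
        assert rebuilt == ref[0].sequence

    def test_min_len_respected(self):
        ref = simulate_reference([500_000], seed=4)
        contigs, _ = fragment_into_contigs(ref, target_n50=50_000,
                                           min_len=10_000, seed=4)
        assert all(len(c.sequence) >= 10_000 for c in contigs)

    def test_n50_tracks_target_over_20_seeds(self):
        ref = simulate_reference([5_000_000], seed=9)
        target = 300_000
        n50s = []
        for seed in range(20):
            contigs, _ = fragment_into_contigs(ref, target_n50=target,
                                               min_len=10_000, seed=seed)
            n50s.append(nxx([len(c.sequence) for c in contigs]))
        assert abs(np.mean(n50s) - target) / target < 0.25

    def test_avoid_intervals_are_never_cut(self):
        ref = simulate_reference([5_000_000], seed=5)
        avoid = [("chr1", 2_000_000, 2_500_000)]
        contigs, prov = fragment_into_contigs(
            ref, target_n50=200_000, min_len=10_000, seed=5, avoid=avoid
        )
        for chrom, s, e, _ in prov.values():
            assert not (2_000_000 < s < 2_500_000)
            assert not (2_000_000 < e < 2_500_000)


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self):
        ref = simulate_reference([200_000], seed=6)
        reads, prov = simulate_reads(ref, coverage=2, mean_length=5000, seed=6)
        genome = ref[0].sequence
        for rid, (src, s, e, strand, nerr) in list(prov.items())[:50]:
            read = next(r for r in reads if r.id == rid)
            expect = genome[s:e]
            if strand == "-":
                expect = reverse_complement(expect)
            assert read.sequence == expect and nerr == 0

    def test_read_count_poisson_bound(self):
        ref = simulate_reference([1_000_000], seed=7)
        reads, _ = simulate_reads(ref, coverage=20, mean_length=10_000, seed=7)
        assert abs(len(reads) - 2000) < 4 * (2000 ** 0.5)

    def test_substitution_rate_binomial_bound(self):
        ref = simulate_reference([100_000], seed=8)
        reads, prov = simulate_reads(
            ref, coverage=10, mean_length=100_000, length_sd=1,
            sub_rate=0.05, seed=8,
        )
        sampled = sum(e - s for _, s, e, _, _ in prov.values())
        errors = sum(n for *_, n in prov.values())
        expected = 0.05 * sampled
        sd = (sampled * 0.05 * 0.95) ** 0.5
        assert abs(errors - expected) < 3 * sd

    def test_invalid_rate_rejected(self):
        ref = simulate_reference([1000], seed=0)
        with pytest.raises(ValueError):
            simulate_reads(ref, coverage=1, sub_rate=0.5)


class TestTruthAlignments:
    def test_unrearranged_contig_single_record(self):
        maps = {"chr1": [Segment("chr1", 0, 10_000, "+")]}
        prov = {"c": ("chr1", 1000, 2000, "+")}
        (rec,) = truth_alignments(prov, maps, {"chr1": 10_000})
        assert (rec.query_start, rec.query_end) == (0, 1000)
        assert (rec.target_start, rec.target_end) == (1000, 2000)
        assert rec.strand == "+" and rec.mapq == 60

    def test_contig_spanning_inversion_yields_two_strands(self):
        segs = [Segment("chr1", 0, 20_000, "+")]
        _invert(segs, 8_000, 14_000)
        maps = {"chr1": segs}
        prov = {"c": ("chr1", 6_000, 10_000, "+")}
        recs = truth_alignments(prov, maps, {"chr1": 20_000})
        assert sorted(r.strand for r in recs) == ["+", "-"]
        assert len(recs) == 2

    def test_full_contig_set_tiles_reference(self):
        ref = simulate_reference([300_000], seed=10)
        sample, truth = plant_rearrangements(ref, [], seed=10)
        contigs, prov = fragment_into_contigs(sample, target_n50=40_000,
                                              min_len=5_000, seed=10, truth=truth)
        recs = truth_alignments(prov, truth.segment_maps,
                                {"chr1": 300_000})
        covered = sorted((r.target_start, r.target_end) for r in recs)
        pos = 0
        for s, e in covered:
            assert s == pos
            pos = e
        assert pos == 300_000

    def test_reads_truth_paf_roundtrip(self):
        ref = simulate_reference([50_000], seed=11)
        reads, prov = simulate_reads(ref, coverage=1, mean_length=4000, seed=11)
        read_lengths = {r.id: len(r.sequence) for r in reads}
        paf = reads_truth_paf(prov, read_lengths, {"chr1": 50_000})
        assert len(paf) == len(reads)
        assert all(a.mapq == 60 for a in paf)


class TestEndToEndRecovery:
    def test_planted_events_recovered_exactly(self):
        from chromoscaf import svclassify

        ref = simulate_reference([8_000_000, 8_000_000, 7_000_000, 7_000_000],
                                 seed=42)
        events = [("inversion", 600_000)] * 3 + \
                 [("intra_translocation", 650_000)] * 2 + [("fusion", 0)]
        sample, truth = plant_rearrangements(ref, events, seed=42)
        contigs, prov = fragment_into_contigs(
            sample, target_n50=1_000_000, seed=42,
            avoid=truth.avoid_intervals(400_000), truth=truth,
        )
        ref_lengths = {r.id: len(r.sequence) for r in ref}
        paf = truth_alignments(prov, truth.segment_maps, ref_lengths)
        chains = svclassify.chain_alignments(svclassify.filter_mq(paf))
        _, counts = svclassify.classify_events(chains)
        assert counts.as_tuple() == (1, 2, 3)
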