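"""Synthetic genomes with known truth for exercising every pipeline stage.

The generator produces a random multi-chromosome reference, derives a
sample genome from it by planting large inversions, intra-chromosomal
translocations and chromosome fusions/fissions, fragments the sample into
contigs of known provenance and random orientation, and simulates noisy
long reads with recorded origins.  Because the sample genome is maintained
as a piecewise-rigid segment map onto the reference, exact truth alignments
(PAF) can be emitted for any contig — these stand in for an external
aligner in tests, and a real aligner's PAF can be substituted anywhere.

Event placement allocates disjoint loci with generous margins from
chromosome ends and from each other, so planted events never interact;
fragmentation can be told to avoid breakpoints inside those loci so that
each event is witnessed intact by a single contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PafAlignment, SequenceRecord, reverse_complement
from .svclassify import RearrangementEvent

__all__ = [
    "Segment",
    "SyntheticTruth",
    "simulate_reference",
    "plant_rearrangements",
    "fragment_into_contigs",
    "simulate_reads",
    "truth_alignments",
    "reads_truth_paf",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Segment:
    """A rigid piece of a sample chromosome mapped onto the reference."""

    ref_name: str
    ref_start: int
    ref_end: int
    strand: str  # orientation of the sample copy relative to the reference

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def flipped(self) -> "Segment":
        return Segment(
            self.ref_name, self.ref_start, self.ref_end,
            "-" if self.strand == "+" else "+",
        )


@dataclass
class SyntheticTruth:
    """Everything needed for exact-recovery tests."""

    planted_events: list[RearrangementEvent]
    # event loci: full affected interval per event in final sample coords
    loci: list[tuple[str, int, int]]
    segment_maps: dict[str, list[Segment]]  # sample chrom -> ordered segments
    contig_provenance: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    read_provenance: dict[str, tuple[str, int, int, str, int]] = field(default_factory=dict)
    seed: int = 0

    def sample_lengths(self) -> dict[str, int]:
        return {
            name: sum(s.length for s in segs)
            for name, segs in self.segment_maps.items()
        }

    def avoid_intervals(self, margin: int) -> list[tuple[str, int, int]]:
        """Event loci expanded by ``margin``, for breakpoint avoidance."""
        return [(c, max(0, s - margin), e + margin) for c, s, e in self.loci]


def simulate_reference(
    chrom_lengths: Sequence[int], gc: float = 0.5, seed: int = 0
) -> list[SequenceRecord]:
    """Random i.i.d. genome; chromosome ids chr1..chrK; deterministic."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if any(l < 1 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for k, length in enumerate(chrom_lengths, start=1):
        idx = rng.choice(4, size=length, p=probs)
        seq = _BASES[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(f"chr{k}", seq))
    return records


def _materialize(
    segs: Sequence[Segment], ref_by_id: Mapping[str, SequenceRecord]
) -> str:
    parts = []
    for s in segs:
        piece = ref_by_id[s.ref_name].sequence[s.ref_start : s.ref_end]
        parts.append(piece if s.strand == "+" else reverse_complement(piece))
    return "".join(parts)


def _split_at(segs: list[Segment], pos: int) -> int:
    """Ensure a segment boundary at sample offset ``pos``; return its index."""
    acc = 0
    for i, seg in enumerate(segs):
        if acc == pos:
            return i
        if acc < pos < acc + seg.length:
            off = pos - acc
            if seg.strand == "+":
                left = Segment(seg.ref_name, seg.ref_start, seg.ref_start + off, "+")
                right = Segment(seg.ref_name, seg.ref_start + off, seg.ref_end, "+")
            else:
                left = Segment(seg.ref_name, seg.ref_end - off, seg.ref_end, "-")
                right = Segment(seg.ref_name, seg.ref_start, seg.ref_end - off, "-")
            segs[i : i + 1] = [left, right]
            return i + 1
        acc += seg.length
    if acc == pos:
        return len(segs)
    raise ValueError(f"position {pos} outside chromosome of length {acc}")


def _invert(segs: list[Segment], start: int, end: int) -> None:
    i = _split_at(segs, start)
    j = _split_at(segs, end)
    segs[i:j] = [s.flipped() for s in reversed(segs[i:j])]


def _excise(segs: list[Segment], start: int, end: int) -> list[Segment]:
    i = _split_at(segs, start)
    j = _split_at(segs, end)
    mid = segs[i:j]
    del segs[i:j]
    return mid


def _allocate_loci(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    widths: Sequence[int],
    margin: int,
) -> list[tuple[str, int]]:
    """Place loci of the given widths >= margin from chromosome ends and
    from each other, by rejection sampling (deterministic under the rng)."""
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    chroms = sorted(chrom_lengths)
    out: list[tuple[str, int]] = []
    for width in widths:
        placed = False
        for _ in range(5000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            lo, hi = margin, chrom_lengths[chrom] - margin - width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if all(
                start - margin >= e or start + width + margin <= s
                for s, e in used[chrom]
            ):
                used[chrom].append((start, start + width))
                out.append((chrom, start))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place a locus of width {width} with margin {margin}"
            )
    return out


def plant_rearrangements(
    genome: Sequence[SequenceRecord],
    events: Sequence[tuple[str, int]],
    seed: int = 0,
    margin: int = 1_000_000,
    displacement: int = 1_000_000,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Derive a sample genome by planting large rearrangements.

    ``events`` is a list of (kind, size) with kind in {"inversion",
    "intra_translocation", "fusion", "fission"}.  Inversions reverse-
    complement a segment in place; translocations excise a segment and
    reinsert it ``displacement`` bases downstream on the same chromosome
    (length conserved); fusions join the two largest unused chromosomes end
    to end; fissions split a chromosome at a locus boundary.  All loci are
    kept >= ``margin`` from chromosome ends and from each other, so events
    never interact.  Truth records every event at its final sample
    coordinates, plus the full affected locus for breakpoint avoidance.
    """
    rng = np.random.default_rng(seed)
    ref_by_id = {r.id: r for r in genome}
    chrom_lengths = {r.id: len(r.sequence) for r in genome}

    # one locus per in-place event (fusions/fissions handled afterwards)
    inplace = [(k, s) for k, s in events if k in ("inversion", "intra_translocation")]
    fissions = [(k, s) for k, s in events if k == "fission"]
    fusions = [(k, s) for k, s in events if k == "fusion"]
    widths = [
        size if kind == "inversion" else size + displacement
        for kind, size in inplace
    ] + [1 for _ in fissions]
    loci_pos = _allocate_loci(rng, chrom_lengths, widths, margin)

    maps: dict[str, list[Segment]] = {
        r.id: [Segment(r.id, 0, len(r.sequence), "+")] for r in genome
    }
    planted: list[RearrangementEvent] = []
    loci: list[tuple[str, int, int]] = []

    for (kind, size), (chrom, start) in zip(inplace, loci_pos[: len(inplace)]):
        segs = maps[chrom]
        if kind == "inversion":
            _invert(segs, start, start + size)
            planted.append(
                RearrangementEvent("inversion", chrom, start, start + size,
                                   (chrom,), size)
            )
            loci.append((chrom, start, start + size))
        else:
            # excise [start, start+size), reinsert `displacement` downstream
            mid = _excise(segs, start, start + size)
            insert_at = start + displacement  # post-excision coordinates
            i = _split_at(segs, insert_at)
            segs[i:i] = mid
            planted.append(
                RearrangementEvent(
                    "intra_translocation", chrom, insert_at, insert_at + size,
                    (chrom,), size,
                )
            )
            loci.append((chrom, start, start + displacement + size))

    for (kind, _size), (chrom, start) in zip(
        fissions, loci_pos[len(inplace):]
    ):
        segs = maps.pop(chrom)
        i = _split_at(segs, start)
        left, right = segs[:i], segs[i:]
        maps[f"{chrom}a"] = left
        maps[f"{chrom}b"] = right
        planted.append(
            RearrangementEvent("fusion_fission", chrom, start, start, (chrom,),
                               min(start, sum(s.length for s in right)))
        )
        _rename_chrom(planted, loci, chrom, start, f"{chrom}a", f"{chrom}b")

    for _ in fusions:
        # join the two largest chromosomes not yet fused (deterministic)
        names = sorted(maps, key=lambda c: (-sum(s.length for s in maps[c]), c))
        a, b = names[0], names[1]
        junction = sum(s.length for s in maps[a])
        fused = f"{a}_{b}"
        maps[fused] = maps.pop(a) + maps.pop(b)
        blen = sum(s.length for s in maps[fused]) - junction
        planted = [
            _shift_event(ev, a, b, fused, junction) for ev in planted
        ]
        loci = [
            (fused, s + (junction if c == b else 0), e + (junction if c == b else 0))
            if c in (a, b) else (c, s, e)
            for c, s, e in loci
        ]
        planted.append(
            RearrangementEvent("fusion_fission", fused, junction, junction,
                               (a, b), min(junction, blen))
        )
        loci.append((fused, junction, junction))

    truth = SyntheticTruth(planted, loci, maps, seed=seed)
    sample = [
        SequenceRecord(name, _materialize(maps[name], ref_by_id))
        for name in sorted(maps)
    ]
    return sample, truth


def _shift_event(
    ev: RearrangementEvent, a: str, b: str, fused: str, junction: int
) -> RearrangementEvent:
    if ev.query_name == a:
        return RearrangementEvent(ev.kind, fused, ev.query_start, ev.query_end,
                                  ev.ref_names, ev.size)
    if ev.query_name == b:
        return RearrangementEvent(
            ev.kind, fused, ev.query_start + junction, ev.query_end + junction,
            ev.ref_names, ev.size,
        )
    return ev


def _rename_chrom(
    planted: list[RearrangementEvent],
    loci: list[tuple[str, int, int]],
    chrom: str,
    split_at: int,
    left_name: str,
    right_name: str,
) -> None:
    for idx, ev in enumerate(planted):
        if ev.query_name == chrom and ev.kind != "fusion_fission":
            if ev.query_end <= split_at:
                planted[idx] = RearrangementEvent(
                    ev.kind, left_name, ev.query_start, ev.query_end,
                    ev.ref_names, ev.size,
                )
            else:
                planted[idx] = RearrangementEvent(
                    ev.kind, right_name, ev.query_start - split_at,
                    ev.query_end - split_at, ev.ref_names, ev.size,
                )
    for idx, (c, s, e) in enumerate(loci):
        if c == chrom:
            if e <= split_at:
                loci[idx] = (left_name, s, e)
            else:
                loci[idx] = (right_name, s - split_at, e - split_at)


def fragment_into_contigs(
    genome: Sequence[SequenceRecord],
    target_n50: int | None = None,
    breakpoints: Mapping[str, Sequence[int]] | None = None,
    min_len: int = 1000,
    seed: int = 0,
    avoid: Sequence[tuple[str, int, int]] = (),
    truth: SyntheticTruth | None = None,
) -> tuple[list[SequenceRecord], dict[str, tuple[str, int, int, str]]]:
    """Fragment a genome into shuffled, randomly oriented contigs.

    Either explicit ``breakpoints`` per chromosome or a ``target_n50`` must
    be given; in the latter case fragment lengths are drawn uniformly in
    [0.5, 1.5] x a scale calibrated so the achieved N50 tracks the target.
    Breakpoints falling inside an ``avoid`` interval are pushed past it, so
    planted-event loci stay intact within single contigs.  Provenance
    intervals tile each chromosome exactly; the recorded strand is the
    orientation applied to the sample slice to produce the contig sequence.
    If ``truth`` is given, provenance is also stored on it.
    """
    if (target_n50 is None) == (breakpoints is None):
        raise ValueError("give exactly one of target_n50 or breakpoints")
    rng = np.random.default_rng(seed)
    avoid_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in avoid:
        avoid_by_chrom.setdefault(c, []).append((s, e))

    pieces: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for rec in genome:
        n = len(rec.sequence)
        if breakpoints is not None:
            bps = sorted(p for p in breakpoints.get(rec.id, ()) if 0 < p < n)
        else:
            scale = max(min_len, int(target_n50 / 1.118))
            if min_len > n:
                raise ValueError(f"min_len {min_len} exceeds chromosome {rec.id}")
            bps = []
            pos = 0
            while True:
                step = int(rng.uniform(0.5, 1.5) * scale)
                cand = pos + max(min_len, step)
                for s, e in sorted(avoid_by_chrom.get(rec.id, ())):
                    if s < cand < e:
                        cand = e
                if cand >= n - min_len:
                    break
                bps.append(cand)
                pos = cand
        bounds = [0, *bps, n]
        for s, e in zip(bounds, bounds[1:]):
            pieces.append((rec.id, s, e))

    order = rng.permutation(len(pieces))
    by_id = {r.id: r for r in genome}
    contigs: list[SequenceRecord] = []
    provenance: dict[str, tuple[str, int, int, str]] = {}
    width = max(5, len(str(len(pieces))))
    for rank, idx in enumerate(order, start=1):
        chrom, s, e = pieces[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = by_id[chrom].sequence[s:e]
        if strand == "-":
            seq = reverse_complement(seq)
        cid = f"ctg_{rank:0{width}d}"
        contigs.append(SequenceRecord(cid, seq))
        provenance[cid] = (chrom, s, e, strand)
    if truth is not None:
        truth.contig_provenance = provenance
    return contigs, provenance


def _apply_errors(
    rng: np.random.Generator, seq: str, sub: float, ins: float, dele: float
) -> tuple[str, int]:
    """i.i.d. per-base substitutions/insertions/deletions; returns (seq, n)."""
    if sub == ins == dele == 0:
        return seq, 0
    n = len(seq)
    r = rng.random(n)
    hit = np.flatnonzero(r < sub + ins + dele)
    if len(hit) == 0:
        return seq, 0
    bases = "ACGT"
    out: list[str] = []
    prev = 0
    for p in hit:
        out.append(seq[prev:p])
        x = r[p]
        if x < sub:
            cur = seq[p]
            repl = bases[int(rng.integers(4))]
            while repl == cur:
                repl = bases[int(rng.integers(4))]
            out.append(repl)
            prev = p + 1
        elif x < sub + ins:
            out.append(bases[int(rng.integers(4))] + seq[p])
            prev = p + 1
        else:  # deletion
            prev = p + 1
    out.append(seq[prev:])
    return "".join(out), int(len(hit))


def simulate_reads(
    genome: Sequence[SequenceRecord],
    coverage: float,
    mean_length: int = 10_000,
    length_sd: int = 1_000,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    seed: int = 0,
    min_length: int = 500,
    truth: SyntheticTruth | None = None,
) -> tuple[list[SequenceRecord], dict[str, tuple[str, int, int, str, int]]]:
    """Noisy long reads with recorded origins.

    Read count is Poisson(coverage x genome_length / mean_length); start
    positions are uniform, lengths normal (clipped to [min_length,
    chromosome end]), ~50% of reads reverse-complemented, errors i.i.d.
    per base at the stated rates.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not 0 <= rate <= 0.2:
            raise ValueError("error rates must be in [0, 0.2]")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    total = sum(len(r.sequence) for r in genome)
    n_reads = int(rng.poisson(coverage * total / mean_length))
    weights = np.array([len(r.sequence) for r in genome], dtype=float)
    weights /= weights.sum()
    reads: list[SequenceRecord] = []
    provenance: dict[str, tuple[str, int, int, str, int]] = {}
    width = max(6, len(str(n_reads)))
    for i in range(1, n_reads + 1):
        src = genome[int(rng.choice(len(genome), p=weights))]
        n = len(src.sequence)
        length = int(np.clip(rng.normal(mean_length, length_sd), min_length, n))
        start = int(rng.integers(0, max(1, n - length + 1)))
        end = min(n, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        raw = src.sequence[start:end]
        if strand == "-":
            raw = reverse_complement(raw)
        seq, nerr = _apply_errors(rng, raw, sub_rate, ins_rate, del_rate)
        rid = f"read_{i:0{width}d}"
        reads.append(
            SequenceRecord(rid, seq, f"origin={src.id}:{start}-{end}:{strand}")
        )
        provenance[rid] = (src.id, start, end, strand, nerr)
    if truth is not None:
        truth.read_provenance = provenance
    return reads, provenance


def truth_alignments(
    contig_provenance: Mapping[str, tuple[str, int, int, str]],
    segment_maps: Mapping[str, list[Segment]],
    ref_lengths: Mapping[str, int],
) -> list[PafAlignment]:
    """Exact contig-to-reference PAF derived from provenance and the planted
    coordinate maps.

    One record per maximal collinear piece; a contig spanning an inversion
    boundary yields records of opposite strand; all records carry mapq 60
    and matches equal to the piece length.
    """
    out: list[PafAlignment] = []
    # prefix sums of sample offsets per chromosome
    offsets: dict[str, list[int]] = {}
    for chrom, segs in segment_maps.items():
        acc = [0]
        for s in segs:
            acc.append(acc[-1] + s.length)
        offsets[chrom] = acc

    for cid in sorted(contig_provenance):
        chrom, a, b, ori = contig_provenance[cid]
        if chrom not in segment_maps:
            raise KeyError(f"provenance references unknown chromosome {chrom!r}")
        segs = segment_maps[chrom]
        acc = offsets[chrom]
        qlen = b - a
        records: list[PafAlignment] = []
        for i, seg in enumerate(segs):
            ss, se = acc[i], acc[i + 1]
            s, e = max(a, ss), min(b, se)
            if s >= e:
                continue
            if seg.strand == "+":
                rs = seg.ref_start + (s - ss)
                re_ = rs + (e - s)
            else:
                re_ = seg.ref_end - (s - ss)
                rs = re_ - (e - s)
            if ori == "+":
                qs, qe = s - a, e - a
            else:
                qs, qe = b - e, b - s
            strand = "+" if ori == seg.strand else "-"
            records.append(
                PafAlignment(
                    cid, qlen, qs, qe, strand, seg.ref_name,
                    ref_lengths[seg.ref_name], rs, re_, e - s, e - s, 60,
                )
            )
        records.sort(key=lambda r: r.query_start)
        out.extend(_merge_collinear(records))
    return out


def _merge_collinear(records: list[PafAlignment]) -> list[PafAlignment]:
    merged: list[PafAlignment] = []
    for r in records:
        if merged:
            p = merged[-1]
            abut_ref = (
                r.target_start == p.target_end
                if r.strand == "+"
                else r.target_end == p.target_start
            )
            if (
                r.target_name == p.target_name
                and r.strand == p.strand
                and r.query_start == p.query_end
                and abut_ref
            ):
                merged[-1] = PafAlignment(
                    p.query_name, p.query_length, p.query_start, r.query_end,
                    p.strand, p.target_name, p.target_length,
                    min(p.target_start, r.target_start),
                    max(p.target_end, r.target_end),
                    p.matches + r.matches, p.block_length + r.block_length, 60,
                )
                continue
        merged.append(r)
    return merged


def reads_truth_paf(
    read_provenance: Mapping[str, tuple[str, int, int, str, int]],
    read_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
) -> list[PafAlignment]:
    """Exact read-to-source PAF from read provenance (indel-agnostic: the
    whole read maps to its origin interval)."""
    out: list[PafAlignment] = []
    for rid in sorted(read_provenance):
        src, s, e, strand, _nerr = read_provenance[rid]
        qlen = read_lengths[rid]
        span = e - s
        out.append(
            PafAlignment(
                rid, qlen, 0, qlen, strand, src, target_lengths[src], s, e,
                min(qlen, span), max(qlen, span), 60,
            )
        )
    return out
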