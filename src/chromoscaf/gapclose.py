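"""Gap closing: window extraction, pseudo-reads, local assembly, stitching.

Around every scaffold gap (and every scaffold terminus) a window of reads
is extracted and locally re-assembled; the resulting patch contigs — or,
failing that, a direct end-overlap of the two flanking contigs — are used
to replace the gap with real sequence.  Contigs that exceed an assembler's
read-length cap can be chunked into overlapping pseudo-reads first.

The local assembler here is a greedy end-overlap assembler: it repeatedly
merges the pair of sequences (in either orientation) with the longest
suffix-prefix overlap passing an identity threshold, verified by edit-
distance alignment (edlib).  The interface is pluggable — any external
assembler's contigs can be passed to ``close_gaps`` as patches instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .io_formats import PafAlignment, SequenceRecord, reverse_complement
from .refscaffold import Scaffold, ScaffoldComponent, ScaffoldPlan

__all__ = [
    "GapWindow",
    "OverlapMerge",
    "GapReport",
    "extract_gap_windows",
    "chunk_pseudo_reads",
    "suffix_prefix_overlap",
    "greedy_overlap_assemble",
    "stitch_gap",
    "assemble_gap_patches",
    "close_gaps",
]

WTDBG2_READ_CAP = 256_000  # hard read-length limit of the target assembler


@dataclass
class GapWindow:
    """Reads overlapping a window around one scaffold gap or terminus."""

    gap_id: str
    scaffold_id: str
    window_start: int
    window_end: int
    read_ids: set[str] = field(default_factory=set)


@dataclass
class OverlapMerge:
    """An accepted suffix-prefix overlap between two oriented sequences."""

    left_id: str
    right_id: str
    overlap_length: int
    identity: float
    merged_length: int


@dataclass
class GapReport:
    gap_id: str
    outcome: str  # patched | stitched | open
    overlap_left: int = 0
    overlap_right: int = 0
    identity: float = 0.0
    inserted_bases: int = 0


def extract_gap_windows(
    plan: ScaffoldPlan,
    read_alignments: Iterable[PafAlignment],
    window: int = 20_000,
) -> list[GapWindow]:
    """One window per plan gap (gap +/- ``window``) plus two terminal
    windows per scaffold; a read joins a window if any of its alignments to
    that scaffold overlaps it by >= 1 base.  A read may appear in several
    windows (windows are independent re-assembly jobs).
    """
    by_target: dict[str, list[PafAlignment]] = {}
    for a in read_alignments:
        by_target.setdefault(a.target_name, []).append(a)

    windows: list[GapWindow] = []
    for scaf in plan.scaffolds:
        slen = plan.scaffold_length(scaf)
        pos = 0
        gap_coords: list[tuple[int, int]] = []
        for i, comp in enumerate(scaf.components):
            pos += plan.contig_lengths[comp.contig_id]
            if i < len(scaf.gaps):
                gap_coords.append((pos, pos + scaf.gaps[i]))
                pos += scaf.gaps[i]
        for j, (gs, ge) in enumerate(gap_coords):
            windows.append(
                GapWindow(
                    f"{scaf.scaffold_id}.gap{j}", scaf.scaffold_id,
                    max(0, gs - window), min(slen, ge + window),
                )
            )
        windows.append(
            GapWindow(f"{scaf.scaffold_id}.start", scaf.scaffold_id, 0, min(window, slen))
        )
        windows.append(
            GapWindow(
                f"{scaf.scaffold_id}.end", scaf.scaffold_id, max(0, slen - window), slen
            )
        )
    for w in windows:
        for a in by_target.get(w.scaffold_id, ()):
            if a.target_start < w.window_end and a.target_end > w.window_start:
                w.read_ids.add(a.query_name)
    return windows


def chunk_pseudo_reads(
    contig: SequenceRecord, chunk_length: int = 250_000, step: int = 200_000
) -> list[SequenceRecord]:
    """Tile a contig into overlapping chunks no longer than the assembler's
    read cap; chunk ids encode the origin contig and offset."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if chunk_length > WTDBG2_READ_CAP:
        raise ValueError(f"chunk_length must be <= {WTDBG2_READ_CAP}")
    if step > chunk_length:
        raise ValueError("step must be <= chunk_length")
    n = len(contig.sequence)
    chunks: list[SequenceRecord] = []
    s = 0
    while True:
        e = min(s + chunk_length, n)
        chunks.append(
            SequenceRecord(
                f"{contig.id}:{s}-{e}", contig.sequence[s:e],
                f"pseudo_read origin={contig.id} offset={s}",
            )
        )
        if e >= n:
            break
        s += step
    return chunks


def _identity_nw(a: str, b: str, min_identity: float) -> float:
    # bound the search: distances beyond the acceptance threshold are useless
    aln_len = max(len(a), len(b))
    max_dist = int(aln_len * (1.0 - min_identity)) + 1
    res = edlib.align(a, b, task="distance", mode="NW", k=max_dist)
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return 1.0 - dist / aln_len if aln_len else 0.0


def suffix_prefix_overlap(
    left: str,
    right: str,
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    max_search: int = 100_000,
    kmer: int = 15,
) -> tuple[int, float] | None:
    """Longest acceptable overlap of ``left``'s suffix with ``right``'s
    prefix, or None.

    Candidate overlap lengths are voted by shared k-mers between the last
    ``max_search`` bases of left and the first ``max_search`` bases of
    right (a k-mer match at left position p and right position q implies an
    overlap of ``len(left) - p + q``); candidates are verified longest-
    first by global edit-distance alignment of the two putative overlap
    regions.  Returns (overlap_length, identity).
    """
    la, lb = len(left), len(right)
    cap = min(la, lb, max_search)
    if cap < min_overlap:
        return None
    ta = left[-cap:]
    tb = right[:cap]
    index: dict[str, list[int]] = {}
    for p in range(len(ta) - kmer + 1):
        index.setdefault(ta[p : p + kmer], []).append(p)
    votes: Counter[int] = Counter()
    for q in range(len(tb) - kmer + 1):
        for p in index.get(tb[q : q + kmer], ()):
            ov = (len(ta) - p) + q
            if min_overlap <= ov <= cap:
                votes[ov] += 1
    if not votes:
        return None
    # demand >= 3 supporting k-mers unless the overlap is too short to hold them
    candidates = sorted(
        (ov for ov, v in votes.items() if v >= min(3, max(1, ov - kmer + 1))),
        reverse=True,
    )
    if not candidates:
        candidates = sorted(votes, reverse=True)
    for ov in candidates[:25]:
        ident = _identity_nw(left[-ov:], right[:ov], min_identity)
        if ident >= min_identity:
            return ov, ident
    # fall back to the best-supported candidate if the longest ones failed
    best = max(votes, key=lambda ov: (votes[ov], ov))
    ident = _identity_nw(left[-best:], right[:best], min_identity)
    if ident >= min_identity:
        return best, ident
    return None


def _contained(inner: str, outer: str, min_identity: float) -> bool:
    if len(inner) > len(outer):
        return False
    max_dist = int(len(inner) * (1.0 - min_identity)) + 1
    res = edlib.align(inner, outer, task="distance", mode="HW", k=max_dist)
    dist = res["editDistance"]
    return dist >= 0 and 1.0 - dist / len(inner) >= min_identity


def greedy_overlap_assemble(
    sequences: Iterable[SequenceRecord],
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    kmer: int = 15,
    max_search: int = 100_000,
) -> list[SequenceRecord]:
    """Greedy overlap-layout assembly of a small sequence set.

    Sequences fully contained in another (either orientation) are absorbed
    first.  Then the pair with the longest acceptable end-overlap — in any
    relative orientation — is merged (ties: identity descending, then
    lexicographic ids), until no merge qualifies.  Every input base ends up
    in exactly one output contig.
    """
    pool: dict[str, SequenceRecord] = {r.id: r for r in sequences}

    def absorb_contained() -> None:
        ids = sorted(pool, key=lambda i: (len(pool[i].sequence), i))
        for small in ids:
            if small not in pool:
                continue
            s = pool[small].sequence
            for big in sorted(pool, key=lambda i: (-len(pool[i].sequence), i)):
                if big == small or len(pool[big].sequence) < len(s):
                    continue
                t = pool[big].sequence
                if _contained(s, t, min_identity) or _contained(
                    reverse_complement(s), t, min_identity
                ):
                    del pool[small]
                    break

    absorb_contained()
    while len(pool) > 1:
        best: tuple[int, float, str, str, str, str] | None = None
        ids = sorted(pool)
        for lid in ids:
            for rid in ids:
                if lid == rid:
                    continue
                for lori, rori in (("+", "+"), ("+", "-"), ("-", "+")):
                    ls = pool[lid].sequence
                    rs = pool[rid].sequence
                    if lori == "-":
                        ls = reverse_complement(ls)
                    if rori == "-":
                        rs = reverse_complement(rs)
                    hit = suffix_prefix_overlap(
                        ls, rs, min_overlap, min_identity, max_search, kmer
                    )
                    if hit is None:
                        continue
                    ov, ident = hit
                    key = (ov, ident, lid, rid, lori, rori)
                    if best is None or (ov, ident) > (best[0], best[1]) or (
                        (ov, ident) == (best[0], best[1])
                        and (lid, rid) < (best[2], best[3])
                    ):
                        best = key
        if best is None:
            break
        ov, ident, lid, rid, lori, rori = best
        ls = pool[lid].sequence if lori == "+" else reverse_complement(pool[lid].sequence)
        rs = pool[rid].sequence if rori == "+" else reverse_complement(pool[rid].sequence)
        merged = SequenceRecord(f"{lid}|{rid}", ls + rs[ov:])
        del pool[lid]
        del pool[rid]
        pool[merged.id] = merged
        absorb_contained()
    return [pool[i] for i in sorted(pool)]


def stitch_gap(
    left: SequenceRecord,
    right: SequenceRecord,
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    max_search: int = 100_000,
    kmer: int = 15,
) -> OverlapMerge | None:
    """Close one gap by direct overlap of the two oriented flanks.

    ``left``'s 3' end is searched against ``right``'s 5' end; the longest
    suffix-prefix alignment of length >= ``min_overlap`` and identity >=
    ``min_identity`` is accepted.  Junction bases come from the left flank.
    """
    hit = suffix_prefix_overlap(
        left.sequence, right.sequence, min_overlap, min_identity, max_search, kmer
    )
    if hit is None:
        return None
    ov, ident = hit
    return OverlapMerge(
        left.id, right.id, ov, ident,
        len(left.sequence) + len(right.sequence) - ov,
    )


def assemble_gap_patches(
    windows: Iterable[GapWindow],
    reads: Mapping[str, SequenceRecord],
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    kmer: int = 15,
) -> dict[str, list[SequenceRecord]]:
    """Locally assemble each window's reads into candidate patch contigs."""
    patches: dict[str, list[SequenceRecord]] = {}
    for w in windows:
        seqs = [reads[rid] for rid in sorted(w.read_ids) if rid in reads]
        if not seqs:
            continue
        patches[w.gap_id] = greedy_overlap_assemble(
            seqs, min_overlap=min_overlap, min_identity=min_identity, kmer=kmer
        )
    return patches


def close_gaps(
    plan: ScaffoldPlan,
    contigs: Iterable[SequenceRecord],
    patches: Mapping[str, Sequence[SequenceRecord]] | Sequence[SequenceRecord] | None = None,
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    max_search: int = 100_000,
) -> tuple[ScaffoldPlan, list[SequenceRecord], list[GapReport]]:
    """Close scaffold gaps by patch-mediated joins, then direct stitches.

    For every gap, a patch contig spanning both flanks (overlapping each by
    >= ``min_overlap`` at >= ``min_identity``) replaces the gap with its
    inter-flank sequence; otherwise a direct flank-to-flank stitch is
    attempted.  Returns the updated plan, the new component sequences
    (merged components get joined ids, orientation "+"), and a per-gap
    report.  Re-running on the output closes nothing further.
    """
    by_id = {c.id: c for c in contigs}
    patch_lookup: Mapping[str, Sequence[SequenceRecord]] | None
    flat_patches: Sequence[SequenceRecord]
    if patches is None:
        patch_lookup, flat_patches = None, ()
    elif isinstance(patches, Mapping):
        patch_lookup, flat_patches = patches, ()
    else:
        patch_lookup, flat_patches = None, list(patches)

    new_scaffolds: list[Scaffold] = []
    new_records: dict[str, SequenceRecord] = {}
    reports: list[GapReport] = []
    new_lengths: dict[str, int] = {}

    for scaf in plan.scaffolds:
        comps = scaf.components

        def oriented(comp: ScaffoldComponent) -> str:
            seq = by_id[comp.contig_id].sequence
            return reverse_complement(seq) if comp.orientation == "-" else seq

        work_id = comps[0].contig_id
        work_seq = oriented(comps[0])
        work_merged = False
        out_components: list[ScaffoldComponent] = []
        out_gaps: list[int] = []

        for j in range(len(scaf.gaps)):
            gap_id = f"{scaf.scaffold_id}.gap{j}"
            right_comp = comps[j + 1]
            right_seq = oriented(right_comp)
            report = GapReport(gap_id, "open")

            candidates = (
                list(patch_lookup.get(gap_id, ())) if patch_lookup is not None
                else list(flat_patches)
            )
            for patch in candidates:
                for pseq in (patch.sequence, reverse_complement(patch.sequence)):
                    h1 = suffix_prefix_overlap(
                        work_seq, pseq, min_overlap, min_identity, max_search
                    )
                    if h1 is None:
                        continue
                    h2 = suffix_prefix_overlap(
                        pseq, right_seq, min_overlap, min_identity, max_search
                    )
                    if h2 is None:
                        continue
                    ov1, id1 = h1
                    ov2, id2 = h2
                    if ov1 + ov2 > len(pseq):
                        continue  # patch does not span beyond the flanks
                    insert = pseq[ov1 : len(pseq) - ov2]
                    work_seq = work_seq + insert + right_seq
                    report = GapReport(
                        gap_id, "patched", ov1, ov2, min(id1, id2), len(insert)
                    )
                    break
                if report.outcome == "patched":
                    break

            if report.outcome == "open":
                merge = stitch_gap(
                    SequenceRecord(work_id, work_seq),
                    SequenceRecord(right_comp.contig_id, right_seq),
                    min_overlap, min_identity, max_search,
                )
                if merge is not None:
                    work_seq = work_seq + right_seq[merge.overlap_length :]
                    report = GapReport(
                        gap_id, "stitched", merge.overlap_length,
                        merge.overlap_length, merge.identity, 0,
                    )

            if report.outcome == "open":
                out_components.append(ScaffoldComponent(work_id, "+" if work_merged else comps_orientation(comps, work_id)))
                out_gaps.append(scaf.gaps[j])
                finalize_record(new_records, new_lengths, work_id, work_seq, work_merged, by_id)
                work_id = right_comp.contig_id
                work_seq = right_seq
                work_merged = False
            else:
                work_id = f"{work_id}|{right_comp.contig_id}"
                work_merged = True
            reports.append(report)

        out_components.append(ScaffoldComponent(work_id, "+" if work_merged else comps_orientation(comps, work_id)))
        finalize_record(new_records, new_lengths, work_id, work_seq, work_merged, by_id)
        new_scaffolds.append(Scaffold(scaf.scaffold_id, out_components, out_gaps))

    for cid in plan.unplaced:
        if cid in by_id:
            new_records[cid] = by_id[cid]
            new_lengths[cid] = len(by_id[cid].sequence)
    new_plan = ScaffoldPlan(new_scaffolds, list(plan.unplaced), new_lengths)
    return new_plan, list(new_records.values()), reports


def comps_orientation(comps: Sequence[ScaffoldComponent], contig_id: str) -> str:
    for c in comps:
        if c.contig_id == contig_id:
            return c.orientation
    return "+"


def finalize_record(
    records: dict[str, SequenceRecord],
    lengths: dict[str, int],
    work_id: str,
    work_seq: str,
    merged: bool,
    by_id: Mapping[str, SequenceRecord],
) -> None:
    if merged:
        records[work_id] = SequenceRecord(work_id, work_seq)
    else:
        records[work_id] = by_id[work_id]
    lengths[work_id] = len(records[work_id].sequence)
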