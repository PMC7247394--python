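"""Contig curation: coverage-based splitting, dual-assembly reconciliation
and partial-mapping read rescue.

This is the first stage of the pipeline.  Two independently produced draft
assemblies rarely make the same misjoin, so an assembly-vs-assembly
alignment gap pinpoints suspect junctions (``reconcile_assemblies``).
Re-mapping the long reads — and 500 bp end-pairs of the reads, which add
span evidence across repeats — exposes regions no read supports
(``find_zero_coverage_splits``).  Reads that barely map at all (<10 % of
their length by default) are flagged for re-assembly rescue
(``classify_partially_mapped_reads``).  Splits are materialized by
``apply_splits``, which conserves every base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import BedInterval, PafAlignment, SequenceRecord

__all__ = [
    "CoverageProfile",
    "SplitPoint",
    "coverage_from_alignments",
    "combine_profiles",
    "make_read_end_pairs",
    "find_zero_coverage_splits",
    "classify_partially_mapped_reads",
    "reconcile_assemblies",
    "apply_splits",
]


@dataclass
class CoverageProfile:
    """Per-base read depth over one contig."""

    contig_id: str
    depth: np.ndarray  # non-negative int32, length == contig length

    @property
    def contig_length(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class SplitPoint:
    """A cut before ``position`` on a contig; never at the ends."""

    contig_id: str
    position: int
    reason: str  # reconciliation | zero_coverage | scaffold_conflict


def coverage_from_alignments(
    alignments: Iterable[PafAlignment],
    contig_lengths: Mapping[str, int],
    min_mapq: int = 0,
) -> dict[str, CoverageProfile]:
    """Per-base depth on each contig from read-to-contig alignments.

    Alignments with ``mapq < min_mapq`` are ignored.  Depth at position p is
    the number of retained alignments whose target interval contains p.
    Every contig in ``contig_lengths`` gets a profile (possibly all-zero).
    """
    diffs = {
        cid: np.zeros(length + 1, dtype=np.int32)
        for cid, length in contig_lengths.items()
    }
    for a in alignments:
        if a.mapq != 255 and a.mapq < min_mapq:
            continue
        if a.target_name not in diffs:
            raise KeyError(f"alignment targets unknown contig {a.target_name!r}")
        if a.target_end > contig_lengths[a.target_name]:
            raise ValueError(
                f"alignment end {a.target_end} exceeds declared length of "
                f"{a.target_name}"
            )
        d = diffs[a.target_name]
        d[a.target_start] += 1
        d[a.target_end] -= 1
    return {
        cid: CoverageProfile(cid, np.cumsum(d[:-1], dtype=np.int32))
        for cid, d in diffs.items()
    }


def combine_profiles(*profile_sets: Mapping[str, CoverageProfile]) -> dict[str, CoverageProfile]:
    """Sum depth across profile sets (e.g. raw reads + end-pairs) per contig."""
    out: dict[str, CoverageProfile] = {}
    for pset in profile_sets:
        for cid, prof in pset.items():
            if cid in out:
                out[cid] = CoverageProfile(cid, out[cid].depth + prof.depth)
            else:
                out[cid] = CoverageProfile(cid, prof.depth.copy())
    return out


def make_read_end_pairs(
    reads: Iterable[SequenceRecord], end_length: int = 500
) -> tuple[list[SequenceRecord], int]:
    """Extract the two terminal ``end_length``-base windows of each read.

    Emits ``<read>/1`` (first ``end_length`` bases) and ``<read>/2`` (last
    ``end_length`` bases), both forward-stranded, with the origin offset in
    the description.  Reads shorter than ``2 * end_length`` are skipped.

    Returns (pairs, number_of_skipped_reads).
    """
    if end_length < 1:
        raise ValueError("end_length must be >= 1")
    pairs: list[SequenceRecord] = []
    skipped = 0
    for read in reads:
        n = len(read.sequence)
        if n < 2 * end_length:
            skipped += 1
            continue
        pairs.append(
            SequenceRecord(
                f"{read.id}/1",
                read.sequence[:end_length],
                f"origin={read.id}:0-{end_length}:+",
            )
        )
        pairs.append(
            SequenceRecord(
                f"{read.id}/2",
                read.sequence[n - end_length :],
                f"origin={read.id}:{n - end_length}-{n}:+",
            )
        )
    return pairs, skipped


def _zero_runs(depth: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero depth as half-open intervals."""
    iszero = depth == 0
    if not iszero.any():
        return []
    padded = np.concatenate(([False], iszero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def find_zero_coverage_splits(
    profiles: Mapping[str, CoverageProfile],
    min_zero_run: int = 1,
    end_trim: int = 0,
) -> tuple[list[SplitPoint], list[BedInterval]]:
    """Split points at internal zero-coverage runs; end runs become trims.

    A maximal zero-depth run of length >= ``min_zero_run`` that does not
    reach within ``end_trim`` bases of either contig end yields one split at
    its midpoint (floor).  Runs touching an end are reported as trim
    intervals instead — splitting there would only shave unsupported
    termini, not fix a join.
    """
    splits: list[SplitPoint] = []
    trims: list[BedInterval] = []
    for cid in sorted(profiles):
        prof = profiles[cid]
        n = prof.contig_length
        for start, end in _zero_runs(prof.depth):
            touches_end = start <= end_trim or end >= n - end_trim
            if touches_end:
                trims.append(BedInterval(cid, start, end, "zero_coverage_trim"))
            elif end - start >= min_zero_run:
                splits.append(SplitPoint(cid, (start + end) // 2, "zero_coverage"))
    return splits, trims


def classify_partially_mapped_reads(
    alignments: Iterable[PafAlignment],
    read_lengths: Mapping[str, int],
    max_mapped_fraction: float = 0.10,
) -> set[str]:
    """Read ids whose mapped fraction is strictly below the threshold.

    Mapped fraction = |union of query intervals across all alignments| /
    read length.  Completely unmapped reads (no alignments) are rescued.
    A read mapping exactly at the threshold is NOT rescued.
    """
    intervals: dict[str, list[tuple[int, int]]] = {rid: [] for rid in read_lengths}
    for a in alignments:
        if a.query_name not in intervals:
            raise KeyError(f"alignment for unknown read {a.query_name!r}")
        intervals[a.query_name].append((a.query_start, a.query_end))
    rescued: set[str] = set()
    for rid, ivs in intervals.items():
        covered = _union_length(ivs)
        if covered / read_lengths[rid] < max_mapped_fraction:
            rescued.add(rid)
    return rescued


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def reconcile_assemblies(
    alignments_a_on_b: Iterable[PafAlignment],
    contig_lengths_a: Mapping[str, int],
    coverage_tolerance: int = 100,
) -> list[SplitPoint]:
    """Split A-contigs where the companion assembly B fails to cover them.

    Coverage is partner-agnostic: alignments to any B-contig count, and
    gaps <= ``coverage_tolerance`` between successive covered intervals are
    bridged.  Each remaining internal uncovered run longer than the
    tolerance yields one split at its midpoint.  Uncovered contig ends are
    not discrepancies (alignment end effects).
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for a in alignments_a_on_b:
        if a.query_name not in contig_lengths_a:
            raise KeyError(f"alignment for unknown contig {a.query_name!r}")
        by_contig.setdefault(a.query_name, []).append((a.query_start, a.query_end))
    splits: list[SplitPoint] = []
    for cid in sorted(by_contig):
        ivs = sorted(by_contig[cid])
        merged: list[tuple[int, int]] = [ivs[0]]
        for s, e in ivs[1:]:
            ps, pe = merged[-1]
            if s - pe <= coverage_tolerance:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            # internal by construction: gap > tolerance between covered blocks
            splits.append(SplitPoint(cid, (e1 + s2) // 2, "reconciliation"))
    return splits


def apply_splits(
    records: Iterable[SequenceRecord], splits: Iterable[SplitPoint]
) -> list[SequenceRecord]:
    """Cut contigs at the given positions, naming fragments ``<id>.1`` ...

    Fragment concatenation equals the original sequence (base conservation).
    Contigs without splits pass through unchanged under their original id.
    """
    by_contig: dict[str, list[int]] = {}
    records = list(records)
    known = {r.id for r in records}
    for sp in splits:
        if sp.contig_id not in known:
            raise KeyError(f"split for unknown contig {sp.contig_id!r}")
        by_contig.setdefault(sp.contig_id, []).append(sp.position)
    out: list[SequenceRecord] = []
    for rec in records:
        positions = sorted(set(by_contig.get(rec.id, ())))
        if not positions:
            out.append(rec)
            continue
        n = len(rec.sequence)
        for p in positions:
            if not (0 < p < n):
                raise ValueError(
                    f"split position {p} outside contig {rec.id} of length {n}"
                )
        bounds = [0, *positions, n]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            out.append(SequenceRecord(f"{rec.id}.{i}", rec.sequence[s:e]))
    return out
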