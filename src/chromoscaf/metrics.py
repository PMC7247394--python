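"""Assembly statistics: Nxx, ungapped length, top-n completeness.

The top-n fraction — the share of assembled (non-N) bases held by the n
largest scaffolds, with n the haploid chromosome number — measures how much
of an assembly has reached chromosome scale.  Contig-level metrics are
derived by splitting scaffolds at N runs of at least ``min_gap_run`` bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "AssemblyMetrics",
    "nxx",
    "ungapped_length",
    "top_n_fraction",
    "split_at_gaps",
    "assembly_report",
]


@dataclass
class AssemblyMetrics:
    n_sequences: int
    total_length: int
    ungapped_length: int
    n50: int
    l50: int
    contig_count: int
    contig_n50: int
    top_n: int
    top_n_fraction: float
    gap_count: int
    gap_bases: int

    def to_tsv(self) -> str:
        pairs = [
            ("n_sequences", self.n_sequences),
            ("total_length", self.total_length),
            ("ungapped_length", self.ungapped_length),
            ("n50", self.n50),
            ("l50", self.l50),
            ("contig_count", self.contig_count),
            ("contig_n50", self.contig_n50),
            ("top_n", self.top_n),
            ("top_n_fraction", f"{self.top_n_fraction:.6f}"),
            ("gap_count", self.gap_count),
            ("gap_bases", self.gap_bases),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in pairs) + "\n"


def nxx(lengths: Iterable[int], x: float = 50) -> int:
    """Smallest length L such that sequences >= L sum to >= x% of the total."""
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("nxx of an empty length collection")
    if any(l < 1 for l in lens):
        raise ValueError("all lengths must be >= 1")
    threshold = sum(lens) * x / 100.0
    acc = 0
    for l in lens:
        acc += l
        if acc >= threshold:
            return l
    return lens[-1]


def ungapped_length(seq: SequenceRecord | str) -> int:
    """Number of non-N bases."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    return len(s) - s.count("N")


def top_n_fraction(ungapped_lengths: Sequence[int], n: int) -> float:
    """Share of total (ungapped) bases in the n largest sequences."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    if not ungapped_lengths:
        raise ValueError("empty length collection with n > 0")
    lens = sorted(ungapped_lengths, reverse=True)
    total = sum(lens)
    if total == 0:
        return 0.0
    return sum(lens[:n]) / total


def split_at_gaps(records: Iterable[SequenceRecord], min_gap_run: int = 10) -> list[SequenceRecord]:
    """Break scaffolds into contigs at N runs of >= ``min_gap_run`` bases."""
    pattern = re.compile(f"N{{{min_gap_run},}}")
    out: list[SequenceRecord] = []
    for rec in records:
        pieces = [p for p in pattern.split(rec.sequence) if p]
        if len(pieces) <= 1:
            out.append(SequenceRecord(rec.id, pieces[0] if pieces else rec.sequence))
        else:
            for i, p in enumerate(pieces, start=1):
                out.append(SequenceRecord(f"{rec.id}_ctg{i}", p))
    return out


def assembly_report(
    records: Sequence[SequenceRecord], n: int, min_gap_run: int = 10
) -> AssemblyMetrics:
    """All headline statistics for a scaffold (or contig) set."""
    if not records:
        raise ValueError("assembly_report of an empty collection")
    lens = sorted((len(r.sequence) for r in records), reverse=True)
    total = sum(lens)
    un_lens = [ungapped_length(r) for r in records]
    n50 = nxx(lens, 50)
    acc = 0
    l50 = 0
    for l in lens:
        acc += l
        l50 += 1
        if acc >= total / 2:
            break
    contigs = split_at_gaps(records, min_gap_run)
    gap_pattern = re.compile(f"N{{{min_gap_run},}}")
    gap_count = 0
    gap_bases = 0
    for rec in records:
        for m in gap_pattern.finditer(rec.sequence):
            gap_count += 1
            gap_bases += m.end() - m.start()
    return AssemblyMetrics(
        n_sequences=len(records),
        total_length=total,
        ungapped_length=sum(un_lens),
        n50=n50,
        l50=l50,
        contig_count=len(contigs),
        contig_n50=nxx([len(c.sequence) for c in contigs], 50),
        top_n=n,
        top_n_fraction=top_n_fraction(un_lens, n),
        gap_count=gap_count,
        gap_bases=gap_bases,
    )
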