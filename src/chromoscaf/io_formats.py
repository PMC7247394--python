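"""Readers and writers for the standard formats the pipeline touches.

Dialect rules, fixed once for the whole package:

* FASTA — multi-record, wrapped at a configurable width.  Sequences are
  uppercase-normalized on input; any character outside ``{A,C,G,T,N}`` is
  replaced by ``N`` and counted (length is always conserved).
* PAF — 12 mandatory tab-separated columns, 0-based half-open coordinates;
  optional columns from 13 onward are preserved verbatim as opaque strings.
* AGP — version 2.1, 1-based inclusive coordinates, component (``W``) and
  gap (``N``) rows tiling each scaffold without holes.
* BED — BED3 plus one free-text label column, 0-based half-open.

Plain and gzip-compressed files are both accepted, sniffed by extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SequenceRecord",
    "PafAlignment",
    "AgpRow",
    "BedInterval",
    "reverse_complement",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_agp",
    "write_agp",
    "read_bed",
    "write_bed",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and replace non-ACGTN characters by N.

    Returns the normalized sequence and the number of replaced characters.
    Length is conserved — bases are never dropped.
    """
    up = seq.upper()
    if set(up) <= _ALLOWED:
        return up, 0
    replaced = sum(1 for c in up if c not in _ALLOWED)
    norm = "".join(c if c in _ALLOWED else "N" for c in up)
    return norm, replaced


@dataclass
class SequenceRecord:
    """A named nucleotide sequence: contig, read, scaffold or pseudo-read."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.sequence), self.description)


@dataclass
class PafAlignment:
    """One pairwise alignment record with PAF semantics (0-based half-open)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    block_length: int
    mapq: int
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"invalid query interval [{self.query_start},{self.query_end}) "
                f"for {self.query_name} of length {self.query_length}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise ValueError(
                f"invalid target interval [{self.target_start},{self.target_end}) "
                f"for {self.target_name} of length {self.target_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.matches > self.block_length:
            raise ValueError("matches cannot exceed block_length")
        if not (0 <= self.mapq <= 60 or self.mapq == 255):
            raise ValueError(f"mapq must be in 0..60 or 255, got {self.mapq}")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class AgpRow:
    """One AGP v2.1 row (1-based inclusive scaffold coordinates)."""

    scaffold_id: str
    scaffold_start: int
    scaffold_end: int
    part_number: int
    component_type: str  # "W" (contig) or "N" (gap)
    # W fields
    component_id: str = ""
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N fields
    gap_length: int = 0
    gap_type: str = "scaffold"

    def __post_init__(self) -> None:
        if self.component_type not in ("W", "N"):
            raise ValueError(f"component_type must be W or N, got {self.component_type!r}")
        span = self.scaffold_end - self.scaffold_start + 1
        if span < 1:
            raise ValueError("scaffold_end must be >= scaffold_start")
        if self.component_type == "W":
            if span != self.component_end - self.component_start + 1:
                raise ValueError("W-row scaffold span must equal component span")
            if self.orientation not in ("+", "-"):
                raise ValueError("orientation must be + or -")
        else:
            if span != self.gap_length:
                raise ValueError("N-row scaffold span must equal gap_length")


@dataclass
class BedInterval:
    """A labelled half-open interval on a named sequence."""

    name: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    The record id is the first whitespace-delimited header token; the rest of
    the header is kept as the description.  Sequences are normalized with
    :func:`normalize_sequence`; replaced-base counts are accumulated on the
    function attribute ``read_fasta.last_replaced`` for logging.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    replaced_total = 0
    with _open_text(path) as fh:
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            nonlocal replaced_total
            if header is None:
                return
            parts = header.split(None, 1)
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            seq = "".join(chunks)
            if not seq:
                raise ValueError(f"empty sequence for record {rec_id!r} in {path}")
            if rec_id in seen:
                raise ValueError(f"duplicate sequence id {rec_id!r} in {path}")
            seen.add(rec_id)
            norm, nrep = normalize_sequence(seq)
            replaced_total += nrep
            records.append(SequenceRecord(rec_id, norm, desc))

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"sequence data before first header in {path}")
                chunks.append(line.strip())
        flush()
    read_fasta.last_replaced = replaced_total  # type: ignore[attr-defined]
    return records


read_fasta.last_replaced = 0  # type: ignore[attr-defined]


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 80
) -> None:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_paf(path: str | Path) -> list[PafAlignment]:
    """Parse a (possibly gzipped) PAF file; fails loudly on malformed rows."""
    out: list[PafAlignment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: PAF line has {len(fields)} columns, need >= 12"
                )
            try:
                aln = PafAlignment(
                    query_name=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_name=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_length=int(fields[10]),
                    mapq=int(fields[11]),
                    tags=tuple(fields[12:]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(aln)
    return out


def write_paf(alignments: Iterable[PafAlignment], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for a in alignments:
            fields = [
                a.query_name,
                str(a.query_length),
                str(a.query_start),
                str(a.query_end),
                a.strand,
                a.target_name,
                str(a.target_length),
                str(a.target_start),
                str(a.target_end),
                str(a.matches),
                str(a.block_length),
                str(a.mapq),
                *a.tags,
            ]
            fh.write("\t".join(fields) + "\n")


_AGP_HEADER = "##agp-version\t2.1\n"


def write_agp(plan, path: str | Path) -> None:
    """Serialize a ScaffoldPlan (see ``refscaffold``) as AGP v2.1.

    Raises ``KeyError`` when a component's length is unknown to the plan.
    """
    rows = plan.to_agp_rows()
    with _open_text(path, "wt") as fh:
        fh.write(_AGP_HEADER)
        for r in rows:
            if r.component_type == "W":
                cols = [
                    r.scaffold_id,
                    str(r.scaffold_start),
                    str(r.scaffold_end),
                    str(r.part_number),
                    "W",
                    r.component_id,
                    str(r.component_start),
                    str(r.component_end),
                    r.orientation,
                ]
            else:
                cols = [
                    r.scaffold_id,
                    str(r.scaffold_start),
                    str(r.scaffold_end),
                    str(r.part_number),
                    "N",
                    str(r.gap_length),
                    r.gap_type,
                    "yes",
                    "align_genus",
                ]
            fh.write("\t".join(cols) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    """Parse AGP rows, validating tiling invariants per scaffold."""
    rows: list[AgpRow] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: AGP line has {len(f)} columns")
            ctype = f[4]
            try:
                if ctype == "W":
                    row = AgpRow(
                        scaffold_id=f[0],
                        scaffold_start=int(f[1]),
                        scaffold_end=int(f[2]),
                        part_number=int(f[3]),
                        component_type="W",
                        component_id=f[5],
                        component_start=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8],
                    )
                elif ctype in ("N", "U"):
                    row = AgpRow(
                        scaffold_id=f[0],
                        scaffold_start=int(f[1]),
                        scaffold_end=int(f[2]),
                        part_number=int(f[3]),
                        component_type="N",
                        gap_length=int(f[5]),
                        gap_type=f[6] if len(f) > 6 else "scaffold",
                    )
                else:
                    raise ValueError(f"unsupported component type {ctype!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    _check_agp_tiling(rows)
    return rows


def _check_agp_tiling(rows: Sequence[AgpRow]) -> None:
    by_scaf: dict[str, list[AgpRow]] = {}
    for r in rows:
        by_scaf.setdefault(r.scaffold_id, []).append(r)
    for scaf, srows in by_scaf.items():
        srows.sort(key=lambda r: r.part_number)
        pos = 1
        for i, r in enumerate(srows, start=1):
            if r.part_number != i:
                raise ValueError(f"{scaf}: part_numbers not consecutive from 1")
            if r.scaffold_start != pos:
                raise ValueError(
                    f"{scaf}: row {i} starts at {r.scaffold_start}, expected {pos}"
                )
            pos = r.scaffold_end + 1


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                BedInterval(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "")
            )
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.name}\t{iv.start}\t{iv.end}\t{iv.label}\n")
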