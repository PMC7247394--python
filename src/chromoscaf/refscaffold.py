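"""Reference-guided ordering and orienting of contigs into chromosome
scaffolds.

Contig-to-reference alignments (PAF, from any whole-genome aligner or from
the synthetic truth generator) are chained into anchor blocks.  Each contig
is assigned to the chromosome carrying most of its anchor weight, oriented
by the strand majority, and positioned at the weighted median of its anchor
midpoints.  Gaps between neighbours are estimated by projecting reference
distance, minus the unaligned contig tails that will occupy part of it.
Several (increasingly diverged) references may be applied sequentially:
contigs confidently placed by an earlier reference are never re-placed.

The plan is AGP-expressible and can be materialized to scaffold FASTA with
``plan_to_sequences``.  ``detect_scaffold_conflicts`` flags contigs whose
alignments jump between prior scaffolds (or far within one) so they can be
split before re-scaffolding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .curation import SplitPoint
from .io_formats import AgpRow, PafAlignment, SequenceRecord, reverse_complement

__all__ = [
    "AnchorBlock",
    "ContigPlacement",
    "ScaffoldComponent",
    "Scaffold",
    "ScaffoldPlan",
    "build_anchor_blocks",
    "place_contigs",
    "order_and_gap",
    "scaffold_multi_reference",
    "detect_scaffold_conflicts",
    "plan_to_sequences",
    "plan_from_agp_rows",
]


@dataclass
class AnchorBlock:
    """Merged collinear alignment evidence tying a contig to a reference."""

    contig_id: str
    contig_start: int
    contig_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    weight: int  # summed PAF matches
    n_members: int = 1

    @property
    def contig_span(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class ContigPlacement:
    contig_id: str
    ref_name: str
    position_key: float  # weighted median of anchor ref midpoints
    orientation: str
    support: int  # total weight on the chosen chromosome
    ambiguity: float  # runner-up chromosome weight / chosen weight


@dataclass(frozen=True)
class ScaffoldComponent:
    contig_id: str
    orientation: str  # + or -


@dataclass
class Scaffold:
    scaffold_id: str
    components: list[ScaffoldComponent]
    gaps: list[int]  # len == len(components) - 1

    def __post_init__(self) -> None:
        if len(self.gaps) != max(0, len(self.components) - 1):
            raise ValueError("gap list must have one entry per adjacent pair")


@dataclass
class ScaffoldPlan:
    """Ordered, oriented contig components and estimated gaps per scaffold."""

    scaffolds: list[Scaffold]
    unplaced: list[str]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for scaf in self.scaffolds:
            for comp in scaf.components:
                if comp.contig_id in seen:
                    raise ValueError(f"contig {comp.contig_id} appears twice in plan")
                seen.add(comp.contig_id)
        for cid in self.unplaced:
            if cid in seen:
                raise ValueError(f"contig {cid} both placed and unplaced")

    @property
    def gap_count(self) -> int:
        return sum(len(s.gaps) for s in self.scaffolds)

    def scaffold_length(self, scaffold: Scaffold) -> int:
        total = sum(self.contig_lengths[c.contig_id] for c in scaffold.components)
        return total + sum(scaffold.gaps)

    def to_agp_rows(self) -> list[AgpRow]:
        rows: list[AgpRow] = []
        for scaf in self.scaffolds:
            pos = 1
            part = 1
            for i, comp in enumerate(scaf.components):
                clen = self.contig_lengths[comp.contig_id]
                rows.append(
                    AgpRow(
                        scaffold_id=scaf.scaffold_id,
                        scaffold_start=pos,
                        scaffold_end=pos + clen - 1,
                        part_number=part,
                        component_type="W",
                        component_id=comp.contig_id,
                        component_start=1,
                        component_end=clen,
                        orientation=comp.orientation,
                    )
                )
                pos += clen
                part += 1
                if i < len(scaf.gaps):
                    g = scaf.gaps[i]
                    rows.append(
                        AgpRow(
                            scaffold_id=scaf.scaffold_id,
                            scaffold_start=pos,
                            scaffold_end=pos + g - 1,
                            part_number=part,
                            component_type="N",
                            gap_length=g,
                        )
                    )
                    pos += g
                    part += 1
        return rows


def plan_from_agp_rows(
    rows: Sequence[AgpRow], unplaced: Sequence[str] = ()
) -> ScaffoldPlan:
    """Reconstruct a ScaffoldPlan from parsed AGP rows."""
    order: list[str] = []
    comps: dict[str, list[ScaffoldComponent]] = {}
    gaps: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    for r in sorted(rows, key=lambda r: (r.scaffold_id, r.part_number)):
        if r.scaffold_id not in comps:
            comps[r.scaffold_id] = []
            gaps[r.scaffold_id] = []
            order.append(r.scaffold_id)
        if r.component_type == "W":
            comps[r.scaffold_id].append(
                ScaffoldComponent(r.component_id, r.orientation)
            )
            lengths[r.component_id] = r.component_end - r.component_start + 1
        else:
            gaps[r.scaffold_id].append(r.gap_length)
    scaffolds = [Scaffold(sid, comps[sid], gaps[sid]) for sid in order]
    return ScaffoldPlan(scaffolds, list(unplaced), lengths)


def build_anchor_blocks(
    alignments: Iterable[PafAlignment],
    min_mapq: int = 30,
    min_block: int = 5000,
    max_chain_gap: int = 100_000,
) -> list[AnchorBlock]:
    """Chain contig-to-reference alignments into anchor blocks.

    Alignments below ``min_mapq`` are discarded.  Surviving records sharing
    (contig, ref, strand) are merged when both the query gap and the ref gap
    between successive records are <= ``max_chain_gap`` and the ref order is
    collinear for the strand.  Blocks whose merged query span is below
    ``min_block`` are dropped as repeat noise.
    """
    groups: dict[tuple[str, str, str], list[PafAlignment]] = {}
    for a in alignments:
        if a.mapq != 255 and a.mapq < min_mapq:
            continue
        groups.setdefault((a.query_name, a.target_name, a.strand), []).append(a)
    blocks: list[AnchorBlock] = []
    for (cid, ref, strand), alns in sorted(groups.items()):
        alns.sort(key=lambda a: a.query_start)
        cur: AnchorBlock | None = None
        for a in alns:
            if cur is None:
                cur = AnchorBlock(
                    cid, a.query_start, a.query_end, ref, a.target_start,
                    a.target_end, strand, a.matches, 1,
                )
                continue
            qgap = a.query_start - cur.contig_end
            if strand == "+":
                rgap = a.target_start - cur.ref_end
                collinear = a.target_start >= cur.ref_start
            else:
                rgap = cur.ref_start - a.target_end
                collinear = a.target_end <= cur.ref_end
            if collinear and qgap <= max_chain_gap and rgap <= max_chain_gap:
                cur.contig_end = max(cur.contig_end, a.query_end)
                cur.ref_start = min(cur.ref_start, a.target_start)
                cur.ref_end = max(cur.ref_end, a.target_end)
                cur.weight += a.matches
                cur.n_members += 1
            else:
                blocks.append(cur)
                cur = AnchorBlock(
                    cid, a.query_start, a.query_end, ref, a.target_start,
                    a.target_end, strand, a.matches, 1,
                )
        if cur is not None:
            blocks.append(cur)
    return [b for b in blocks if b.contig_span >= min_block]


def _weighted_median(values_weights: list[tuple[float, int]]) -> float:
    values_weights.sort()
    total = sum(w for _, w in values_weights)
    acc = 0
    for v, w in values_weights:
        acc += w
        if acc * 2 >= total:
            return v
    return values_weights[-1][0]


def place_contigs(blocks: Iterable[AnchorBlock]) -> list[ContigPlacement]:
    """Assign each contig a chromosome, orientation and ordering key.

    Chromosome: argmax of summed block weight (ties to the lexicographically
    smallest name).  Orientation: majority strand weight on that chromosome
    (tie -> "+").  Position key: weight-weighted median of block reference
    midpoints.  Ambiguity: runner-up chromosome weight over chosen weight.
    """
    by_contig: dict[str, list[AnchorBlock]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig_id, []).append(b)
    placements: list[ContigPlacement] = []
    for cid in sorted(by_contig):
        cblocks = by_contig[cid]
        weight_by_ref: dict[str, int] = {}
        for b in cblocks:
            weight_by_ref[b.ref_name] = weight_by_ref.get(b.ref_name, 0) + b.weight
        chosen = min(weight_by_ref, key=lambda r: (-weight_by_ref[r], r))
        support = weight_by_ref[chosen]
        others = [w for r, w in weight_by_ref.items() if r != chosen]
        ambiguity = max(others) / support if others else 0.0
        on_chosen = [b for b in cblocks if b.ref_name == chosen]
        plus = sum(b.weight for b in on_chosen if b.strand == "+")
        minus = sum(b.weight for b in on_chosen if b.strand == "-")
        orientation = "-" if minus > plus else "+"
        midpoints = [((b.ref_start + b.ref_end) / 2.0, b.weight) for b in on_chosen]
        placements.append(
            ContigPlacement(
                cid, chosen, _weighted_median(midpoints), orientation, support,
                ambiguity,
            )
        )
    return placements


def order_and_gap(
    placements: Iterable[ContigPlacement],
    blocks: Iterable[AnchorBlock],
    contig_lengths: Mapping[str, int],
    min_gap: int = 100,
    prefix: str = "scaffold_",
) -> ScaffoldPlan:
    """Order placed contigs per chromosome and estimate the gaps between
    neighbours.

    Contigs are sorted by position key (ties: longer contig first, then id).
    The gap between two neighbours is the reference distance between their
    facing anchors minus the unaligned contig tails that project into it,
    floored at ``min_gap``.  Contigs with no placement end up unplaced.
    """
    blocks = list(blocks)
    placements = list(placements)
    placed_ids = {p.contig_id for p in placements}
    by_chrom: dict[str, list[ContigPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.ref_name, []).append(p)
    blocks_by_key: dict[tuple[str, str], list[AnchorBlock]] = {}
    for b in blocks:
        blocks_by_key.setdefault((b.contig_id, b.ref_name), []).append(b)

    scaffolds: list[Scaffold] = []
    for chrom in sorted(by_chrom):
        chrom_placements = sorted(
            by_chrom[chrom],
            key=lambda p: (p.position_key, -contig_lengths[p.contig_id], p.contig_id),
        )
        components = [
            ScaffoldComponent(p.contig_id, p.orientation) for p in chrom_placements
        ]
        gaps: list[int] = []
        for cur, nxt in zip(chrom_placements, chrom_placements[1:]):
            cur_blocks = blocks_by_key[(cur.contig_id, chrom)]
            nxt_blocks = blocks_by_key[(nxt.contig_id, chrom)]
            cur_ref_end = max(b.ref_end for b in cur_blocks)
            nxt_ref_start = min(b.ref_start for b in nxt_blocks)
            ref_dist = nxt_ref_start - cur_ref_end
            gaps.append(
                max(
                    min_gap,
                    ref_dist
                    - _right_tail(cur, cur_blocks, contig_lengths)
                    - _left_tail(nxt, nxt_blocks, contig_lengths),
                )
            )
        scaffolds.append(Scaffold(f"{prefix}{chrom}", components, gaps))

    unplaced = sorted(set(contig_lengths) - placed_ids)
    return ScaffoldPlan(scaffolds, unplaced, dict(contig_lengths))


def _right_tail(
    p: ContigPlacement, blocks: list[AnchorBlock], lengths: Mapping[str, int]
) -> int:
    """Unaligned contig bases past the last anchor, in scaffold direction."""
    if p.orientation == "+":
        return lengths[p.contig_id] - max(b.contig_end for b in blocks)
    return min(b.contig_start for b in blocks)


def _left_tail(
    p: ContigPlacement, blocks: list[AnchorBlock], lengths: Mapping[str, int]
) -> int:
    if p.orientation == "+":
        return min(b.contig_start for b in blocks)
    return lengths[p.contig_id] - max(b.contig_end for b in blocks)


def scaffold_multi_reference(
    alignments_per_ref: Sequence[Iterable[PafAlignment]],
    contig_lengths: Mapping[str, int],
    min_mapq: int = 30,
    min_block: int = 5000,
    max_chain_gap: int = 100_000,
    min_gap: int = 100,
    max_ambiguity: float = 0.8,
    prefix: str = "scaffold_",
) -> ScaffoldPlan:
    """Apply several references in precedence order (closest first).

    Contigs placed confidently (ambiguity <= ``max_ambiguity``) by an
    earlier reference are withheld from later ones; a later reference never
    unplaces or moves an earlier placement.
    """
    remaining = set(contig_lengths)
    all_scaffolds: list[Scaffold] = []
    for k, alignments in enumerate(alignments_per_ref):
        blocks = [
            b
            for b in build_anchor_blocks(
                alignments, min_mapq=min_mapq, min_block=min_block,
                max_chain_gap=max_chain_gap,
            )
            if b.contig_id in remaining
        ]
        placements = place_contigs(blocks)
        if k + 1 < len(alignments_per_ref):
            placements = [p for p in placements if p.ambiguity <= max_ambiguity]
        placed_ids = {p.contig_id for p in placements}
        sub_lengths = {c: contig_lengths[c] for c in placed_ids}
        ref_prefix = prefix if k == 0 else f"{prefix}ref{k + 1}_"
        plan_k = order_and_gap(
            placements, blocks, sub_lengths, min_gap=min_gap, prefix=ref_prefix
        )
        all_scaffolds.extend(plan_k.scaffolds)
        remaining -= placed_ids
    return ScaffoldPlan(all_scaffolds, sorted(remaining), dict(contig_lengths))


def detect_scaffold_conflicts(
    alignments: Iterable[PafAlignment],
    min_mapq: int = 30,
    max_jump: int = 1_000_000,
    min_side: int = 50_000,
) -> list[SplitPoint]:
    """Split contigs whose alignments to prior scaffolds are inconsistent.

    Adjacent alignments (in query order) on different scaffolds, or on the
    same scaffold with a target jump beyond ``max_jump``, indicate a
    misjoin; a split is emitted at the midpoint between the two query
    intervals provided both sides carry >= ``min_side`` aligned bases.
    """
    by_contig: dict[str, list[PafAlignment]] = {}
    for a in alignments:
        if a.mapq != 255 and a.mapq < min_mapq:
            continue
        by_contig.setdefault(a.query_name, []).append(a)
    splits: list[SplitPoint] = []
    for cid in sorted(by_contig):
        alns = sorted(by_contig[cid], key=lambda a: a.query_start)
        left_sum = 0
        total = sum(a.query_span for a in alns)
        for prev, nxt in zip(alns, alns[1:]):
            left_sum += prev.query_span
            if prev.target_name != nxt.target_name:
                conflict = True
            else:
                jump = max(
                    nxt.target_start - prev.target_end,
                    prev.target_start - nxt.target_end,
                )
                conflict = jump > max_jump
            if conflict and left_sum >= min_side and total - left_sum >= min_side:
                pos = (prev.query_end + nxt.query_start) // 2
                pos = min(max(pos, 1), prev.query_length - 1)
                splits.append(SplitPoint(cid, pos, "scaffold_conflict"))
    return splits


def plan_to_sequences(
    plan: ScaffoldPlan,
    contigs: Iterable[SequenceRecord],
    gap_char: str = "N",
) -> list[SequenceRecord]:
    """Materialize scaffold sequences from a plan.

    Minus-oriented components are reverse-complemented; gaps become runs of
    ``gap_char``.  Unplaced contigs are emitted unchanged under their own
    ids.  Total non-N bases are conserved.
    """
    by_id = {c.id: c for c in contigs}
    out: list[SequenceRecord] = []
    for scaf in plan.scaffolds:
        parts: list[str] = []
        for i, comp in enumerate(scaf.components):
            if comp.contig_id not in by_id:
                raise KeyError(f"plan component {comp.contig_id!r} not in contigs")
            seq = by_id[comp.contig_id].sequence
            if comp.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            if i < len(scaf.gaps):
                parts.append(gap_char * scaf.gaps[i])
        out.append(SequenceRecord(scaf.scaffold_id, "".join(parts)))
    for cid in plan.unplaced:
        if cid in by_id:
            out.append(by_id[cid])
    return out
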