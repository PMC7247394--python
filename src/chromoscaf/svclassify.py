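"""Large-scale rearrangement counting from assembly-to-reference alignments.

The input is a PAF file of assembly (query) vs reference (target), e.g.
from a diverged-assembly whole-genome mapping.  Records are filtered to the
most uniquely placed alignments (mapping quality 60), split neighbouring
alignments are re-chained, and three classes of large (>300 kb by default)
discrepancies are counted per query sequence:

* ``fusion_fission`` (f) — a junction joining segments from two different
  reference chromosomes;
* ``intra_translocation`` (t) — a same-chromosome segment displaced out of
  collinear order, identified as a chain excluded from the weight-maximal
  monotone subsequence of reference starts;
* ``inversion`` (i) — a maximal run of chains aligned opposite to the
  query's dominant strand.  A query that is entirely reverse-complemented
  relative to the reference is *not* an inversion: dominance is computed
  per query, so global orientation cancels out.

``dotplot_data`` exports chain coordinates with cumulative chromosome
offsets, sufficient to draw whole-genome dot plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import PafAlignment

__all__ = [
    "ChainedAlignment",
    "RearrangementEvent",
    "EventCounts",
    "filter_mq",
    "chain_alignments",
    "classify_events",
    "dotplot_data",
]


@dataclass
class ChainedAlignment:
    """Convex hull of collinear PAF records on one (query, ref, strand)."""

    query_name: str
    query_start: int
    query_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    n_members: int
    weight: int  # summed matches

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def to_paf(self, query_length: int, ref_length: int) -> PafAlignment:
        """Induced PAF representation (for idempotence checks and export)."""
        return PafAlignment(
            self.query_name, query_length, self.query_start, self.query_end,
            self.strand, self.ref_name, ref_length, self.ref_start, self.ref_end,
            min(self.weight, self.query_span), max(self.weight, self.query_span),
            60,
        )


@dataclass
class RearrangementEvent:
    kind: str  # fusion_fission | intra_translocation | inversion
    query_name: str
    query_start: int
    query_end: int
    ref_names: tuple[str, ...]
    size: int  # query span of the offending segment


@dataclass
class EventCounts:
    fusion_fission: int = 0
    intra_translocation: int = 0
    inversion: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.fusion_fission, self.intra_translocation, self.inversion)


def filter_mq(
    alignments: Iterable[PafAlignment], min_mapq: int = 60
) -> list[PafAlignment]:
    """Keep records with mapq >= ``min_mapq`` (order preserved)."""
    return [a for a in alignments if a.mapq != 255 and a.mapq >= min_mapq]


def chain_alignments(
    alignments: Iterable[PafAlignment], max_chain_gap: int = 300_000
) -> list[ChainedAlignment]:
    """Re-join split neighbouring alignments into chains.

    Per query, records are taken in query order; successive records sharing
    (ref, strand) merge when both the query gap and the ref gap are
    <= ``max_chain_gap`` and the ref order is collinear for the strand
    (increasing for ``+``, decreasing for ``-``).  The operation is
    idempotent on its induced record representation.
    """
    by_query: dict[str, list[PafAlignment]] = {}
    for a in alignments:
        by_query.setdefault(a.query_name, []).append(a)
    chains: list[ChainedAlignment] = []
    for qname in sorted(by_query):
        alns = sorted(by_query[qname], key=lambda a: (a.query_start, a.query_end))
        cur: ChainedAlignment | None = None
        for a in alns:
            if cur is not None and a.target_name == cur.ref_name and a.strand == cur.strand:
                qgap = a.query_start - cur.query_end
                if a.strand == "+":
                    rgap = a.target_start - cur.ref_end
                    collinear = a.target_start >= cur.ref_start
                else:
                    rgap = cur.ref_start - a.target_end
                    collinear = a.target_end <= cur.ref_end
                if collinear and qgap <= max_chain_gap and rgap <= max_chain_gap:
                    cur.query_end = max(cur.query_end, a.query_end)
                    cur.ref_start = min(cur.ref_start, a.target_start)
                    cur.ref_end = max(cur.ref_end, a.target_end)
                    cur.n_members += 1
                    cur.weight += a.matches
                    continue
            if cur is not None:
                chains.append(cur)
            cur = ChainedAlignment(
                qname, a.query_start, a.query_end, a.target_name, a.target_start,
                a.target_end, a.strand, 1, a.matches,
            )
        if cur is not None:
            chains.append(cur)
    return chains


def _weighted_monotone_subsequence(
    keys: list[int], weights: list[int], increasing: bool
) -> set[int]:
    """Indices of the weight-maximal strictly monotone subsequence.

    O(n^2) dynamic program; chain counts per query are small.  Ties are
    resolved toward the earliest predecessor, making the result
    deterministic for fixed input order.
    """
    n = len(keys)
    if n == 0:
        return set()
    sign = 1 if increasing else -1
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if sign * keys[j] < sign * keys[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chosen: set[int] = set()
    while end != -1:
        chosen.add(end)
        end = prev[end]
    return chosen


def classify_events(
    chains: Iterable[ChainedAlignment], min_event_size: int = 300_000
) -> tuple[list[RearrangementEvent], EventCounts]:
    """Count fusions/fissions, intra-chromosomal translocations and
    inversions per query from chained alignments.

    Chains whose query span is below ``min_event_size`` are ignored
    entirely — fragments smaller than a countable event neither trigger
    events nor vote on dominance.
    """
    by_query: dict[str, list[ChainedAlignment]] = {}
    for c in chains:
        by_query.setdefault(c.query_name, []).append(c)
    events: list[RearrangementEvent] = []
    counts = EventCounts()
    for qname in sorted(by_query):
        retained = sorted(
            (c for c in by_query[qname] if c.query_span >= min_event_size),
            key=lambda c: c.query_start,
        )
        if not retained:
            continue

        # (1) fusion/fission: adjacent pair on different reference chromosomes
        for left, right in zip(retained, retained[1:]):
            if left.ref_name != right.ref_name:
                counts.fusion_fission += 1
                events.append(
                    RearrangementEvent(
                        "fusion_fission", qname, left.query_end, right.query_start,
                        (left.ref_name, right.ref_name),
                        min(left.query_span, right.query_span),
                    )
                )

        # (2) dominant chromosome and strand by summed weight
        w_by_ref: dict[str, int] = {}
        for c in retained:
            w_by_ref[c.ref_name] = w_by_ref.get(c.ref_name, 0) + c.weight
        dom_ref = min(w_by_ref, key=lambda r: (-w_by_ref[r], r))
        on_dom = [c for c in retained if c.ref_name == dom_ref]
        w_plus = sum(c.weight for c in on_dom if c.strand == "+")
        w_minus = sum(c.weight for c in on_dom if c.strand == "-")
        dom_strand = "-" if w_minus > w_plus else "+"

        # (3) inversion: maximal opposite-strand runs of sufficient span
        run: list[ChainedAlignment] = []
        for c in on_dom + [None]:  # type: ignore[list-item]
            if c is not None and c.strand != dom_strand:
                run.append(c)
                continue
            if run:
                span = run[-1].query_end - run[0].query_start
                if span >= min_event_size:
                    counts.inversion += 1
                    events.append(
                        RearrangementEvent(
                            "inversion", qname, run[0].query_start,
                            run[-1].query_end, (dom_ref,), span,
                        )
                    )
                run = []

        # (4) translocation: dominant-strand chains excluded from the
        # weight-maximal monotone subsequence of ref starts
        collinear_set = [c for c in on_dom if c.strand == dom_strand]
        keys = [c.ref_start for c in collinear_set]
        weights = [c.weight for c in collinear_set]
        kept = _weighted_monotone_subsequence(keys, weights, dom_strand == "+")
        for i, c in enumerate(collinear_set):
            if i not in kept:
                counts.intra_translocation += 1
                events.append(
                    RearrangementEvent(
                        "intra_translocation", qname, c.query_start, c.query_end,
                        (dom_ref,), c.query_span,
                    )
                )
    return events, counts


def dotplot_data(
    chains: Iterable[ChainedAlignment],
    ref_lengths: Mapping[str, int],
    query_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """One row per chain with cumulative-offset coordinates for dot plots.

    Chromosomes are concatenated in sorted-name order on both axes; the
    columns give plot-space segment endpoints plus the raw fields.
    """
    ref_offsets = _cumulative_offsets(ref_lengths)
    query_offsets = _cumulative_offsets(query_lengths)
    rows = []
    for c in chains:
        if c.ref_name not in ref_offsets:
            raise KeyError(f"chain references unknown ref {c.ref_name!r}")
        if c.query_name not in query_offsets:
            raise KeyError(f"chain references unknown query {c.query_name!r}")
        roff = ref_offsets[c.ref_name]
        qoff = query_offsets[c.query_name]
        rows.append(
            {
                "query_name": c.query_name,
                "ref_name": c.ref_name,
                "strand": c.strand,
                "query_plot_start": qoff + c.query_start,
                "query_plot_end": qoff + c.query_end,
                "ref_plot_start": roff + (c.ref_start if c.strand == "+" else c.ref_end),
                "ref_plot_end": roff + (c.ref_end if c.strand == "+" else c.ref_start),
                "weight": c.weight,
            }
        )
    columns = [
        "query_name", "ref_name", "strand", "query_plot_start", "query_plot_end",
        "ref_plot_start", "ref_plot_end", "weight",
    ]
    return pd.DataFrame(rows, columns=columns)


def _cumulative_offsets(lengths: Mapping[str, int]) -> dict[str, int]:
    offsets: dict[str, int] = {}
    acc = 0
    for name in sorted(lengths):
        offsets[name] = acc
        acc += lengths[name]
    return offsets
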