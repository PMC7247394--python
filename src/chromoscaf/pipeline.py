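"""End-to-end pipeline orchestration: curate -> scaffold -> gap-fill ->
statistics and rearrangement counts, with a JSON manifest of every stage.

Alignments are pluggable inputs (PAF from any mapper, or truth PAF from the
synthetic generator).  Optional external mapper/assembler command templates
can be configured; the default pipeline consumes precomputed alignments
only, so runs are deterministic and tool-free.  Contigs fragmented by
curation keep derived ids (``<id>.1`` ...); re-anchoring them against the
reference requires re-mapping via the external hook — without it they
simply remain unplaced.
"""

from __future__ import annotations

import hashlib
import json
import shlex
import subprocess
from pathlib import Path
from typing import Iterable, Mapping

from . import curation, gapclose, metrics, refscaffold, svclassify
from .config import PipelineConfig
from .io_formats import (
    PafAlignment,
    SequenceRecord,
    read_fasta,
    read_paf,
    write_agp,
    write_bed,
    write_fasta,
    write_paf,
)
from .refscaffold import ScaffoldPlan

__all__ = [
    "run_pipeline",
    "project_reads_to_scaffolds",
    "project_contig_queries_to_scaffolds",
    "run_external",
]


def _component_layout(plan: ScaffoldPlan) -> dict[str, tuple[str, int, str, int]]:
    """contig id -> (scaffold, offset, orientation, scaffold_length)."""
    layout: dict[str, tuple[str, int, str, int]] = {}
    for scaf in plan.scaffolds:
        slen = plan.scaffold_length(scaf)
        pos = 0
        for i, comp in enumerate(scaf.components):
            layout[comp.contig_id] = (scaf.scaffold_id, pos, comp.orientation, slen)
            pos += plan.contig_lengths[comp.contig_id]
            if i < len(scaf.gaps):
                pos += scaf.gaps[i]
    return layout


def project_reads_to_scaffolds(
    plan: ScaffoldPlan, alignments: Iterable[PafAlignment]
) -> list[PafAlignment]:
    """Lift read-to-contig alignments into scaffold coordinates.

    Alignments to unplaced contigs pass through unchanged.
    """
    layout = _component_layout(plan)
    out: list[PafAlignment] = []
    for a in alignments:
        if a.target_name not in layout:
            out.append(a)
            continue
        scaf, off, ori, slen = layout[a.target_name]
        clen = plan.contig_lengths[a.target_name]
        if ori == "+":
            ts, te = off + a.target_start, off + a.target_end
            strand = a.strand
        else:
            ts, te = off + clen - a.target_end, off + clen - a.target_start
            strand = "-" if a.strand == "+" else "+"
        out.append(
            PafAlignment(
                a.query_name, a.query_length, a.query_start, a.query_end,
                strand, scaf, slen, ts, te, a.matches, a.block_length, a.mapq,
                a.tags,
            )
        )
    return out


def project_contig_queries_to_scaffolds(
    plan: ScaffoldPlan, alignments: Iterable[PafAlignment]
) -> list[PafAlignment]:
    """Lift contig-to-reference alignments so the query becomes the scaffold
    each contig was placed in (for scaffold-level rearrangement counting)."""
    layout = _component_layout(plan)
    out: list[PafAlignment] = []
    for a in alignments:
        if a.query_name not in layout:
            out.append(a)
            continue
        scaf, off, ori, slen = layout[a.query_name]
        clen = plan.contig_lengths[a.query_name]
        if ori == "+":
            qs, qe = off + a.query_start, off + a.query_end
            strand = a.strand
        else:
            qs, qe = off + clen - a.query_end, off + clen - a.query_start
            strand = "-" if a.strand == "+" else "+"
        out.append(
            PafAlignment(
                scaf, slen, qs, qe, strand, a.target_name, a.target_length,
                a.target_start, a.target_end, a.matches, a.block_length,
                a.mapq, a.tags,
            )
        )
    return out


def run_external(template: str, **fields: str) -> None:
    """Run an external tool from a command template like
    ``minimap2 {target} {query} -o {out}``; raises on nonzero exit."""
    cmd = [part.format(**fields) for part in shlex.split(template)]
    subprocess.run(cmd, check=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the pipeline per ``config``; returns the manifest dict.

    Stages: curation (optional), reference scaffolding, gap filling with
    local patches and direct stitches, assembly statistics and large-scale
    rearrangement counts.  Every stage records its parameters and output
    checksums in ``manifest.json``; any failure raises with the stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "counters": {}}
    log_lines: list[str] = []

    def record_stage(name: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "parameters": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    def log(msg: str) -> None:
        log_lines.append(msg)

    try:
        contigs = read_fasta(config.contigs)
    except Exception as exc:
        raise RuntimeError(f"stage inputs failed: {exc}") from exc
    contig_lengths = {c.id: len(c.sequence) for c in contigs}

    # ---------------- Step 1: curation ----------------
    if not config.skip_curation and (config.reads_paf or config.alt_paf):
        try:
            splits: list[curation.SplitPoint] = []
            trims = []
            rescued: set[str] = set()
            if config.alt_paf:
                alt = read_paf(config.alt_paf)
                splits += curation.reconcile_assemblies(
                    alt, contig_lengths, config.coverage_tolerance
                )
            if config.reads_paf:
                reads_aln = read_paf(config.reads_paf)
                profiles = curation.coverage_from_alignments(
                    reads_aln, contig_lengths, config.min_mapq_coverage
                )
                zsplits, trims = curation.find_zero_coverage_splits(
                    profiles, config.min_zero_run, config.end_trim
                )
                splits += zsplits
                read_lengths = {a.query_name: a.query_length for a in reads_aln}
                rescued = curation.classify_partially_mapped_reads(
                    reads_aln, read_lengths, config.max_mapped_fraction
                )
            contigs = curation.apply_splits(contigs, splits)
            contig_lengths = {c.id: len(c.sequence) for c in contigs}
            curated_fa = outdir / "curated_contigs.fasta"
            write_fasta(contigs, curated_fa)
            bed = outdir / "curation_splits.bed"
            write_bed(list(trims) + [_split_bed(s) for s in splits], bed)
            rescue_txt = outdir / "rescue_reads.txt"
            rescue_txt.write_text("".join(f"{r}\n" for r in sorted(rescued)))
            manifest["counters"]["curation_splits"] = len(splits)
            manifest["counters"]["rescued_reads"] = len(rescued)
            log(f"curate: {len(splits)} splits, {len(rescued)} rescued reads")
            record_stage(
                "curate",
                {"coverage_tolerance": config.coverage_tolerance,
                 "min_zero_run": config.min_zero_run,
                 "max_mapped_fraction": config.max_mapped_fraction},
                [curated_fa, bed, rescue_txt],
            )
        except Exception as exc:
            raise RuntimeError(f"stage curate failed: {exc}") from exc

    # ---------------- Step 2: reference scaffolding ----------------
    if not config.ref_pafs:
        raise RuntimeError("stage scaffold failed: no reference PAFs configured")
    try:
        ref_alignment_sets = [read_paf(p) for p in config.ref_pafs]
        plan = refscaffold.scaffold_multi_reference(
            ref_alignment_sets, contig_lengths,
            min_mapq=config.min_mapq_anchor, min_block=config.min_block,
            max_chain_gap=config.max_chain_gap_anchor, min_gap=config.min_gap,
            max_ambiguity=config.max_ambiguity, prefix=config.scaffold_prefix,
        )
        scaffold_seqs = refscaffold.plan_to_sequences(plan, contigs)
        scaf_fa = outdir / "scaffolds.fasta"
        write_fasta(scaffold_seqs, scaf_fa)
        agp = outdir / "scaffolds.agp"
        write_agp(plan, agp)
        placements = refscaffold.place_contigs(
            refscaffold.build_anchor_blocks(
                ref_alignment_sets[0], config.min_mapq_anchor,
                config.min_block, config.max_chain_gap_anchor,
            )
        )
        table = outdir / "placements.tsv"
        with open(table, "w") as fh:
            fh.write("contig\tchrom\tposition_key\torientation\tsupport\tambiguity\n")
            for p in placements:
                fh.write(
                    f"{p.contig_id}\t{p.ref_name}\t{p.position_key:.1f}\t"
                    f"{p.orientation}\t{p.support}\t{p.ambiguity:.4f}\n"
                )
        unplaced_txt = outdir / "unplaced.txt"
        unplaced_txt.write_text("".join(f"{u}\n" for u in plan.unplaced))
        manifest["counters"]["placed_contigs"] = sum(
            len(s.components) for s in plan.scaffolds
        )
        manifest["counters"]["unplaced_contigs"] = len(plan.unplaced)
        manifest["counters"]["scaffold_gaps"] = plan.gap_count
        log(f"scaffold: {len(plan.scaffolds)} scaffolds, {plan.gap_count} gaps")
        record_stage(
            "scaffold",
            {"min_mapq": config.min_mapq_anchor, "min_block": config.min_block,
             "min_gap": config.min_gap},
            [scaf_fa, agp, table, unplaced_txt],
        )
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage scaffold failed: {exc}") from exc

    # ---------------- Step 3/4: gap filling and stitching ----------------
    try:
        patches: dict[str, list[SequenceRecord]] | None = None
        if config.reads and config.reads_paf:
            reads = {r.id: r for r in read_fasta(config.reads)}
            scaffold_reads = project_reads_to_scaffolds(
                plan, read_paf(config.reads_paf)
            )
            windows = gapclose.extract_gap_windows(
                plan, scaffold_reads, config.window
            )
            patches = gapclose.assemble_gap_patches(
                windows, reads, config.min_overlap, config.min_identity
            )
        new_plan, new_seqs, reports = gapclose.close_gaps(
            plan, contigs, patches, config.min_overlap, config.min_identity,
            config.max_search,
        )
        closed_fa = outdir / "scaffolds_gapfilled.fasta"
        write_fasta(refscaffold.plan_to_sequences(new_plan, new_seqs), closed_fa)
        closed_agp = outdir / "scaffolds_gapfilled.agp"
        write_agp(new_plan, closed_agp)
        report_tsv = outdir / "gap_report.tsv"
        with open(report_tsv, "w") as fh:
            fh.write("gap_id\toutcome\toverlap_left\toverlap_right\tidentity\tinserted\n")
            for r in reports:
                fh.write(
                    f"{r.gap_id}\t{r.outcome}\t{r.overlap_left}\t"
                    f"{r.overlap_right}\t{r.identity:.4f}\t{r.inserted_bases}\n"
                )
        closed = sum(1 for r in reports if r.outcome != "open")
        manifest["counters"]["gaps_closed"] = closed
        manifest["counters"]["gaps_open"] = len(reports) - closed
        log(f"gapfill: closed {closed}/{len(reports)} gaps")
        record_stage(
            "gapfill",
            {"min_overlap": config.min_overlap,
             "min_identity": config.min_identity, "window": config.window},
            [closed_fa, closed_agp, report_tsv],
        )
        final_plan, final_seqs = new_plan, new_seqs
    except Exception as exc:
        raise RuntimeError(f"stage gapfill failed: {exc}") from exc

    # ---------------- statistics and rearrangement counts ----------------
    try:
        final_scaffolds = refscaffold.plan_to_sequences(final_plan, final_seqs)
        ref_lengths = {
            a.target_name: a.target_length for a in ref_alignment_sets[0]
        }
        top_n = config.top_n or len(ref_lengths)
        stats = metrics.assembly_report(final_scaffolds, top_n, config.min_gap_run)
        stats_tsv = outdir / "assembly_stats.tsv"
        stats_tsv.write_text(stats.to_tsv())

        sv_input = project_contig_queries_to_scaffolds(
            final_plan, ref_alignment_sets[0]
        )
        filtered = svclassify.filter_mq(sv_input, config.min_mapq_sv)
        chains = svclassify.chain_alignments(filtered, config.max_chain_gap_sv)
        events, counts = svclassify.classify_events(chains, config.min_event_size)
        events_tsv = outdir / "rearrangements.tsv"
        with open(events_tsv, "w") as fh:
            fh.write("kind\tquery\tstart\tend\trefs\tsize\n")
            for e in events:
                fh.write(
                    f"{e.kind}\t{e.query_name}\t{e.query_start}\t{e.query_end}\t"
                    f"{','.join(e.ref_names)}\t{e.size}\n"
                )
        manifest["counters"]["fusion_fission"] = counts.fusion_fission
        manifest["counters"]["intra_translocation"] = counts.intra_translocation
        manifest["counters"]["inversion"] = counts.inversion
        manifest["counters"]["scaffold_n50"] = stats.n50
        manifest["counters"]["contig_n50"] = stats.contig_n50
        log(
            f"svstats: f={counts.fusion_fission} t={counts.intra_translocation} "
            f"i={counts.inversion}"
        )
        record_stage(
            "stats",
            {"top_n": top_n, "min_event_size": config.min_event_size},
            [stats_tsv, events_tsv],
        )
    except Exception as exc:
        raise RuntimeError(f"stage stats failed: {exc}") from exc

    (outdir / "pipeline.log").write_text("".join(f"{l}\n" for l in log_lines))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _split_bed(s: curation.SplitPoint):
    from .io_formats import BedInterval

    return BedInterval(s.contig_id, s.position, s.position + 1, s.reason)
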