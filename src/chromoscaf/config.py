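"""Pipeline configuration: a commented INI file mirroring every stage
default, with strict unknown-key validation."""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig", "write_default_config", "read_config"]


@dataclass
class PipelineConfig:
    # [inputs]
    contigs: str = ""
    reads: str = ""
    reads_paf: str = ""          # reads -> contigs
    alt_paf: str = ""            # assembly A -> assembly B (reconciliation)
    ref_pafs: list[str] = field(default_factory=list)  # contigs -> refs, closest first
    seed: int = 0
    threads: int = 1             # advisory
    skip_curation: bool = False
    # [curate]
    min_mapq_coverage: int = 0
    end_pair_length: int = 500
    min_zero_run: int = 1
    end_trim: int = 0
    max_mapped_fraction: float = 0.10
    coverage_tolerance: int = 100
    # [scaffold]
    min_mapq_anchor: int = 30
    min_block: int = 5000
    max_chain_gap_anchor: int = 100_000
    min_gap: int = 100
    max_ambiguity: float = 0.8
    scaffold_prefix: str = "scaffold_"
    max_jump: int = 1_000_000
    min_side: int = 50_000
    # [gapclose]
    window: int = 20_000
    chunk_length: int = 250_000
    chunk_step: int = 200_000
    min_overlap: int = 1000
    min_identity: float = 0.95
    max_search: int = 100_000
    # [svclassify]
    min_mapq_sv: int = 60
    max_chain_gap_sv: int = 300_000
    min_event_size: int = 300_000
    # [metrics]
    top_n: int = 0               # 0 -> use the number of reference chromosomes
    min_gap_run: int = 10
    # [external]  command templates, e.g. "minimap2 -x map-ont {target} {query}"
    mapper_cmd: str = ""
    assembler_cmd: str = ""

    def validate(self) -> None:
        if not 0 <= self.max_mapped_fraction <= 1:
            raise ValueError("max_mapped_fraction must be in [0, 1]")
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must be in [0, 1]")
        if not 0 <= self.max_ambiguity <= 1:
            raise ValueError("max_ambiguity must be in [0, 1]")
        for name in ("min_zero_run", "min_overlap", "min_gap", "min_block",
                     "chunk_length", "chunk_step", "window", "min_event_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chunk_step > self.chunk_length:
            raise ValueError("chunk_step must be <= chunk_length")


_SECTIONS: dict[str, list[str]] = {
    "inputs": ["contigs", "reads", "reads_paf", "alt_paf", "ref_pafs", "seed",
               "threads", "skip_curation"],
    "curate": ["min_mapq_coverage", "end_pair_length", "min_zero_run",
               "end_trim", "max_mapped_fraction", "coverage_tolerance"],
    "scaffold": ["min_mapq_anchor", "min_block", "max_chain_gap_anchor",
                 "min_gap", "max_ambiguity", "scaffold_prefix", "max_jump",
                 "min_side"],
    "gapclose": ["window", "chunk_length", "chunk_step", "min_overlap",
                 "min_identity", "max_search"],
    "svclassify": ["min_mapq_sv", "max_chain_gap_sv", "min_event_size"],
    "metrics": ["top_n", "min_gap_run"],
    "external": ["mapper_cmd", "assembler_cmd"],
}

_COMMENTS: dict[str, str] = {
    "ref_pafs": "comma-separated contig-to-reference PAFs, closest reference first",
    "max_mapped_fraction": "reads mapping < this fraction of their length are rescued",
    "min_mapq_sv": "keep only the most uniquely placed alignments (MQ 60)",
    "min_event_size": "rearrangements smaller than this many bases are not counted",
    "chunk_length": "pseudo-read length; must respect the assembler read cap (256000)",
    "mapper_cmd": "optional external mapper template with {query} {target} {out}",
}


def write_default_config(path: str | Path) -> None:
    """Emit a commented config file carrying every default value."""
    cfg = PipelineConfig()
    lines = ["# chromoscaf pipeline configuration", ""]
    for section, keys in _SECTIONS.items():
        lines.append(f"[{section}]")
        for key in keys:
            if key in _COMMENTS:
                lines.append(f"# {_COMMENTS[key]}")
            value = getattr(cfg, key)
            if isinstance(value, list):
                value = ",".join(value)
            lines.append(f"{key} = {value}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a config file; unknown keys are errors."""
    parser = configparser.ConfigParser(inline_comment_prefixes=("#",))
    with open(path) as fh:
        parser.read_file(fh)
    cfg = PipelineConfig()
    types = {f.name: f.type for f in fields(PipelineConfig)}
    for section in parser.sections():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        for key, raw in parser.items(section):
            if key not in _SECTIONS[section]:
                raise ValueError(f"unknown config key {key!r} in [{section}]")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value: object = raw.strip().lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            elif isinstance(current, list):
                value = [p.strip() for p in raw.split(",") if p.strip()]
            else:
                value = raw.strip()
            setattr(cfg, key, value)
    cfg.validate()
    return cfg
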