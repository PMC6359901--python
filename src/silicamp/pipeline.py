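"""End-to-end orchestration of the three phases.

``run`` reads the pool, builds the inter-primer filter, tiles and denoises
the kMer ladder, extends every starting read, and writes the terminated,
primer-trimmed amplicons as FASTA.  Zero amplicons is a warning, not an
error: a primer pair simply may not occur in a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import extender, kmer_tables, region_filter
from .extender import DecisionStats, ExtensionConfig
from .seqcore import PrimerPairContext, read_sequences, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; mirrors the CLI flag for flag."""

    forward_primer: str
    reverse_primer: str
    inputs: list  # paths or glob patterns
    output: str
    k_min: int = 32
    k_step: int = 8
    min_count: int = 2
    variant_ratio: int = 20
    max_mismatches: int = 0
    max_amplicon_length: int = 5000
    lookahead_budget: int = 500
    rng_seed: int = 1
    stats_path: str | None = None

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("both primers must be non-empty")
        if self.k_min < 16:
            raise ValueError("k_min must be >= 16")


@dataclass
class RunSummary:
    n_reads: int
    n_region_reads: int
    n_starting: int
    n_extended: int
    n_abandoned: int
    output_path: str
    stats: DecisionStats = field(default_factory=DecisionStats)


def run(config: RunConfig) -> RunSummary:
    ctx = PrimerPairContext.from_strings(
        config.forward_primer, config.reverse_primer, config.max_mismatches)

    reads = list(read_sequences(config.inputs))
    logger.info("read %d sequences", len(reads))

    filt, region_reads = region_filter.build_region_reads(
        reads, ctx, k=config.k_min)
    starting = [r for r in region_reads if r.is_starting]

    results = []
    stats = DecisionStats()
    if starting:
        modal = kmer_tables.modal_read_length(region_reads)
        ks = kmer_tables.k_values(max(modal, config.k_min),
                                  config.k_min, config.k_step)
        ladder = kmer_tables.build_ladder(region_reads, ks)
        ladder = kmer_tables.denoise_ladder(
            ladder, min_count=config.min_count,
            variant_ratio=config.variant_ratio)
        logger.info("phase 2: ladder %s", ladder.size_report())
        cfg = ExtensionConfig(
            max_amplicon_length=config.max_amplicon_length,
            lookahead_budget=config.lookahead_budget,
            rng_seed=config.rng_seed)
        results, stats = extender.extend_all(starting, ladder, ctx, cfg)
    else:
        logger.warning("no starting reads found; writing empty output")

    amplicons = [(f"{r.source_id}", r.sequence)
                 for r in results if r.terminated]
    # header records the source read id and the amplicon length
    named = [(f"{sid} len={len(seq)}", seq) for sid, seq in amplicons]
    write_fasta(named, config.output)
    if not amplicons:
        logger.warning("zero amplicons written to %s", config.output)

    if config.stats_path:
        stats.write_tsv(config.stats_path)

    return RunSummary(
        n_reads=len(reads),
        n_region_reads=len(region_reads),
        n_starting=stats.starting_reads,
        n_extended=stats.fully_extended,
        n_abandoned=stats.abandoned,
        output_path=str(config.output),
        stats=stats,
    )
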