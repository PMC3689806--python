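"""End-to-end wiring of the discovery and genotyping stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .caller import (
    GenomeIndex,
    align_trimmed_reads,
    call_insertions,
    classify_reference_sites,
    cluster_flankers,
    scan_reference_for_te,
)
from .model import InsertionCall, TEModel
from .tescan import scan_and_trim

log = logging.getLogger("tetrace")


@dataclass
class RunConfig:
    """All tunable stage parameters, at their standard defaults."""

    seed_len: int = 7
    min_aligned: int = 10
    mismatch_allowance: float = 0.0
    min_trimmed_len: int = 10
    max_genome_mismatch: int = 3
    reference_scan: bool = False
    flank_len: int = 100
    chunk_size: int = 1_000_000
    footprint_min_support: int = 2
    seed: int = 0
    tsd_override: str | None = None


@dataclass
class DiscoveryResult:
    calls: list[InsertionCall]
    flanker_alignments: list
    reference_copies: list
    counts: dict = field(default_factory=dict)


def run_discovery(
    te: TEModel,
    reference: dict[str, str],
    reads,
    config: RunConfig = RunConfig(),
    paired: bool = False,
) -> DiscoveryResult:
    """TE scan, trim, flanker alignment, clustering and insertion calling.

    With ``config.reference_scan`` the reference is also scanned for
    full-length copies, classified shared or reference-only against the
    flanker alignments.
    """
    if config.tsd_override:
        te = TEModel(te.name, te.sequence, config.tsd_override)
    counts: dict = {}
    trimmed = scan_and_trim(
        reads,
        te,
        seed_len=config.seed_len,
        min_aligned=config.min_aligned,
        allowance=config.mismatch_allowance,
        min_len=config.min_trimmed_len,
        counts=counts,
    )
    index = GenomeIndex(reference)
    aln_counts: dict = {}
    alignments = align_trimmed_reads(
        trimmed,
        index,
        max_mismatch=config.max_genome_mismatch,
        paired=paired,
        counts=aln_counts,
    )
    counts.update(aln_counts)
    clusters = cluster_flankers(alignments)
    counts["clusters"] = len(clusters)
    calls = call_insertions(clusters, te.tsd, reference, te.name)
    counts["calls"] = len(calls)
    copies = []
    if config.reference_scan:
        copies = classify_reference_sites(
            scan_reference_for_te(reference, te),
            alignments,
            slop=te.tsd.width + 2,
        )
        counts["reference_copies"] = len(copies)
    for stage, value in sorted(counts.items()):
        log.info("%s=%s", stage, value)
    return DiscoveryResult(calls, alignments, copies, counts)
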