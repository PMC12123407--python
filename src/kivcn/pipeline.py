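"""One-sample end-to-end pipeline: count → estimate → SNP calls → report."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from .counting import SampleKmerCounts, count_kmers_in_reads
from .estimation import CopyNumberEstimate, estimate_copy_number, format_report
from .kmerdb import KmerDatabase
from .snps import SnpCall, SnpKmerPanel, call_snps, format_snp_calls

logger = logging.getLogger(__name__)


def run_sample_pipeline(
    db: KmerDatabase,
    fastq_paths: Sequence[str | Path],
    sample_id: str,
    panel: SnpKmerPanel | None = None,
    diploid_factor: float = 2.0,
    min_alt_count: int = 1,
) -> tuple[CopyNumberEstimate, list[SnpCall], SampleKmerCounts]:
    """Count a sample's reads, estimate copy number, call panel SNPs.

    Errors propagate with a stage label so a failing run names the stage.
    """
    extra = panel.all_kmers if panel is not None else ()
    try:
        counts = count_kmers_in_reads(fastq_paths, db, sample_id, extra_kmers=extra)
    except Exception as exc:
        raise RuntimeError(f"[counting] {exc}") from exc
    try:
        estimate = estimate_copy_number(counts, db, diploid_factor=diploid_factor)
    except Exception as exc:
        raise RuntimeError(f"[estimation] {exc}") from exc
    calls: list[SnpCall] = []
    if panel is not None:
        try:
            calls = call_snps(counts, panel, min_alt_count=min_alt_count)
        except Exception as exc:
            raise RuntimeError(f"[snp_typing] {exc}") from exc
    logger.info("sample report:\n%s", format_report(estimate))
    if calls:
        logger.info("SNP calls:\n%s", format_snp_calls(calls))
    return estimate, calls, counts
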