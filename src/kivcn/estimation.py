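"""Diploid copy-number estimation from k-mer occurrence means.

The estimator is deliberately simple: with a database of repeat-specific
k-mers (one occurrence per repeat unit) and normalization k-mers from a
single-copy region, a sample carrying N total repeat copies across its two
haplotypes yields repeat-k-mer occurrences proportional to N × depth while
normalization k-mers see 2 × depth (both haplotypes).  Hence

    copy_number = diploid_factor × mean_repeat / mean_norm,

with ``diploid_factor = 2`` converting the per-haplotype-equivalent ratio to
the diploid total.  Absent k-mers (count exactly 0) are ignored when taking
the means: a zero signals divergence from the reference, a null allele or a
coverage hole — not a fractional copy.  Both means carry the same read-edge
and error attenuation factors, which cancel in the ratio, making the
estimate robust to depth and (to first order) to base-calling error rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .counting import SampleKmerCounts
from .kmerdb import KmerDatabase

logger = logging.getLogger(__name__)

DEFAULT_DIPLOID_FACTOR = 2.0


class NoNormalizationSignalError(RuntimeError):
    """All normalization k-mers are absent: depth cannot be calibrated."""


@dataclass
class CopyNumberEstimate:
    sample_id: str
    mean_repeat: float
    mean_norm: float
    n_missing_repeat: int
    n_missing_norm: int
    copy_number: float
    diploid_factor: float = DEFAULT_DIPLOID_FACTOR


def _occurrences(counts: SampleKmerCounts, kmers: frozenset[str]) -> np.ndarray:
    return np.array([counts.counts.get(km, 0) for km in kmers], dtype=np.int64)


def estimate_copy_number(
    counts: SampleKmerCounts,
    db: KmerDatabase,
    diploid_factor: float = DEFAULT_DIPLOID_FACTOR,
) -> CopyNumberEstimate:
    """Estimate the total diploid repeat copy number of one sample.

    Means are arithmetic means over k-mers with count > 0 only.  Raises
    :class:`NoNormalizationSignalError` if every normalization k-mer is
    absent; an all-absent repeat set yields an estimate of 0 with a warning
    (possible null allele or no coverage).
    """
    rep = _occurrences(counts, db.repeat_kmers)
    norm = _occurrences(counts, db.norm_kmers)
    n_missing_repeat = int((rep == 0).sum())
    n_missing_norm = int((norm == 0).sum())

    norm_present = norm[norm > 0]
    if norm_present.size == 0:
        raise NoNormalizationSignalError(
            f"sample {counts.sample_id}: no normalization signal "
            f"(all {len(norm)} normalization k-mers absent)"
        )
    mean_norm = float(norm_present.mean())

    rep_present = rep[rep > 0]
    if rep_present.size == 0:
        logger.warning(
            "sample %s: every repeat k-mer absent; reporting copy number 0 "
            "(possible null allele or no repeat coverage)",
            counts.sample_id,
        )
        mean_repeat = 0.0
    else:
        mean_repeat = float(rep_present.mean())

    return CopyNumberEstimate(
        sample_id=counts.sample_id,
        mean_repeat=mean_repeat,
        mean_norm=mean_norm,
        n_missing_repeat=n_missing_repeat,
        n_missing_norm=n_missing_norm,
        copy_number=diploid_factor * mean_repeat / mean_norm,
        diploid_factor=diploid_factor,
    )


REPORT_COLUMNS = (
    "sample_id",
    "copy_number",
    "mean_repeat",
    "mean_norm",
    "n_missing_repeat",
    "n_missing_norm",
)


def format_report(estimate: CopyNumberEstimate) -> str:
    """Deterministic human-readable per-sample report."""
    lines = [
        f"sample            : {estimate.sample_id}",
        f"copy number       : {estimate.copy_number:.3f}",
        f"mean occurrence   : repeat {estimate.mean_repeat:.3f}"
        f" / normalization {estimate.mean_norm:.3f}",
        f"missing k-mers    : repeat {estimate.n_missing_repeat}"
        f" / normalization {estimate.n_missing_norm}",
    ]
    if estimate.mean_repeat == 0:
        lines.append("WARNING           : all repeat k-mers absent")
    return "\n".join(lines)


def report_row(estimate: CopyNumberEstimate) -> str:
    """One machine-readable TSV row (see :data:`REPORT_COLUMNS`)."""
    vals = asdict(estimate)
    out = []
    for col in REPORT_COLUMNS:
        v = vals[col]
        out.append(f"{v:.6g}" if isinstance(v, float) else str(v))
    return "\t".join(out)


def write_report(
    estimates: list[CopyNumberEstimate], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write per-sample estimates as TSV (default) or JSON records."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in estimates], fh, indent=2)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for e in estimates:
                fh.write(report_row(e) + "\n")


def plot_occurrences(
    counts: SampleKmerCounts,
    db: KmerDatabase,
    path: str | Path,
    diploid_factor: float = DEFAULT_DIPLOID_FACTOR,
) -> None:
    """Histogram of repeat vs normalization k-mer occurrences.

    Absent k-mers are shown in the zero bin; the two present-k-mer means are
    marked as vertical lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = estimate_copy_number(counts, db, diploid_factor)
    rep = _occurrences(counts, db.repeat_kmers)
    norm = _occurrences(counts, db.norm_kmers)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    upper = max(int(rep.max(initial=1)), int(norm.max(initial=1))) + 2
    bins = np.arange(0, upper + 1) - 0.5
    ax.hist(norm, bins=bins, alpha=0.6, label="normalization k-mers", color="#4878d0")
    ax.hist(rep, bins=bins, alpha=0.6, label="repeat k-mers", color="#d65f5f")
    ax.axvline(est.mean_norm, color="#1f3f8f", ls="--", lw=1.2,
               label=f"norm mean = {est.mean_norm:.1f}")
    ax.axvline(est.mean_repeat, color="#8f1f1f", ls="--", lw=1.2,
               label=f"repeat mean = {est.mean_repeat:.1f}")
    ax.set_xlabel("k-mer occurrence in reads")
    ax.set_ylabel("number of k-mers")
    ax.set_title(
        f"{counts.sample_id}: estimated copy number {est.copy_number:.2f}"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
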