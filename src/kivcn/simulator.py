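"""Diploid locus simulator with known repeat copy numbers.

Builds synthetic diploid samples around a locus template that mirrors the
real architecture of a VNTR locus: a 5' flank, a tandem array of
repeat-unit variants, a single-copy normalization region, and a 3' flank,
all on one contig.  Each simulated individual carries n1 repeat copies on
haplotype 1 and n2 on haplotype 2 (both drawn uniformly from 6–30 under
the validation protocol, so diploid truths span 12–60), with each copy
drawn uniformly with replacement from the template's unit variants.
Haplotype 2 additionally receives random substitutions outside the array
(default 1 per 1000 bp), emulating the heterozygous-SNP divergence of a
real second haplotype.

Reads are 150 bp paired-end with Normal insert sizes, uniform fragment
placement per haplotype, and independent per-base substitution errors at
rate 10^(-Q/10) where Q is drawn per base from a truncated
Normal(mean_quality, 3).  "Coverage c" means expected depth per haplotype:
each haplotype of length L receives round(c·L / (2·read_length)) read
pairs.  Everything is deterministic under a fixed seed.

``run_condition`` drives the full loop — simulate, count, estimate — and
returns a per-sample truth/estimate table; ``summarize_condition`` reduces
it to R², slope and intercept of the estimate-on-truth regression.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counting import count_encoded_reads
from .estimation import (
    DEFAULT_DIPLOID_FACTOR,
    NoNormalizationSignalError,
    estimate_copy_number,
)
from .kmerdb import KmerDatabase, build_database
from .kmers import decode_bases
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

# Locus geometry defaults mirror the real KIV-2 locus: ~5.5 kb repeat units
# and ~100 kb of single-copy normalization sequence (the LPA gene minus the
# repeat array).  Region lengths set the number of reads informing each
# occurrence mean, hence the estimation noise floor; shrinking them is fine
# for unit tests but degrades copy-number precision at low coverage.
DEFAULT_UNIT_LENGTH = 5_500
DEFAULT_N_UNITS = 6
DEFAULT_UNIT_DIVERGENCE = 0.005  # expected pairwise divergence between variants
DEFAULT_NORM_LENGTH = 100_000
DEFAULT_FLANK_LENGTH = 5_000
DEFAULT_SNP_RATE = 0.001  # haplotype-2 substitutions outside the array, per bp
DEFAULT_READ_LENGTH = 150
DEFAULT_INSERT_MEAN = 400.0
DEFAULT_INSERT_SD = 60.0
QUALITY_SD = 3.0
MIN_QUALITY, MAX_QUALITY = 2, 41
COPY_RANGE = (6, 30)  # per-haplotype copy-number range of the protocol

_PHRED_OFFSET = 33


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def make_repeat_units(
    rng: np.random.Generator,
    n_units: int = DEFAULT_N_UNITS,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    divergence: float = DEFAULT_UNIT_DIVERGENCE,
) -> list[np.ndarray]:
    """Generate repeat-unit variants as diverged copies of one ancestor.

    Each variant receives substitutions at rate ``divergence / 2`` from the
    common ancestor, giving the stated expected *pairwise* divergence
    between variants.
    """
    base = _random_seq_codes(rng, unit_length)
    units = []
    for _ in range(n_units):
        unit = base.copy()
        hit = rng.random(unit_length) < divergence / 2
        idx = np.flatnonzero(hit)
        unit[idx] = (unit[idx] + rng.integers(1, 4, size=idx.size)) % 4
        units.append(unit)
    return units


@dataclass
class LocusTemplate:
    """Reference locus: 5' flank | repeat array (all unit variants) | normalization | 3' flank."""

    chrom: str
    flank5: np.ndarray
    units: list[np.ndarray]
    norm: np.ndarray
    flank3: np.ndarray

    @property
    def reference_codes(self) -> np.ndarray:
        return np.concatenate([self.flank5, *self.units, self.norm, self.flank3])

    @property
    def reference(self) -> dict[str, str]:
        return {self.chrom: decode_bases(self.reference_codes)}

    @property
    def array_span(self) -> tuple[int, int]:
        start = len(self.flank5)
        return start, start + sum(len(u) for u in self.units)

    @property
    def repeat_regions(self) -> list[GenomicRegion]:
        s, e = self.array_span
        return [GenomicRegion(self.chrom, s, e, "repeat")]

    @property
    def norm_regions(self) -> list[GenomicRegion]:
        _, e = self.array_span
        return [GenomicRegion(self.chrom, e, e + len(self.norm), "normalization")]

    def build_database(self, k: int = 31, **kwargs) -> KmerDatabase:
        """Database over this template's reference and regions."""
        return build_database(
            self.reference, self.repeat_regions, self.norm_regions, k=k, **kwargs
        )


def make_locus_template(
    rng: np.random.Generator,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    n_units: int = DEFAULT_N_UNITS,
    divergence: float = DEFAULT_UNIT_DIVERGENCE,
    norm_length: int = DEFAULT_NORM_LENGTH,
    flank_length: int = DEFAULT_FLANK_LENGTH,
    chrom: str = "locus",
) -> LocusTemplate:
    return LocusTemplate(
        chrom=chrom,
        flank5=_random_seq_codes(rng, flank_length),
        units=make_repeat_units(rng, n_units, unit_length, divergence),
        norm=_random_seq_codes(rng, norm_length),
        flank3=_random_seq_codes(rng, flank_length),
    )


@dataclass
class SimulatedSample:
    """A diploid individual with a known (truth) total repeat copy number."""

    sample_id: str
    hap1_codes: np.ndarray
    hap2_codes: np.ndarray
    n_copies_h1: int
    n_copies_h2: int
    coverage: float | None = None
    mean_quality: float | None = None
    seed: int | None = None

    @property
    def truth_total(self) -> int:
        return self.n_copies_h1 + self.n_copies_h2

    @property
    def haplotype_sequences(self) -> tuple[str, str]:
        return decode_bases(self.hap1_codes), decode_bases(self.hap2_codes)


def build_diploid_locus(
    template: LocusTemplate,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    snp_rate: float = DEFAULT_SNP_RATE,
    sample_id: str = "sim",
) -> SimulatedSample:
    """Construct the two haplotype sequences of one simulated individual.

    Haplotype i replaces the template's repeat array with n_i unit copies
    drawn uniformly with replacement from the template variants; haplotype 2
    additionally receives substitutions at ``snp_rate`` per base outside the
    array.  The truth label is fixed here, before any read is generated.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("per-haplotype copy numbers must be >= 1")
    if not template.units:
        raise ValueError("locus template has no repeat-array units")

    def hap(n_copies: int, apply_snps: bool) -> np.ndarray:
        choices = rng.integers(0, len(template.units), size=n_copies)
        array = np.concatenate([template.units[i] for i in choices])
        flank5, norm, flank3 = (
            template.flank5.copy(),
            template.norm.copy(),
            template.flank3.copy(),
        )
        if apply_snps and snp_rate > 0:
            for seg in (flank5, norm, flank3):
                hit = np.flatnonzero(rng.random(len(seg)) < snp_rate)
                seg[hit] = (seg[hit] + rng.integers(1, 4, size=hit.size)) % 4
        return np.concatenate([flank5, array, norm, flank3])

    return SimulatedSample(
        sample_id=sample_id,
        hap1_codes=hap(n1, apply_snps=False),
        hap2_codes=hap(n2, apply_snps=True),
        n_copies_h1=n1,
        n_copies_h2=n2,
    )


@dataclass
class ReadSet:
    """Paired-end reads (2-bit base codes) with per-base Phred qualities."""

    r1: np.ndarray  # (n_pairs, read_length) uint8 base codes
    r2: np.ndarray
    q1: np.ndarray  # (n_pairs, read_length) uint8 Phred scores
    q2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def matrices(self) -> list[np.ndarray]:
        return [self.r1, self.r2]

    def sequences(self) -> list[str]:
        return [decode_bases(row) for row in self.r1] + [
            decode_bases(row) for row in self.r2
        ]

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path,
                    sample_id: str = "sim") -> None:
        for path, reads, quals, mate in (
            (r1_path, self.r1, self.q1, 1),
            (r2_path, self.r2, self.q2, 2),
        ):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(path, "wt") as fh:
                for i in range(reads.shape[0]):
                    seq = decode_bases(reads[i])
                    qual = (quals[i] + _PHRED_OFFSET).tobytes().decode("ascii")
                    fh.write(f"@{sample_id}_pair{i}/{mate}\n{seq}\n+\n{qual}\n")


def _simulate_haplotype_reads(
    hap: np.ndarray,
    coverage: float,
    mean_quality: float,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    rng: np.random.Generator,
    apply_errors: bool = True,
) -> ReadSet:
    L = len(hap)
    n_pairs = int(round(coverage * L / (2 * read_length)))
    if n_pairs == 0:
        empty = np.empty((0, read_length), dtype=np.uint8)
        return ReadSet(empty, empty.copy(), empty.copy(), empty.copy())
    insert = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)), read_length, L
    ).astype(np.int64)
    start = np.floor(rng.random(n_pairs) * (L - insert + 1)).astype(np.int64)
    offsets = np.arange(read_length, dtype=np.int64)
    r1 = hap[start[:, None] + offsets]
    # mate 2 reads inward from the far end of the fragment: reverse complement
    r2_fwd = hap[(start + insert - read_length)[:, None] + offsets]
    r2 = (3 - r2_fwd[:, ::-1]).astype(np.uint8)

    def qualities(shape: tuple[int, int]) -> np.ndarray:
        q = np.rint(rng.normal(mean_quality, QUALITY_SD, size=shape))
        return np.clip(q, MIN_QUALITY, MAX_QUALITY).astype(np.uint8)

    def substitute(reads: np.ndarray, quals: np.ndarray) -> np.ndarray:
        perr = 10.0 ** (-quals.astype(np.float64) / 10.0)
        err = rng.random(reads.shape) < perr
        out = reads.copy()
        n_err = int(err.sum())
        if n_err:
            out[err] = (out[err] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
        return out

    q1, q2 = qualities(r1.shape), qualities(r2.shape)
    if not apply_errors:  # error-free reads with the same fragment layout
        return ReadSet(r1, r2, q1, q2)
    return ReadSet(substitute(r1, q1), substitute(r2, q2), q1, q2)


def simulate_reads(
    sample: SimulatedSample,
    coverage: float,
    mean_quality: float,
    rng: np.random.Generator,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    apply_errors: bool = True,
) -> ReadSet:
    """Simulate paired-end reads from both haplotypes of a sample.

    Records the condition on the sample object; the truth label is never
    touched.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 2 <= mean_quality <= 45:
        raise ValueError("mean_quality must be in [2, 45]")
    parts = [
        _simulate_haplotype_reads(
            hap, coverage, mean_quality, read_length, insert_mean, insert_sd,
            rng, apply_errors=apply_errors,
        )
        for hap in (sample.hap1_codes, sample.hap2_codes)
    ]
    sample.coverage = coverage
    sample.mean_quality = mean_quality
    return ReadSet(
        r1=np.vstack([p.r1 for p in parts]),
        r2=np.vstack([p.r2 for p in parts]),
        q1=np.vstack([p.q1 for p in parts]),
        q2=np.vstack([p.q2 for p in parts]),
    )


def expected_read_pairs(coverage: float, hap_length: int,
                        read_length: int = DEFAULT_READ_LENGTH) -> int:
    """Pairs per haplotype so that expected per-haplotype depth = coverage."""
    return int(round(coverage * hap_length / (2 * read_length)))


def run_condition(
    db: KmerDatabase,
    template: LocusTemplate,
    coverage: float,
    mean_quality: float,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    snp_rate: float = DEFAULT_SNP_RATE,
    copy_range: tuple[int, int] = COPY_RANGE,
    diploid_factor: float = DEFAULT_DIPLOID_FACTOR,
    read_length: int = DEFAULT_READ_LENGTH,
) -> pd.DataFrame:
    """Simulate, count and estimate ``n_samples`` individuals at one condition.

    Returns a per-sample table with truth and estimate; samples whose
    estimation fails are recorded with a missing estimate and excluded from
    downstream metrics (with a warning).
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows = []
    lo, hi = copy_range
    for i, child in enumerate(ss.spawn(n_samples)):
        rng = np.random.default_rng(child)
        n1, n2 = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
        sample = build_diploid_locus(
            template, n1, n2, rng, snp_rate=snp_rate, sample_id=f"sim{i:03d}"
        )
        reads = simulate_reads(
            sample, coverage, mean_quality, rng, read_length=read_length
        )
        counts = count_encoded_reads(reads.matrices(), db, sample_id=sample.sample_id)
        try:
            est = estimate_copy_number(counts, db, diploid_factor=diploid_factor)
            estimate = est.copy_number
            mean_repeat, mean_norm = est.mean_repeat, est.mean_norm
        except NoNormalizationSignalError as exc:
            logger.warning("estimation failed for %s: %s", sample.sample_id, exc)
            estimate = mean_repeat = mean_norm = np.nan
        rows.append(
            {
                "sample_id": sample.sample_id,
                "coverage": coverage,
                "mean_quality": mean_quality,
                "n_copies_h1": n1,
                "n_copies_h2": n2,
                "truth_total": sample.truth_total,
                "estimate": estimate,
                "mean_repeat": mean_repeat,
                "mean_norm": mean_norm,
            }
        )
    return pd.DataFrame(rows)


def summarize_condition(results: pd.DataFrame) -> dict[str, float]:
    """R², OLS slope and intercept of estimate on truth for one condition."""
    ok = results.dropna(subset=["estimate"])
    n_failed = len(results) - len(ok)
    if n_failed:
        logger.warning("%d samples excluded from metrics (estimation failed)", n_failed)
    if len(ok) < 3:
        raise ValueError("need at least 3 successful samples to summarize")
    fit = stats.linregress(ok["truth_total"], ok["estimate"])
    return {
        "n": int(len(ok)),
        "n_failed": int(n_failed),
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def run_experiment(
    db: KmerDatabase,
    template: LocusTemplate,
    conditions: list[tuple[float, float]],
    n_samples: int,
    seed: int,
    shared_truths: bool = False,
    **kwargs,
) -> tuple[pd.DataFrame, list[dict[str, float]]]:
    """Run a list of (coverage, mean_quality) conditions.

    With ``shared_truths`` the same per-sample seed sequence (hence the same
    truth copy numbers and haplotypes) is reused across conditions; otherwise
    each condition draws independent individuals.
    """
    tables, metrics = [], []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(conditions))
    for i, (coverage, quality) in enumerate(conditions):
        cond_seed = root if shared_truths else children[i]
        tbl = run_condition(
            db, template, coverage, quality, n_samples, cond_seed, **kwargs
        )
        summary = summarize_condition(tbl)
        summary.update({"coverage": coverage, "mean_quality": quality})
        tables.append(tbl)
        metrics.append(summary)
    return pd.concat(tables, ignore_index=True), metrics
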