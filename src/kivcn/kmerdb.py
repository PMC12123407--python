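"""Repeat- and normalization-specific k-mer database construction.

The database is built from a reference genome and two BED region sets with a
five-step cascade:

1. enumerate canonical k-mers whose windows lie entirely inside each region
   set (repeat array vs normalization region);
2. keep k-mers whose in-region occurrence equals the expected reference
   multiplicity exactly (6 for the repeat set when the reference carries six
   repeat units, 1 for single-copy normalization k-mers);
3. discard k-mers that occur anywhere else in the supplied reference;
4. discard k-mers shared between the two sets;
5. write both sets as FASTA and TSV (lexicographically sorted, so rebuilds
   are byte-identical).

The result is a pair of disjoint canonical-k-mer sets, each k-mer occurring
in the reference exactly its expected number of times and only inside its
declared regions — the specificity that lets raw occurrence means in a
sample's reads be read as copy number after depth normalization.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kmers import (
    canonical_codes,
    canonicalize,
    code_to_kmer,
    encode_bases,
    kmer_to_code,
)
from .regions import GenomicRegion, read_bed, read_fasta

logger = logging.getLogger(__name__)

DEFAULT_K = 31
DEFAULT_REPEAT_MULTIPLICITY = 6
DEFAULT_NORM_MULTIPLICITY = 1


class DatabaseBuildError(RuntimeError):
    """Raised when a filter stage empties a k-mer set."""


@dataclass
class KmerDatabase:
    """Disjoint repeat / normalization canonical k-mer sets.

    ``repeat_multiplicity`` and ``norm_multiplicity`` record the expected
    per-reference occurrence each retained k-mer satisfied at build time.
    """

    k: int
    repeat_kmers: frozenset[str]
    norm_kmers: frozenset[str]
    repeat_multiplicity: int = DEFAULT_REPEAT_MULTIPLICITY
    norm_multiplicity: int = DEFAULT_NORM_MULTIPLICITY
    _sorted_codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        shared = self.repeat_kmers & self.norm_kmers
        if shared:
            raise ValueError(f"{len(shared)} k-mers shared between the two sets")
        for kmer in self.all_kmers:
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} does not match k={self.k}")
            if canonicalize(kmer) != kmer:
                raise ValueError(f"k-mer {kmer!r} is not in canonical form")

    @property
    def all_kmers(self) -> frozenset[str]:
        return self.repeat_kmers | self.norm_kmers

    def sorted_codes(self) -> np.ndarray:
        """Sorted uint64 codes over the union of both sets (cached)."""
        if self._sorted_codes is None:
            codes = np.fromiter(
                (kmer_to_code(km) for km in self.all_kmers),
                dtype=np.uint64,
                count=len(self.repeat_kmers) + len(self.norm_kmers),
            )
            codes.sort()
            self._sorted_codes = codes
        return self._sorted_codes

    # -- persistence: FASTA (headers = running index + set label) and TSV ----

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, kmers, mult in (
            ("repeat", self.repeat_kmers, self.repeat_multiplicity),
            ("norm", self.norm_kmers, self.norm_multiplicity),
        ):
            ordered = sorted(kmers)
            with open(outdir / f"{name}_kmers.fasta", "w") as fa:
                for i, km in enumerate(ordered):
                    fa.write(f">{name}_{i:06d}\n{km}\n")
            with open(outdir / f"{name}_kmers.tsv", "w") as tsv:
                for km in ordered:
                    tsv.write(f"{km}\t{mult}\n")
        with open(outdir / "db.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "k": self.k,
                    "repeat_multiplicity": self.repeat_multiplicity,
                    "norm_multiplicity": self.norm_multiplicity,
                    "n_repeat_kmers": len(self.repeat_kmers),
                    "n_norm_kmers": len(self.norm_kmers),
                },
                fh,
            )

    @classmethod
    def load(cls, dbdir: str | Path) -> "KmerDatabase":
        dbdir = Path(dbdir)
        with open(dbdir / "db.yaml") as fh:
            meta = yaml.safe_load(fh)
        sets: dict[str, frozenset[str]] = {}
        for name in ("repeat", "norm"):
            with open(dbdir / f"{name}_kmers.tsv") as tsv:
                sets[name] = frozenset(line.split("\t")[0] for line in tsv if line.strip())
        return cls(
            k=meta["k"],
            repeat_kmers=sets["repeat"],
            norm_kmers=sets["norm"],
            repeat_multiplicity=meta["repeat_multiplicity"],
            norm_multiplicity=meta["norm_multiplicity"],
        )


def extract_region_kmers(
    reference: dict[str, str],
    regions: list[GenomicRegion],
    k: int,
) -> Counter[str]:
    """Count canonical k-mers whose windows lie entirely inside the regions.

    Windows containing ambiguous (non-ACGT) bases are skipped; counts sum over
    all listed regions.  Boundary-spanning windows (partially outside a
    region) are not counted.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts: Counter[str] = Counter()
    any_window = False
    for region in regions:
        region.validate_against(reference)
        seq = reference[region.chrom][region.start : region.end]
        codes, valid = canonical_codes(encode_bases(seq), k)
        if valid.any():
            any_window = True
        uniq, n = np.unique(codes[valid], return_counts=True)
        for code, c in zip(uniq, n):
            counts[code_to_kmer(int(code), k)] += int(c)
    if not any_window:
        logger.warning("k=%d exceeds every region length; no k-mers extracted", k)
    return counts


def filter_by_multiplicity(counts: Counter[str] | dict[str, int], expected: int) -> set[str]:
    """K-mers observed exactly `expected` times (strict equality)."""
    if expected < 1:
        raise ValueError(f"expected multiplicity must be >= 1, got {expected}")
    return {km for km, c in counts.items() if c == expected}


def exclude_background(
    kmers: set[str],
    reference: dict[str, str],
    regions: list[GenomicRegion],
    k: int,
) -> set[str]:
    """Drop k-mers with any canonical occurrence outside the listed regions.

    "Outside" means any window of the supplied reference that does not lie
    entirely inside one of the regions — including windows straddling a
    region boundary.
    """
    if not kmers:
        return set()
    genome_counts: Counter[str] = Counter()
    for name, seq in reference.items():
        codes, valid = canonical_codes(encode_bases(seq), k)
        uniq, n = np.unique(codes[valid], return_counts=True)
        for code, c in zip(uniq, n):
            genome_counts[code_to_kmer(int(code), k)] += int(c)
    inside = extract_region_kmers(reference, regions, k)
    return {km for km in kmers if genome_counts[km] - inside.get(km, 0) == 0}


def remove_shared(repeat_kmers: set[str], norm_kmers: set[str]) -> tuple[set[str], set[str]]:
    """Drop the intersection from both sets; outputs are disjoint."""
    shared = repeat_kmers & norm_kmers
    if shared:
        logger.info("discarding %d k-mers shared between sets", len(shared))
    out_repeat = repeat_kmers - shared
    out_norm = norm_kmers - shared
    if not out_repeat or not out_norm:
        logger.warning(
            "empty k-mer set after shared-k-mer removal "
            "(repeat=%d, norm=%d): database unusable downstream",
            len(out_repeat),
            len(out_norm),
        )
    return out_repeat, out_norm


def build_database(
    reference: dict[str, str],
    repeat_regions: list[GenomicRegion],
    norm_regions: list[GenomicRegion],
    k: int = DEFAULT_K,
    repeat_multiplicity: int = DEFAULT_REPEAT_MULTIPLICITY,
    norm_multiplicity: int = DEFAULT_NORM_MULTIPLICITY,
    outdir: str | Path | None = None,
) -> KmerDatabase:
    """Run the full filter cascade and (optionally) persist the database.

    Raises :class:`DatabaseBuildError` with per-stage retention counts if
    either set ends up empty.
    """
    if not repeat_regions or not norm_regions:
        raise ValueError("both region lists must be non-empty")
    all_regions = repeat_regions + norm_regions

    stage: dict[str, tuple[int, int]] = {}
    repeat_counts = extract_region_kmers(reference, repeat_regions, k)
    norm_counts = extract_region_kmers(reference, norm_regions, k)
    stage["extracted"] = (len(repeat_counts), len(norm_counts))

    repeat_set = filter_by_multiplicity(repeat_counts, repeat_multiplicity)
    norm_set = filter_by_multiplicity(norm_counts, norm_multiplicity)
    stage["multiplicity"] = (len(repeat_set), len(norm_set))

    repeat_set = exclude_background(repeat_set, reference, all_regions, k)
    norm_set = exclude_background(norm_set, reference, all_regions, k)
    stage["background"] = (len(repeat_set), len(norm_set))

    repeat_set, norm_set = remove_shared(repeat_set, norm_set)
    stage["shared"] = (len(repeat_set), len(norm_set))

    logger.info("database build stages (repeat, norm): %s", stage)
    if not repeat_set or not norm_set:
        raise DatabaseBuildError(
            "empty k-mer set after filtering; retained (repeat, norm) per "
            f"stage: {stage}"
        )
    db = KmerDatabase(
        k=k,
        repeat_kmers=frozenset(repeat_set),
        norm_kmers=frozenset(norm_set),
        repeat_multiplicity=repeat_multiplicity,
        norm_multiplicity=norm_multiplicity,
    )
    if outdir is not None:
        db.save(outdir)
    return db


def build_database_from_files(
    reference_fasta: str | Path,
    repeat_bed: str | Path,
    norm_bed: str | Path,
    k: int = DEFAULT_K,
    repeat_multiplicity: int = DEFAULT_REPEAT_MULTIPLICITY,
    norm_multiplicity: int = DEFAULT_NORM_MULTIPLICITY,
    outdir: str | Path | None = None,
) -> KmerDatabase:
    """File-based wrapper: FASTA reference + two BED files."""
    reference = read_fasta(reference_fasta)
    return build_database(
        reference,
        read_bed(repeat_bed, "repeat"),
        read_bed(norm_bed, "normalization"),
        k=k,
        repeat_multiplicity=repeat_multiplicity,
        norm_multiplicity=norm_multiplicity,
        outdir=outdir,
    )
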