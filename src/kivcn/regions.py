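"""Genomic intervals and BED/FASTA input.

Regions follow the BED convention: 0-based, half-open.  Each region carries a
role label: ``repeat`` (the tandem-repeat array) or ``normalization`` (a
single-copy interval used as the depth calibrator).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pysam

REGION_LABELS = ("repeat", "normalization")


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.label not in REGION_LABELS:
            raise ValueError(
                f"label must be one of {REGION_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, reference: dict[str, str]) -> None:
        """Raise if the region falls outside the named reference sequence."""
        if self.chrom not in reference:
            raise ValueError(f"region {self} names unknown sequence {self.chrom!r}")
        if self.end > len(reference[self.chrom]):
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end} extends past the "
                f"end of {self.chrom} ({len(reference[self.chrom])} bp)"
            )


def read_bed(path: str | Path, label: str) -> list[GenomicRegion]:
    """Read a 3+ column BED file into labeled regions.

    Only the first three columns are used; comment/track/blank lines are
    skipped.  Transparently handles gzip.
    """
    path = Path(path)
    opener = gzip.open if path.open("rb").read(2) == b"\x1f\x8b" else open
    regions: list[GenomicRegion] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            regions.append(GenomicRegion(fields[0], start, end, label))
    if not regions:
        raise ValueError(f"{path}: no regions found")
    return regions


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped) FASTA file as {name: sequence}."""
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence.upper()
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(regions: list[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
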