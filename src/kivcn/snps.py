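"""K-mer based SNP presence/absence calling.

For variants of interest (e.g. Lp(a)-modulating SNPs inside or near the
repeat), the user supplies reference-allele and alternative-allele k-mers
per rsid.  Panel k-mers are counted in the same pass as the database
k-mers; a sample is called a *carrier* of a variant when at least
``min_alt_count`` reads support at least one alternative k-mer.  No
zygosity is inferred — detection is presence/absence only, which is the
appropriate resolution inside a multi-copy repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .counting import SampleKmerCounts
from .kmers import canonicalize

DEFAULT_MIN_ALT_COUNT = 1


@dataclass(frozen=True)
class SnpPanelEntry:
    rsid: str
    ref_kmers: frozenset[str]
    alt_kmers: frozenset[str]

    def __post_init__(self) -> None:
        if self.ref_kmers & self.alt_kmers:
            raise ValueError(f"{self.rsid}: ref and alt k-mer sets overlap")


@dataclass
class SnpKmerPanel:
    entries: list[SnpPanelEntry]

    @property
    def all_kmers(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.entries:
            out |= e.ref_kmers | e.alt_kmers
        return frozenset(out)


@dataclass
class SnpCall:
    rsid: str
    ref_occurrences: dict[str, int]
    alt_occurrences: dict[str, int]
    carrier: bool


def load_snp_panel(path: str | Path, k: int | None = None) -> SnpKmerPanel:
    """Load a panel TSV with columns rsid, allele (ref|alt), kmer.

    One k-mer per line; k-mers are canonicalized on load.  If ``k`` is
    given, every k-mer must have that length (it must match the counting
    database's k to be countable in the same pass).
    """
    ref: dict[str, set[str]] = {}
    alt: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (rsid, allele, kmer)")
            rsid, allele, kmer = fields
            if allele not in ("ref", "alt"):
                raise ValueError(f"{path}:{lineno}: allele must be 'ref' or 'alt'")
            if k is not None and len(kmer) != k:
                raise ValueError(
                    f"{path}:{lineno}: k-mer length {len(kmer)} does not match k={k}"
                )
            if rsid not in ref:
                ref[rsid] = set()
                alt[rsid] = set()
                order.append(rsid)
            (ref if allele == "ref" else alt)[rsid].add(canonicalize(kmer))
    entries = [
        SnpPanelEntry(rsid, frozenset(ref[rsid]), frozenset(alt[rsid]))
        for rsid in order
    ]
    if not entries:
        raise ValueError(f"{path}: empty SNP panel")
    return SnpKmerPanel(entries)


def call_snps(
    counts: SampleKmerCounts,
    panel: SnpKmerPanel,
    min_alt_count: int = DEFAULT_MIN_ALT_COUNT,
) -> list[SnpCall]:
    """Report per-k-mer occurrences and carrier status for each panel SNP.

    carrier ⇔ at least one alternative k-mer has count >= min_alt_count.
    With the default threshold of 1 a single (possibly erroneous) k-mer
    observation makes a carrier; raise the threshold for noisy libraries.
    """
    calls = []
    for entry in panel.entries:
        ref_occ = {km: counts.counts.get(km, 0) for km in sorted(entry.ref_kmers)}
        alt_occ = {km: counts.counts.get(km, 0) for km in sorted(entry.alt_kmers)}
        carrier = sum(c >= min_alt_count for c in alt_occ.values()) >= 1
        calls.append(SnpCall(entry.rsid, ref_occ, alt_occ, carrier))
    return calls


def format_snp_calls(calls: list[SnpCall]) -> str:
    lines = ["rsid\tcarrier\tref_occurrences\talt_occurrences"]
    for c in calls:
        ref = ",".join(f"{km}:{n}" for km, n in c.ref_occurrences.items()) or "-"
        alt = ",".join(f"{km}:{n}" for km, n in c.alt_occurrences.items()) or "-"
        lines.append(f"{c.rsid}\t{'yes' if c.carrier else 'no'}\t{ref}\t{alt}")
    return "\n".join(lines)
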