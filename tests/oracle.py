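"""Independent brute-force reference implementations used as test oracles.

Pure-Python, string-based, deliberately naive: these share no code with the
package's vectorized/jitted paths.
"""

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def canon(kmer: str) -> str:
    r = rc(kmer)
    return kmer if kmer <= r else r


def window_tally(seq: str, k: int) -> Counter:
    """Canonical k-mer counts over all windows, skipping non-ACGT windows."""
    out: Counter = Counter()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out[canon(w)] += 1
    return out


def read_tally(reads: list[str], k: int, universe: set[str]) -> dict[str, int]:
    """Naive per-read window tally restricted to a k-mer universe."""
    counts = {km: 0 for km in universe}
    for read in reads:
        for km, n in window_tally(read, k).items():
            if km in counts:
                counts[km] += n
    return counts


def brute_build(
    reference: dict[str, str],
    repeat_regions,
    norm_regions,
    k: int,
    repeat_multiplicity: int = 6,
    norm_multiplicity: int = 1,
) -> dict[str, set[str] | dict]:
    """Full reimplementation of the database filter cascade by enumeration."""

    def region_tally(regions) -> Counter:
        out: Counter = Counter()
        for r in regions:
            out.update(window_tally(reference[r.chrom][r.start : r.end], k))
        return out

    rep_counts = region_tally(repeat_regions)
    norm_counts = region_tally(norm_regions)
    stage = {"extracted": (len(rep_counts), len(norm_counts))}

    rep = {km for km, c in rep_counts.items() if c == repeat_multiplicity}
    norm = {km for km, c in norm_counts.items() if c == norm_multiplicity}
    stage["multiplicity"] = (len(rep), len(norm))

    genome: Counter = Counter()
    for seq in reference.values():
        genome.update(window_tally(seq, k))
    inside = region_tally(repeat_regions + norm_regions)
    background = {km for km in genome if genome[km] - inside.get(km, 0) > 0}
    rep -= background
    norm -= background
    stage["background"] = (len(rep), len(norm))

    shared = rep & norm
    rep, norm = rep - shared, norm - shared
    stage["shared"] = (len(rep), len(norm))
    return {"repeat": rep, "norm": norm, "stage": stage}
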