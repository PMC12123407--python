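"""Streaming k-mer counting over sample reads.

Counts occurrences of database (and optional SNP-panel) k-mers in FASTQ
reads.  Only k-mers of the fixed universe are stored, so memory stays
O(|database|) regardless of read volume.  Every length-k window of every
read is canonicalized; windows containing ambiguous bases are skipped;
base qualities are ignored — a sequencing error simply produces a k-mer
that fails to match, which is exactly the robustness the ratio estimator
relies on.

The hot path is a numba-jitted rolling-hash kernel (forward and
reverse-complement codes maintained incrementally, membership via an
open-addressing hash table); the fallback packs windows into 2-bit uint64
codes in vectorized numpy passes and resolves membership with a binary
search against the sorted universe.  Reads are batched into a single
separator-joined array either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .kmerdb import KmerDatabase
from .kmers import canonical_codes, encode_bases

logger = logging.getLogger(__name__)

_BATCH_BASES = 4_000_000  # flush threshold for the read batcher

_HASH_EMPTY = np.uint64(0xFFFFFFFFFFFFFFFF)  # codes use <= 62 bits
_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)

try:  # jitted rolling-hash kernel; the vectorized numpy path is the fallback
    import numba

    @numba.njit(nogil=True)
    def _count_kernel(bases, k, table, slot_index, hits):  # pragma: no cover
        """Rolling canonical k-mer codes + open-addressing table lookups."""
        mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
        rc_shift = np.uint64(2 * (k - 1))
        tmask = np.uint64(table.shape[0] - 1)
        empty = np.uint64(0xFFFFFFFFFFFFFFFF)
        mult = np.uint64(0x9E3779B97F4A7C15)
        fwd = np.uint64(0)
        rc = np.uint64(0)
        run = 0
        for i in range(bases.shape[0]):
            b = np.uint64(bases[i])
            if b > 3:  # ambiguous base or read separator: restart the window
                fwd = np.uint64(0)
                rc = np.uint64(0)
                run = 0
                continue
            fwd = ((fwd << np.uint64(2)) | b) & mask
            rc = (rc >> np.uint64(2)) | ((np.uint64(3) - b) << rc_shift)
            run += 1
            if run >= k:
                c = fwd if fwd < rc else rc
                j = (c * mult) >> np.uint64(40)
                j = j & tmask
                while True:
                    t = table[j]
                    if t == c:
                        hits[slot_index[j]] += 1
                        break
                    if t == empty:
                        break
                    j = (j + np.uint64(1)) & tmask

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _build_hash_table(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Open-addressing table (linear probing) over sorted uint64 codes."""
    size = 1 << max(4, int(np.ceil(np.log2(4 * max(len(codes), 1)))))
    table = np.full(size, _HASH_EMPTY, dtype=np.uint64)
    slot_index = np.zeros(size, dtype=np.int64)
    tmask = np.uint64(size - 1)
    with np.errstate(over="ignore"):  # multiplicative hashing wraps mod 2^64
        slots = ((codes * _HASH_MULT) >> np.uint64(40)) & tmask
    for i, c in enumerate(codes):
        j = slots[i]
        while table[j] != _HASH_EMPTY:
            j = (j + np.uint64(1)) & tmask
        table[j] = c
        slot_index[j] = i
    return table, slot_index


@dataclass
class SampleKmerCounts:
    """Per-sample occurrence counts over a fixed k-mer universe.

    K-mers never observed are present with count 0, so "absent" is
    representable and distinguishable from "not tracked".
    """

    sample_id: str
    counts: dict[str, int]
    n_reads_processed: int = 0
    n_bases_processed: int = 0

    def __getitem__(self, kmer: str) -> int:
        return self.counts[kmer]


class KmerUniverse:
    """Sorted-code index over the k-mers being counted (database ∪ panel)."""

    def __init__(self, k: int, kmers: Iterable[str]):
        self.k = k
        ordered = sorted(set(kmers))
        for km in ordered:
            if len(km) != k:
                raise ValueError(f"k-mer {km!r} does not have length {k}")
        if ordered:
            flat = encode_bases("".join(ordered)).reshape(len(ordered), k)
            if (flat > 3).any():
                bad = ordered[int(np.argmax((flat > 3).any(axis=1)))]
                raise ValueError(f"ambiguous base in k-mer {bad!r}")
            codes = np.zeros(len(ordered), dtype=np.uint64)
            for j in range(k):
                codes = (codes << np.uint64(2)) | flat[:, j].astype(np.uint64)
        else:
            codes = np.empty(0, dtype=np.uint64)
        order = np.argsort(codes)
        self.codes = codes[order]
        self.kmers = [ordered[i] for i in order]
        self._table: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.kmers)

    @classmethod
    def from_database(
        cls, db: KmerDatabase, extra_kmers: Iterable[str] = ()
    ) -> "KmerUniverse":
        extra = set(extra_kmers)
        clash = extra & db.all_kmers
        if clash:
            raise ValueError(
                f"{len(clash)} panel k-mers collide with database k-mers "
                f"(e.g. {sorted(clash)[0]}): ambiguous interpretation"
            )
        if not extra:  # memoize the plain database universe on the db object
            cached = getattr(db, "_universe", None)
            if cached is None:
                cached = cls(db.k, db.all_kmers)
                object.__setattr__(db, "_universe", cached)
            return cached
        return cls(db.k, db.all_kmers | extra)

    def count_windows(self, bases: np.ndarray) -> np.ndarray:
        """Tally universe hits over all valid windows of a base-code array."""
        if _HAVE_NUMBA:
            hits = np.zeros(len(self.codes), dtype=np.int64)
            if len(bases) >= self.k and len(self.codes):
                if self._table is None:
                    self._table = _build_hash_table(self.codes)
                _count_kernel(bases, self.k, *self._table, hits)
            return hits
        return self._count_windows_numpy(bases)

    def _count_windows_numpy(self, bases: np.ndarray) -> np.ndarray:
        codes, valid = canonical_codes(bases, self.k)
        cand = codes[valid]
        hits = np.zeros(len(self.codes), dtype=np.int64)
        if cand.size and len(self.codes):
            idx = np.minimum(np.searchsorted(self.codes, cand), len(self.codes) - 1)
            matched = self.codes[idx] == cand
            hits += np.bincount(idx[matched], minlength=len(self.codes))
        return hits


class _ReadBatcher:
    """Accumulates encoded reads, separator-joined, and flushes counts."""

    def __init__(self, universe: KmerUniverse):
        self.universe = universe
        self.hits = np.zeros(len(universe), dtype=np.int64)
        self._chunks: list[np.ndarray] = []
        self._pending = 0
        self._sep = np.array([4], dtype=np.uint8)
        self.n_reads = 0
        self.n_bases = 0

    def add(self, encoded: np.ndarray) -> None:
        self._chunks.append(encoded)
        self._chunks.append(self._sep)
        self._pending += len(encoded) + 1
        self.n_reads += 1
        self.n_bases += len(encoded)
        if self._pending >= _BATCH_BASES:
            self.flush()

    def add_sequence(self, seq: str) -> None:
        self.add(encode_bases(seq))

    def flush(self) -> None:
        if self._chunks:
            self.hits += self.universe.count_windows(np.concatenate(self._chunks))
            self._chunks = []
            self._pending = 0


def _counts_dict(universe: KmerUniverse, hits: np.ndarray) -> dict[str, int]:
    return {km: int(c) for km, c in zip(universe.kmers, hits)}


def count_sequences(
    sequences: Iterable[str],
    db: KmerDatabase,
    sample_id: str = "sample",
    extra_kmers: Iterable[str] = (),
) -> SampleKmerCounts:
    """Count universe k-mers over in-memory read sequences."""
    universe = KmerUniverse.from_database(db, extra_kmers)
    batcher = _ReadBatcher(universe)
    for seq in sequences:
        batcher.add_sequence(seq)
    batcher.flush()
    return SampleKmerCounts(
        sample_id=sample_id,
        counts=_counts_dict(universe, batcher.hits),
        n_reads_processed=batcher.n_reads,
        n_bases_processed=batcher.n_bases,
    )


def count_encoded_reads(
    read_matrices: Sequence[np.ndarray],
    db: KmerDatabase,
    sample_id: str = "sample",
    extra_kmers: Iterable[str] = (),
) -> SampleKmerCounts:
    """Count over (n_reads, read_length) uint8 base-code matrices.

    Fast path used by the simulator, avoiding any string round-trip.
    """
    universe = KmerUniverse.from_database(db, extra_kmers)
    hits = np.zeros(len(universe), dtype=np.int64)
    n_reads = n_bases = 0
    for mat in read_matrices:
        if mat.size == 0:
            continue
        sep = np.full((mat.shape[0], 1), 4, dtype=np.uint8)
        flat = np.hstack([mat, sep]).ravel()
        hits += universe.count_windows(flat)
        n_reads += mat.shape[0]
        n_bases += mat.shape[0] * mat.shape[1]
    return SampleKmerCounts(
        sample_id=sample_id,
        counts=_counts_dict(universe, hits),
        n_reads_processed=n_reads,
        n_bases_processed=n_bases,
    )


def count_kmers_in_reads(
    fastq_paths: Sequence[str | Path],
    db: KmerDatabase,
    sample_id: str = "sample",
    extra_kmers: Iterable[str] = (),
) -> SampleKmerCounts:
    """Count universe k-mers across one sample's FASTQ file(s).

    Paired-end files are treated as a flat list — pairing is irrelevant to
    counting.  Gzip compression is detected from file content.  A malformed
    record raises with the file and record index.
    """
    universe = KmerUniverse.from_database(db, extra_kmers)
    batcher = _ReadBatcher(universe)
    for path in fastq_paths:
        record_idx = 0
        try:
            with pysam.FastxFile(str(path)) as fh:
                for entry in fh:
                    record_idx += 1
                    batcher.add_sequence(entry.sequence)
        except OSError as exc:
            raise ValueError(
                f"malformed FASTQ in {path} near record {record_idx + 1}: {exc}"
            ) from exc
    batcher.flush()
    if batcher.n_reads == 0:
        logger.warning("no reads found in %s; all counts are zero", list(fastq_paths))
    return SampleKmerCounts(
        sample_id=sample_id,
        counts=_counts_dict(universe, batcher.hits),
        n_reads_processed=batcher.n_reads,
        n_bases_processed=batcher.n_bases,
    )


def write_counts(counts: SampleKmerCounts, path: str | Path) -> None:
    """Write a 2-column TSV (kmer, count); zero counts are written explicitly."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={counts.sample_id}\n")
        fh.write(f"# n_reads={counts.n_reads_processed}\n")
        fh.write(f"# n_bases={counts.n_bases_processed}\n")
        for km in sorted(counts.counts):
            fh.write(f"{km}\t{counts.counts[km]}\n")


def read_counts(path: str | Path, db: KmerDatabase | None = None) -> SampleKmerCounts:
    """Read a counts TSV back; inverse of :func:`write_counts`.

    If a database is supplied, k-mers absent from it are accepted but
    flagged in the log (permissive read).
    """
    meta = {"sample_id": Path(path).stem, "n_reads": 0, "n_bases": 0}
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key in meta:
                    meta[key] = value if key == "sample_id" else int(value)
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                counts[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
    if db is not None:
        unknown = set(counts) - db.all_kmers
        if unknown:
            logger.warning(
                "%s: %d k-mers not in the database (e.g. %s)",
                path,
                len(unknown),
                sorted(unknown)[0],
            )
    return SampleKmerCounts(
        sample_id=str(meta["sample_id"]),
        counts=counts,
        n_reads_processed=int(meta["n_reads"]),
        n_bases_processed=int(meta["n_bases"]),
    )
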