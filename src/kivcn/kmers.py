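"""Canonical k-mer primitives.

K-mers are handled strand-agnostically throughout: every k-mer is replaced by
its *canonical* form, the lexicographically smaller of the k-mer and its
reverse complement.  Reads originate from both strands, so without
canonicalization roughly half of all read k-mers would never match a
database built from one reference strand.

Two representations coexist:

* plain Python strings over ``{A, C, G, T}`` — the user-facing form;
* 2-bit packed ``uint64`` codes (A=0, C=1, G=2, T=3, most significant bits
  first) — the form used by the vectorized counter.  This caps k at 31
  (62 bits), which covers the default k = 31.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 4 marks anything that is not an unambiguous base and
# doubles as the read-separator sentinel in the batch counter.
BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a non-ACGT character."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the canonical form: min(kmer, reverse complement).

    Idempotent.  Raises :class:`AmbiguousBaseError` on non-ACGT characters
    so that callers can skip ambiguous windows.
    """
    kmer = kmer.upper()
    if any(c not in "ACGT" for c in kmer):
        raise AmbiguousBaseError(f"ambiguous base in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 base codes (4 = ambiguous)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_CODES[raw]


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases` (ambiguous codes decode to N)."""
    return _CODE_TO_BASE[np.minimum(codes, 4)].tobytes().decode("ascii")


def kmer_to_code(kmer: str) -> int:
    """Pack a k-mer string (k <= 31, ACGT only) into its 2-bit integer code."""
    if len(kmer) > MAX_K:
        raise ValueError(f"k = {len(kmer)} exceeds the packed-code limit {MAX_K}")
    code = 0
    for c in kmer.upper():
        v = BASE_CODES[ord(c)]
        if v > 3:
            raise AmbiguousBaseError(f"ambiguous base in k-mer {kmer!r}")
        code = (code << 2) | int(v)
    return code


def code_to_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit integer code back into a k-mer string."""
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def canonical_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit codes for every length-k window of a base-code array.

    Parameters
    ----------
    bases:
        uint8 base codes from :func:`encode_bases`; values > 3 mark ambiguous
        positions (and may be used as separators between concatenated reads).
    k:
        k-mer length, 2 <= k <= 31.

    Returns
    -------
    (codes, valid):
        ``codes`` is a uint64 array of length ``len(bases) - k + 1`` holding
        the canonical code of each window; ``valid`` is a boolean mask, False
        wherever the window overlaps an ambiguous position.  Codes at invalid
        positions are meaningless and must be masked by the caller.
    """
    if not 2 <= k <= MAX_K:
        raise ValueError(f"k must be in [2, {MAX_K}], got {k}")
    n = len(bases) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    b = bases.astype(np.uint64)
    three = np.uint64(3)
    # codes of all length-m windows, built by doubling: a length (m1+m2)
    # window is its first m1 bases shifted left 2*m2, OR its last m2 bases.
    # O(log k) full-array passes instead of O(k).
    fwd = b & three  # forward codes, window length m
    rev = (three - b) & three  # reverse-complement codes, window length m
    m = 1
    fwd_parts: list[tuple[np.ndarray, int]] = []
    rev_parts: list[tuple[np.ndarray, int]] = []
    rem = k
    while True:
        if rem & 1:
            fwd_parts.append((fwd, m))
            rev_parts.append((rev, m))
        rem >>= 1
        if rem == 0:
            break
        fwd = (fwd[: len(fwd) - m] << np.uint64(2 * m)) | fwd[m:]
        rev = (rev[m:] << np.uint64(2 * m)) | rev[: len(rev) - m]
        m *= 2
    # stitch the binary decomposition of k, least-significant chunk first:
    # the chunk of length m sits m_prev bases into the window
    codes_f = np.zeros(n, dtype=np.uint64)
    codes_r = np.zeros(n, dtype=np.uint64)
    off = k
    shift = 0
    for (cf, m), (cr, _) in zip(fwd_parts, rev_parts):
        off -= m
        codes_f |= cf[off : off + n] << np.uint64(2 * shift)
        codes_r = (codes_r << np.uint64(2 * m)) | cr[off : off + n]
        shift += m
    codes = np.minimum(codes_f, codes_r)
    bad = (bases > 3).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def sequence_canonical_kmers(seq: str, k: int) -> list[str]:
    """All canonical k-mers of a sequence, in window order, skipping windows
    that contain ambiguous bases.  Convenience wrapper used at database scale.
    """
    codes, valid = canonical_codes(encode_bases(seq), k)
    return [code_to_kmer(int(c), k) for c in codes[valid]]
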