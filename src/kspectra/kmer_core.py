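"""Canonical k-mer spectra.

A k-mer and its reverse complement are counted as one feature (sequencing is
strand-agnostic), so the spectrum of a read set is a dense vector indexed by
canonical k-mer *class*. With the 2-bit encoding A=0, C=1, G=2, T=3, the
lexicographically smaller member of a reverse-complement pair is also the
numerically smaller code, which makes canonicalization a vectorized
``minimum`` over integer codes. After reverse-complement collapsing the
number of classes is 2^(2k-1) for odd k and 2^(2k-1) + 2^(k-1) for even k
(even k admits self-reverse-complement palindromes, counted once).

Counting is fully vectorized: all reads are concatenated with ``N``
separators, encoded through a 256-entry lookup table, and every length-k
window free of ambiguous bases contributes one count to its canonical class.
Dense storage is practical up to k=13 (2^25 classes); the default used in
analyses is k=11.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .sequences_io import ReadSet

__all__ = [
    "KMIN",
    "KMAX",
    "canonical_class_count",
    "CanonicalIndexer",
    "Spectrum",
    "canonicalize",
    "count_spectrum",
    "normalize",
    "subtract_reads",
    "write_spectrum",
    "read_spectrum",
]

KMIN = 1
KMAX = 13  # dense vectors beyond 2^25 classes are wasteful

_BASES = "ACGT"
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)  # 4 marks invalid/ambiguous
for _i, _b in enumerate(_BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def canonical_class_count(k: int) -> int:
    """Number of k-mer classes after reverse-complement collapsing.

    2^(2k-1) for odd k; 2^(2k-1) + 2^(k-1) for even k (palindromic classes
    are their own reverse complement and are not paired).
    """
    if not 1 <= k <= 15:
        raise ValueError(f"k must be in 1..15, got {k}")
    n = 1 << (2 * k - 1)
    if k % 2 == 0:
        n += 1 << (k - 1)
    return n


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit packed k-mer codes."""
    x = codes.astype(np.int64) ^ ((1 << (2 * k)) - 1)  # complement each base
    out = np.zeros_like(x)
    for _ in range(k):  # reverse base order, two bits at a time
        out = (out << 2) | (x & 3)
        x >>= 2
    return out


class CanonicalIndexer:
    """Bijection between canonical k-mer classes and dense indices 0..n-1.

    Class indices follow the numeric (= lexicographic, A<C<G<T) order of the
    canonical representative codes. Instances are cached per k because the
    lookup table costs O(4^k) memory.
    """

    def __init__(self, k: int):
        if not KMIN <= k <= KMAX:
            raise ValueError(f"k must be in {KMIN}..{KMAX}, got {k}")
        self.k = k
        codes = np.arange(1 << (2 * k), dtype=np.int64)
        canon = np.minimum(codes, _revcomp_codes(codes, k))
        self.canonical_codes = np.unique(canon)  # sorted representatives
        self.n_classes = len(self.canonical_codes)
        assert self.n_classes == canonical_class_count(k)
        # dense map: any 2-bit code -> class index of its canonical form
        self.class_of_code = np.searchsorted(self.canonical_codes, canon).astype(
            np.int64 if self.n_classes > (1 << 31) else np.int32
        )

    @staticmethod
    @lru_cache(maxsize=4)
    def cached(k: int) -> "CanonicalIndexer":
        return CanonicalIndexer(k)

    def encode(self, kmer: str) -> int:
        """2-bit code of a k-mer string (A=0, C=1, G=2, T=3 per position)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        enc = _ENCODE_LUT[np.frombuffer(kmer.upper().encode(), dtype=np.uint8)]
        if (enc == 4).any():
            raise ValueError(f"ambiguous or invalid base in {kmer!r}")
        code = 0
        for b in enc:
            code = (code << 2) | int(b)
        return code

    def index(self, kmer: str) -> int:
        """Canonical class index of a k-mer string."""
        return int(self.class_of_code[self.encode(kmer)])

    def kmer(self, class_index: int) -> str:
        """Canonical representative string of a class index."""
        code = int(self.canonical_codes[class_index])
        return "".join(
            _BASES[(code >> (2 * (self.k - 1 - i))) & 3] for i in range(self.k)
        )


def canonicalize(kmer: str, k: int | None = None) -> int:
    """Canonical class index of ``kmer``; a k-mer and its reverse complement
    map to the same index."""
    k = len(kmer) if k is None else k
    return CanonicalIndexer.cached(k).index(kmer)


@dataclass
class Spectrum:
    """Dense canonical k-mer spectrum of one sample.

    ``counts`` has length ``canonical_class_count(k)``; ``total_kmers`` is
    the number of k-mer windows observed before normalization.
    """

    k: int
    counts: np.ndarray
    normalized: bool
    total_kmers: int
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        expected = canonical_class_count(self.k)
        if self.counts.shape != (expected,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match the "
                f"{expected} canonical classes for k={self.k}"
            )
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1")

    @property
    def frequencies(self) -> np.ndarray:
        if self.normalized:
            return self.counts
        return self.counts / self.counts.sum()


def _encode_concatenated(reads: ReadSet) -> np.ndarray:
    joined = "N".join(r.bases for r in reads)
    return _ENCODE_LUT[np.frombuffer(joined.encode(), dtype=np.uint8)]


def count_spectrum(reads: ReadSet, k: int = 11, label: str = "") -> Spectrum:
    """Count canonical k-mers over all reads into an unnormalized spectrum.

    Every length-k window consisting only of A/C/G/T contributes one count;
    windows containing N are skipped; reads shorter than k contribute
    nothing.
    """
    if len(reads) == 0:
        raise ValueError("cannot build a spectrum from an empty read set")
    indexer = CanonicalIndexer.cached(k)  # validates k range

    enc = _encode_concatenated(reads)
    n_windows = len(enc) - k + 1
    counts = np.zeros(indexer.n_classes, dtype=np.float64)
    if n_windows <= 0:
        return Spectrum(k, counts, False, 0, label)

    bad_cum = np.zeros(len(enc) + 1, dtype=np.int32)
    np.cumsum(enc == 4, dtype=np.int32, out=bad_cum[1:])
    valid = bad_cum[k:] == bad_cum[:-k]  # window has no N / separator

    # 2-bit pack each window; codes fit int32 for k <= 13 (2k <= 26 bits)
    safe = np.where(enc == 4, 0, enc).astype(np.int32)
    codes = safe[:n_windows].copy()
    for j in range(1, k):
        codes <<= 2
        codes |= safe[j : j + n_windows]

    class_idx = indexer.class_of_code[codes[valid]]
    counts += np.bincount(class_idx, minlength=indexer.n_classes)
    return Spectrum(k, counts, False, int(valid.sum()), label)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale counts to sum to 1. Idempotent; errors on an all-zero spectrum."""
    total = spectrum.counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    if spectrum.normalized:
        return spectrum
    return replace(spectrum, counts=spectrum.counts / total, normalized=True)


def subtract_reads(spectrum: Spectrum, reads: ReadSet, k: int) -> Spectrum:
    """Subtract the canonical k-mer counts of ``reads`` from an unnormalized
    spectrum, flooring at zero.

    Used to remove a designated component (e.g. a dominant phage) from a
    sample's spectrum before re-normalizing and recomputing dissimilarities.
    """
    if spectrum.normalized:
        raise ValueError("subtract_reads requires an unnormalized spectrum")
    if k != spectrum.k:
        raise ValueError(f"k mismatch: spectrum k={spectrum.k}, requested {k}")
    if len(reads) == 0:
        return spectrum
    sub = count_spectrum(reads, k)
    counts = np.maximum(spectrum.counts - sub.counts, 0.0)
    if not counts.any():
        raise ValueError("subtraction left an all-zero spectrum")
    return replace(
        spectrum,
        counts=counts,
        total_kmers=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# Spectrum I/O: a human-readable TSV of nonzero classes, and a compact binary
# dump of the full dense vector.

_BINARY_MAGIC = b"KSPC"


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str = "tsv") -> Path:
    path = Path(path)
    if format == "tsv":
        indexer = CanonicalIndexer.cached(spectrum.k)
        with open(path, "wt") as fh:
            fh.write(f"#k={spectrum.k}\n")
            fh.write(f"#total={spectrum.total_kmers}\n")
            fh.write(f"#normalized={str(spectrum.normalized).lower()}\n")
            fh.write(f"#label={spectrum.label}\n")
            for idx in np.nonzero(spectrum.counts)[0]:
                fh.write(f"{indexer.kmer(int(idx))}\t{float(spectrum.counts[idx])!r}\n")
    elif format == "binary":
        with open(path, "wb") as fh:
            label = spectrum.label.encode()
            fh.write(_BINARY_MAGIC)
            fh.write(
                struct.pack(
                    "<iiqqi",
                    spectrum.k,
                    int(spectrum.normalized),
                    spectrum.total_kmers,
                    len(spectrum.counts),
                    len(label),
                )
            )
            fh.write(label)
            fh.write(spectrum.counts.astype("<f8").tobytes())
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    return path


def read_spectrum(path: str | Path, k: int | None = None) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum` (format sniffed).

    If ``k`` is given, a mismatch with the stored k is an error.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == _BINARY_MAGIC:
        spec = _read_binary(path)
    else:
        spec = _read_tsv(path)
    if k is not None and spec.k != k:
        raise ValueError(f"spectrum has k={spec.k}, expected k={k}")
    return spec


def _read_binary(path: Path) -> Spectrum:
    with open(path, "rb") as fh:
        fh.read(4)
        k, norm, total, n, label_len = struct.unpack("<iiqqi", fh.read(28))
        label = fh.read(label_len).decode()
        counts = np.frombuffer(fh.read(8 * n), dtype="<f8").copy()
    return Spectrum(k, counts, bool(norm), total, label)


def _read_tsv(path: Path) -> Spectrum:
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            else:
                kmer, _, val = line.partition("\t")
                rows.append((kmer, float(val)))
    k = int(meta["k"])
    indexer = CanonicalIndexer.cached(k)
    counts = np.zeros(indexer.n_classes, dtype=np.float64)
    for kmer, val in rows:
        counts[indexer.index(kmer)] = val
    return Spectrum(
        k,
        counts,
        meta.get("normalized", "false") == "true",
        int(meta.get("total", "0")),
        meta.get("label", ""),
    )
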