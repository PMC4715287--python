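"""Reading, writing, quality-filtering and subsampling of sequence read sets.

FASTA/FASTQ parsing is delegated to Biopython; gzip-compressed inputs are
detected by magic bytes and decompressed transparently. Bases are stored
upper-case and restricted to the alphabet {A, C, G, T, N}: anything else is
rejected at parse time so that downstream k-mer spectra cannot be silently
corrupted.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "ReadSet",
    "read_sequences",
    "write_sequences",
    "quality_filter",
    "subsample_reads",
]

_VALID_BASES = frozenset("ACGTN")
_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence read: an id, bases over {A,C,G,T,N}, optional Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(allowed: A, C, G, T, N)"
            )
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality scores for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadSet:
    """Ordered collection of :class:`SequenceRecord` with a provenance note."""

    records: list[SequenceRecord] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def has_qualities(self) -> bool:
        return all(r.quals is not None for r in self.records)


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open a possibly gzip-compressed file as text, sniffing magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            break
    raise ValueError(f"cannot detect sequence format of {path}")


def read_sequences(
    path: str | Path,
    format: str = "auto",
    phred_offset: int = 33,
) -> ReadSet:
    """Read a FASTA or FASTQ file (optionally gzipped) into a :class:`ReadSet`.

    Parameters
    ----------
    path : file path
    format : {"fasta", "fastq", "auto"}
        ``auto`` sniffs the first non-blank line.
    phred_offset : {33, 64}
        ASCII offset used to decode FASTQ quality strings. Biopython decodes
        at offset 33; for offset 64 the scores are shifted accordingly.
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r} (expected fasta or fastq)")

    shift = phred_offset - 33
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                quals: tuple[int, ...] | None = None
                if format == "fastq":
                    raw = rec.letter_annotations["phred_quality"]
                    quals = tuple(q - shift for q in raw)
                    if any(q < 0 for q in quals):
                        raise ValueError(
                            f"record {rec.id!r}: negative quality after "
                            f"applying offset {phred_offset}"
                        )
                records.append(
                    SequenceRecord(rec.id, str(rec.seq).upper(), quals)
                )
        except ValueError as exc:
            raise ValueError(
                f"parse error in {path} at record index {len(records)}: {exc}"
            ) from exc
    return ReadSet(records, source=str(path))


def write_sequences(
    reads: ReadSet, path: str | Path, format: str = "fasta"
) -> Path:
    """Write a read set as FASTA or FASTQ (gzipped if the path ends in .gz)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    if format == "fastq" and not reads.has_qualities():
        raise ValueError("fastq output requires quality scores on all records")

    bio_records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        if format == "fastq":
            rec.letter_annotations["phred_quality"] = list(r.quals)  # type: ignore[arg-type]
        bio_records.append(rec)

    path = Path(path)
    if path.suffix == ".gz":
        with io.TextIOWrapper(gzip.open(path, "wb")) as fh:
            SeqIO.write(bio_records, fh, format)
    else:
        with open(path, "wt") as fh:
            SeqIO.write(bio_records, fh, format)
    return path


def quality_filter(reads: ReadSet, min_q: int = 30) -> ReadSet:
    """Keep only reads in which *every* base quality is >= ``min_q``.

    This is the strict per-nucleotide reading of a QV>=30 filter: a single
    base below the threshold discards the whole read. Order is preserved and
    the operation is idempotent.
    """
    kept = []
    for r in reads:
        if r.quals is None:
            raise ValueError(f"record {r.id!r} has no quality scores")
        if all(q >= min_q for q in r.quals):
            kept.append(r)
    return ReadSet(kept, source=f"{reads.source}|minQ{min_q}")


def subsample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement, seed-deterministic.

    Indices are sampled from a seeded generator and the selected reads are
    emitted in their original order, so the result does not depend on any
    internal shuffle order.
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    if n > len(reads):
        raise ValueError(
            f"cannot sample {n} reads from a set of {len(reads)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return ReadSet(
        [reads.records[i] for i in idx],
        source=f"{reads.source}|sub{n}s{seed}",
    )


def readset_from_strings(
    seqs: Sequence[str] | Iterable[str], prefix: str = "read"
) -> ReadSet:
    """Convenience constructor: build a ReadSet from bare sequence strings."""
    return ReadSet(
        [SequenceRecord(f"{prefix}{i}", s.upper()) for i, s in enumerate(seqs)],
        source="in-memory",
    )
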