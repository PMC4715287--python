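"""Filter precomputed alignment-hit tables and aggregate gene abundances.

For quantifying a multi-gene element (e.g. a phage) against a reference gene
catalog: hits from an external aligner (BLAST/DIAMOND tabular output) are
filtered by e-value, percent identity and query/subject coverage, gene-level
relative abundances are the ratio of read length mapped to a gene over read
length mapped to the whole catalog, and the element's abundance is the sum
over its genes. Alignment itself is out of scope — only the tables are
consumed.

Note on the identity threshold: the filter keeps hits with identity >= the
threshold (the published criterion prints the comparison the other way
round, which would keep only poor alignments; the direction is configurable
via ``identity_at_least=False`` for strict reproduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "filter_hits",
    "read_hit_table",
    "gene_abundance_from_mapping",
    "phage_abundance",
]

# BLAST/DIAMOND -outfmt 6 default columns, optionally extended with qlen/slen
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit from a tabular aligner output."""

    query: str
    subject: str
    e_value: float
    pct_identity: float
    aln_length: int
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if min(self.aln_length, self.query_length, self.subject_length) <= 0:
            raise ValueError(f"hit {self.query}->{self.subject}: lengths must be > 0")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(
                f"hit {self.query}->{self.subject}: identity "
                f"{self.pct_identity} outside [0, 100]"
            )

    @property
    def query_coverage(self) -> float:
        return self.aln_length / self.query_length

    @property
    def subject_coverage(self) -> float:
        return self.aln_length / self.subject_length


def filter_hits(
    hits: Iterable[HitRecord],
    max_evalue: float = 1e-5,
    min_identity: float = 80.0,
    min_qcov: float = 0.8,
    min_scov: float = 0.8,
    identity_at_least: bool = True,
) -> list[HitRecord]:
    """Keep hits satisfying all similarity criteria.

    A hit passes when e_value < max_evalue, identity >= min_identity
    (or < min_identity if ``identity_at_least`` is False),
    aln_length/query_length > min_qcov and aln_length/subject_length >
    min_scov. Loosening any threshold never removes a previously kept hit.
    """
    kept = []
    for h in hits:
        if h.e_value >= max_evalue:
            continue
        if identity_at_least:
            if h.pct_identity < min_identity:
                continue
        elif h.pct_identity >= min_identity:
            continue
        if h.query_coverage <= min_qcov or h.subject_coverage <= min_scov:
            continue
        kept.append(h)
    return kept


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Read a BLAST/DIAMOND outfmt-6-style TSV into hit records.

    Tables with 14 columns are taken as the extended dialect with trailing
    qlen and slen; the 12-column dialect requires sidecar length mappings.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 14:
        df.columns = OUTFMT6_COLUMNS + ["qlen", "slen"] + [
            f"extra{i}" for i in range(df.shape[1] - 14)
        ]
    elif df.shape[1] == 12:
        if query_lengths is None or subject_lengths is None:
            raise ValueError(
                "12-column hit table requires query_lengths and subject_lengths"
            )
        df.columns = OUTFMT6_COLUMNS
        df["qlen"] = df["qseqid"].map(query_lengths)
        df["slen"] = df["sseqid"].map(subject_lengths)
        if df[["qlen", "slen"]].isna().any().any():
            raise ValueError("sequence ids missing from the length sidecars")
    else:
        raise ValueError(
            f"expected 12 or >=14 tab-separated columns, got {df.shape[1]}"
        )
    return [
        HitRecord(
            str(r.qseqid), str(r.sseqid), float(r.evalue), float(r.pident),
            int(r.length), int(r.qlen), int(r.slen),
        )
        for r in df.itertuples()
    ]


def gene_abundance_from_mapping(
    read_lengths_per_gene: Mapping[str, float], total_mapped_length: float
) -> pd.Series:
    """Per-gene relative abundance: mapped read length for the gene divided
    by mapped read length for the whole catalog."""
    if total_mapped_length <= 0:
        raise ValueError("total mapped length must be positive")
    table = pd.Series(read_lengths_per_gene, dtype=float)
    if (table < 0).any():
        raise ValueError("mapped lengths must be nonnegative")
    if table.sum() > total_mapped_length * (1 + 1e-9):
        raise ValueError(
            "per-gene mapped length exceeds the total mapped length"
        )
    return table / total_mapped_length


def phage_abundance(gene_table: pd.Series | Mapping[str, float], gene_ids: Sequence[str]) -> float:
    """Relative abundance of a multi-gene element: sum over its genes.

    Genes absent from the table contribute 0 (with a warning).
    """
    if len(gene_ids) == 0:
        raise ValueError("empty gene set")
    table = pd.Series(gene_table, dtype=float)
    missing = [g for g in gene_ids if g not in table.index]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from the abundance table "
            f"(contributing 0): {missing[:5]}",
            stacklevel=2,
        )
    present = [g for g in gene_ids if g in table.index]
    return float(table.loc[present].sum()) if present else 0.0
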