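"""Synthetic shotgun-metagenome generator with recorded ground truth.

Emulates the validation setup for reference-free metagenome comparison:

* random "species" genomes (i.i.d. bases at a chosen GC content) stand in
  for downloaded reference genomes;
* community composition per sample is drawn per-genome from a normal
  distribution (negatives redrawn), then normalized to sum 1;
* reads are allocated to genomes multinomially by abundance, sampled
  uniformly from either strand, and optionally carry i.i.d. per-base
  substitution errors (the error model of short-read platforms, ~1%);
* genome families with introduced SNPs come in two flavours — the
  "independent" model (each of 64 mutants gets its own random substitutions
  at a per-genome rate, e.g. 0.5%, so any two mutants differ by ~1%) and the
  "phylogenetic" model (6 rounds of duplicate-then-mutate producing the
  2^6 = 64 leaves of a complete binary copy-tree, modelling gradual
  accumulation of mutations along lineages).

All outputs are reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sequences_io import ReadSet, SequenceRecord

__all__ = [
    "Genome",
    "CommunityProfile",
    "MutationFamily",
    "random_genome",
    "sample_abundances",
    "mutate_independent",
    "mutate_phylogenetic",
    "tree_path_length",
    "sample_reads",
    "pairwise_divergence",
]

_BASES = "ACGT"
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

DEFAULT_READ_BUDGET = 1_000_000
# Per-iteration substitution rate of the phylogenetic model, calibrated so
# that the expected divergence between two random leaves of the depth-6
# copy-tree (mean path length 2*(6 - 57/63) ~ 10.19 edges) matches the ~1%
# pairwise divergence of the independent model at a 0.5% per-genome rate.
DEFAULT_PHYLO_RATE = 0.00098


@dataclass(frozen=True)
class Genome:
    """A synthetic genome: an id and an unambiguous A/C/G/T sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        """Sequence as a 2-bit code array (A=0, C=1, G=2, T=3)."""
        arr = _ENCODE[np.frombuffer(self.sequence.encode(), dtype=np.uint8)]
        if (arr == 255).any():
            raise ValueError(f"genome {self.id!r} contains ambiguous bases")
        return arr

    @staticmethod
    def from_codes(id: str, codes: np.ndarray) -> "Genome":
        return Genome(id, _DECODE[codes].tobytes().decode())


@dataclass
class CommunityProfile:
    """Relative abundances of the genomes making up one sample."""

    genome_ids: list[str]
    abundances: np.ndarray
    read_budget: int = DEFAULT_READ_BUDGET

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.float64)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if len(self.genome_ids) != len(self.abundances):
            raise ValueError("genome_ids and abundances differ in length")


@dataclass
class MutationFamily:
    """A set of mutated copies of one ancestor genome."""

    ancestor_id: str
    members: list[Genome]
    model: str  # "independent" or "phylogenetic"
    rate: float
    seed: int
    iterations: int = 0  # phylogenetic model only

    def __post_init__(self) -> None:
        lengths = {len(g) for g in self.members}
        if len(lengths) > 1:
            raise ValueError("family members differ in length")


def random_genome(length: int, gc: float = 0.5, seed: int = 0, id: str = "genome") -> Genome:
    """I.i.d. random genome with P(G) + P(C) = ``gc``."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome.from_codes(id, codes)


def sample_abundances(
    means: Sequence[float],
    sds: Sequence[float],
    n_samples: int,
    seed: int,
    genome_ids: Sequence[str] | None = None,
    read_budget: int = DEFAULT_READ_BUDGET,
    max_redraws: int = 1000,
) -> list[CommunityProfile]:
    """Draw community profiles: per-genome Normal(mean_i, sd_i), negatives
    redrawn, each profile normalized to sum 1."""
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have the same length")
    if (means <= 0).any():
        raise ValueError("means must be positive")
    if (sds < 0).any():
        raise ValueError("sds must be nonnegative")
    if genome_ids is None:
        genome_ids = [f"g{i}" for i in range(len(means))]

    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_samples):
        draw = rng.normal(means, sds)
        for _attempt in range(max_redraws):
            neg = draw < 0
            if not neg.any():
                break
            draw[neg] = rng.normal(means[neg], sds[neg])
        else:
            raise RuntimeError(
                f"negative abundance draws persisted after {max_redraws} redraws"
            )
        profiles.append(
            CommunityProfile(list(genome_ids), draw / draw.sum(), read_budget)
        )
    return profiles


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a Binomial(L, rate) set of distinct positions, each to a
    uniformly chosen *different* base."""
    out = codes.copy()
    n_mut = rng.binomial(len(codes), rate)
    if n_mut == 0:
        return out
    pos = rng.choice(len(codes), size=n_mut, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def mutate_independent(
    ancestor: Genome, rate: float, n_members: int = 64, seed: int = 0
) -> MutationFamily:
    """Generate mutants of one ancestor, each mutated independently.

    With per-genome rate r, two mutants differ at an expected fraction
    2r(1-r) + (2/3)r^2 of positions (~2r for small r): e.g. r = 0.5% gives
    ~1% pairwise divergence.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    codes = ancestor.codes()
    members = [
        Genome.from_codes(f"{ancestor.id}_m{i}", _mutate_codes(codes, rate, rng))
        for i in range(n_members)
    ]
    return MutationFamily(ancestor.id, members, "independent", rate, seed)


def mutate_phylogenetic(
    ancestor: Genome,
    per_iteration_rate: float = DEFAULT_PHYLO_RATE,
    iterations: int = 6,
    seed: int = 0,
) -> MutationFamily:
    """Duplicate-then-mutate tree model of SNP accumulation.

    Start from the ancestor; at each iteration every genome is copied and
    then *all* genomes (originals and copies) receive independent
    substitutions at ``per_iteration_rate``. After t iterations there are
    2^t members, the leaves of a complete binary copy-tree. Member i's
    parent before the last duplication is member i mod 2^(t-1), so tree
    distances between leaves are recoverable from indices alone
    (:func:`tree_path_length`).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= per_iteration_rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {per_iteration_rate}")
    rng = np.random.default_rng(seed)
    pool = [ancestor.codes()]
    for _ in range(iterations):
        pool = pool + [c.copy() for c in pool]
        pool = [_mutate_codes(c, per_iteration_rate, rng) for c in pool]
    members = [
        Genome.from_codes(f"{ancestor.id}_p{i}", c) for i, c in enumerate(pool)
    ]
    return MutationFamily(
        ancestor.id, members, "phylogenetic", per_iteration_rate, seed, iterations
    )


def tree_path_length(i: int, j: int, iterations: int) -> int:
    """Number of tree edges between leaves i and j of the copy-tree.

    The lowest common ancestor of leaves i and j sits at the deepest level t
    at which i mod 2^t == j mod 2^t; the path then spans 2*(iterations - t)
    edges (mutation rounds accumulated independently by the two lineages).
    """
    if i == j:
        return 0
    lca = 0
    for t in range(iterations, 0, -1):
        if i % (1 << t) == j % (1 << t):
            lca = t
            break
    return 2 * (iterations - lca)


def pairwise_divergence(a: Genome, b: Genome) -> float:
    """Fraction of positions at which two equal-length genomes differ."""
    ca, cb = a.codes(), b.codes()
    if len(ca) != len(cb):
        raise ValueError("genomes differ in length")
    return float((ca != cb).mean())


def sample_reads(
    genomes: Sequence[Genome],
    profile: CommunityProfile,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    with_qualities: bool = False,
) -> tuple[ReadSet, pd.DataFrame]:
    """Sample a shotgun read set from a community.

    Read counts per genome are Multinomial(read_budget, abundances); each
    read starts uniformly on a uniformly chosen strand of its genome; each
    base is substituted with probability ``error_rate`` to a uniformly
    chosen different base. Returns the reads plus a ground-truth table
    (read id, genome, 0-based start on the forward strand, strand).

    Simulated FASTQ qualities, when requested, are constant Q40.
    """
    by_id = {g.id: g for g in genomes}
    missing = [gid for gid in profile.genome_ids if gid not in by_id]
    if missing:
        raise ValueError(f"profile names unknown genomes: {missing}")
    for gid in profile.genome_ids:
        if len(by_id[gid]) < read_length:
            raise ValueError(
                f"genome {gid!r} ({len(by_id[gid])} bp) shorter than "
                f"read length {read_length}"
            )
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(profile.read_budget, profile.abundances)

    records: list[SequenceRecord] = []
    truth_rows: list[pd.DataFrame] = []
    q40 = tuple([40] * read_length) if with_qualities else None
    read_no = 0
    for gid, n_reads in zip(profile.genome_ids, counts):
        if n_reads == 0:
            continue
        codes = by_id[gid].codes()
        starts = rng.integers(0, len(codes) - read_length + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)  # 0 = +, 1 = -
        mat = codes[starts[:, None] + np.arange(read_length)]
        rev = strands == 1
        if rev.any():  # reverse complement the minus-strand reads
            mat[rev] = 3 - mat[rev][:, ::-1]
        if error_rate > 0:
            errs = rng.random(mat.shape) < error_rate
            if errs.any():
                mat[errs] = (mat[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
        text = _DECODE[mat].tobytes().decode()
        for r in range(n_reads):
            records.append(
                SequenceRecord(
                    f"r{read_no + r}",
                    text[r * read_length : (r + 1) * read_length],
                    q40,
                )
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": [f"r{read_no + r}" for r in range(n_reads)],
                    "genome": gid,
                    "start": starts,
                    "strand": np.where(rev, "-", "+"),
                }
            )
        )
        read_no += n_reads

    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["read_id", "genome", "start", "strand"])
    )
    return ReadSet(records, source=f"simulated(seed={seed})"), truth
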