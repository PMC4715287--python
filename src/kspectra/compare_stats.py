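"""Comparison statistics for dissimilarity matrices.

* Mantel test: permutation test of the (Spearman or Pearson) correlation
  between the upper triangles of two distance matrices, permuting sample
  labels jointly across rows and columns of one matrix. Since a joint
  row/column permutation only reorders the multiset of off-diagonal entries,
  ranks can be assigned once and the permuted statistic computed as a
  Pearson correlation of rank matrices, which makes 999 permutations cheap.
* PCoA (classical multidimensional scaling): double-center -0.5 * D^2,
  eigendecompose, keep positive-eigenvalue axes scaled by sqrt(eigenvalue).
* A residual "k-mer difference" statistic for scatter clouds of
  (reference-based, k-mer) dissimilarity pairs: the central trend of the
  cloud is a per-bin median linearly interpolated across bins, each pair's
  difference is its vertical offset from the trend, and pairs whose k-mer
  dissimilarity exceeds an absolute threshold (default 0.5) are flagged as
  extreme outliers — the signature of a dominant unknown component (e.g. a
  phage absent from reference catalogs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import DissimilarityMatrix

__all__ = [
    "MantelResult",
    "PcoaResult",
    "PairCloud",
    "OutlierReport",
    "mantel_test",
    "pcoa",
    "bc_kmer_difference",
    "matrix_correlation_table",
]


# ---------------------------------------------------------------------------
# Mantel test


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str


def _rank_matrix(m: DissimilarityMatrix) -> np.ndarray:
    """Square matrix whose off-diagonal entries are the average ranks of the
    condensed (upper-triangle) distances, symmetric, zero diagonal."""
    n = m.n
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(m.values[iu])  # average ranks for ties
    out = np.zeros((n, n))
    out[iu] = ranks
    return out + out.T


def mantel_test(
    m1: DissimilarityMatrix,
    m2: DissimilarityMatrix,
    method: str = "spearman",
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Permutation Mantel test between two labeled dissimilarity matrices.

    The p-value is one-tailed (greater) with the +1 correction:
    p = (1 + #{permuted r >= observed r}) / (1 + n_permutations).
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels in the same order")
    if m1.n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")

    if method == "spearman":
        a, b = _rank_matrix(m1), _rank_matrix(m2)
    else:
        a, b = m1.values, m2.values

    n = m1.n
    iu = np.triu_indices(n, k=1)

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        xv, yv = x[iu], y[iu]
        if xv.std() == 0 or yv.std() == 0:
            raise ValueError("constant matrix: correlation undefined")
        return float(np.corrcoef(xv, yv)[0, 1])

    r_obs = corr(a, b)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(a[np.ix_(perm, perm)], b) >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, method)


def matrix_correlation_table(
    matrices: dict[str, DissimilarityMatrix],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs Mantel Spearman correlations between named matrices."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    names = list(matrices)
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = mantel_test(
                matrices[a], matrices[b], "spearman", n_permutations, seed
            )
            table.loc[a, b] = table.loc[b, a] = res.r
    return table


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n_samples, n_axes), sqrt(eigenvalue) scaling
    explained: np.ndarray  # variance fractions, nonincreasing, sum <= 1
    labels: list[str]
    truncated: bool = False  # fewer positive axes than requested


def pcoa(m: DissimilarityMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical scaling of a dissimilarity matrix.

    Negative eigenvalues (non-Euclidean input) are dropped; if fewer
    positive eigenvalues than ``n_axes`` exist, fewer axes are returned and
    the result is flagged truncated.
    """
    n = m.n
    if n_axes >= n:
        raise ValueError(f"n_axes must be < {n} samples")
    d2 = m.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos = evals > max(1e-12, 1e-12 * abs(evals).max(initial=0.0))
    n_pos = int(pos.sum())
    truncated = n_pos < n_axes
    if truncated:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes "
            f"instead of {n_axes}",
            stacklevel=2,
        )
    keep = min(n_axes, n_pos)
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    total = evals[pos].sum()
    explained = evals[:keep] / total if total > 0 else np.zeros(keep)
    return PcoaResult(coords, explained, list(m.labels), truncated)


# ---------------------------------------------------------------------------
# BC-kmer-difference outlier statistic


@dataclass
class PairCloud:
    """Per-pair scatter of reference-based (x) vs k-mer (y) dissimilarity."""

    pairs: pd.DataFrame  # columns: sample_a, sample_b, x, y

    def __post_init__(self) -> None:
        required = {"sample_a", "sample_b", "x", "y"}
        if not required <= set(self.pairs.columns):
            raise ValueError(f"pair table must have columns {sorted(required)}")

    @staticmethod
    def from_matrices(
        reference: DissimilarityMatrix, kmer: DissimilarityMatrix
    ) -> "PairCloud":
        if reference.labels != kmer.labels:
            raise ValueError("matrices must share labels in the same order")
        rows = []
        n = reference.n
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (
                        reference.labels[i],
                        reference.labels[j],
                        reference.values[i, j],
                        kmer.values[i, j],
                    )
                )
        return PairCloud(
            pd.DataFrame(rows, columns=["sample_a", "sample_b", "x", "y"])
        )


@dataclass
class OutlierReport:
    pairs: pd.DataFrame  # sample_a, sample_b, x, y, trend, difference, flagged
    threshold: float
    flagged_samples: pd.Series = field(default_factory=pd.Series)

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]]


def _binned_median_trend(
    x: np.ndarray, y: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin median of y over equal-width bins of x; empty bins merge into
    their populated neighbours (i.e. are dropped from the interpolation
    knots). Returns (bin centers, medians)."""
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("x values must span a positive range")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    centers, medians = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append((edges[b] + edges[b + 1]) / 2.0)
            medians.append(np.median(y[mask]))
    if len(centers) < 2:
        raise ValueError(
            "all pairs fall in a single bin; cannot interpolate a trend"
        )
    return np.array(centers), np.array(medians)


def bc_kmer_difference(
    cloud: PairCloud, n_bins: int = 20, threshold: float = 0.5
) -> OutlierReport:
    """Residuals of k-mer dissimilarity from the cloud's central trend, plus
    the extreme-outlier rule.

    The trend is the per-bin median of y, linearly interpolated between bin
    centers and flat beyond them; each pair's difference is y - trend(x).
    Pairs with y strictly greater than ``threshold`` are flagged extreme and
    per-sample flag counts are aggregated.
    """
    df = cloud.pairs.copy()
    if len(df) < 2 * n_bins:
        raise ValueError(
            f"need at least {2 * n_bins} pairs for {n_bins} bins, got {len(df)}"
        )
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    centers, medians = _binned_median_trend(x, y, n_bins)
    trend = np.interp(x, centers, medians)  # flat extrapolation at the ends
    df["trend"] = trend
    df["difference"] = y - trend
    df["flagged"] = y > threshold

    flagged = df[df["flagged"]]
    counts = (
        pd.concat([flagged["sample_a"], flagged["sample_b"]])
        .value_counts()
        .sort_values(ascending=False)
    )
    return OutlierReport(df, threshold, counts)
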