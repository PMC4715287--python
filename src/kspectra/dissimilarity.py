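"""Bray-Curtis dissimilarity between k-mer spectra and labeled pairwise matrices.

For two feature vectors x, y the Bray-Curtis dissimilarity is

    BC(x, y) = 1 - 2 * sum_i min(x_i, y_i) / sum_i (x_i + y_i)

which for vectors each normalized to sum 1 reduces to 1 - sum_i min(x_i, y_i).
BC is 0 when the two profiles are identical and 1 when they share no feature.
Because reverse-complement pair counts are merged into one canonical class in
*both* spectra, BC over canonical classes equals BC over the full 4^k
expansion, so the collapsed vectors are used directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kmer_core import Spectrum

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "pairwise_matrix",
    "write_matrix",
    "read_matrix",
]

_NORM_TOL = 1e-6


@dataclass
class DissimilarityMatrix:
    """Symmetric matrix of pairwise dissimilarities with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate sample labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (scipy 'condensed')."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _check_normalized(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if (v < 0).any():
        raise ValueError(f"{name} contains negative entries")
    if abs(v.sum() - 1.0) > _NORM_TOL:
        raise ValueError(
            f"{name} is not normalized (sum={v.sum():.6g}, expected 1)"
        )
    return v


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two normalized feature vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    x = _check_normalized(x, "x")
    y = _check_normalized(y, "y")
    num = 2.0 * np.minimum(x, y).sum()
    den = x.sum() + y.sum()
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def pairwise_matrix(
    spectra: Sequence[Spectrum] | Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis matrix over normalized spectra (or bare vectors).

    All spectra must share the same k and be normalized; bare vectors must
    each sum to 1.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    if isinstance(spectra[0], Spectrum):
        ks = {s.k for s in spectra}  # type: ignore[union-attr]
        if len(ks) != 1:
            raise ValueError(f"mixed k values: {sorted(ks)}")
        if not all(s.normalized for s in spectra):  # type: ignore[union-attr]
            raise ValueError("all spectra must be normalized")
        vectors = [s.counts for s in spectra]  # type: ignore[union-attr]
        if labels is None:
            labels = [s.label or f"S{i}" for i, s in enumerate(spectra)]  # type: ignore[union-attr]
    else:
        vectors = [np.asarray(v, dtype=np.float64) for v in spectra]
        if labels is None:
            labels = [f"S{i}" for i in range(len(vectors))]
    labels = list(labels)

    n = len(vectors)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(vectors[i], vectors[j])
    return DissimilarityMatrix(labels, mat)


def write_matrix(m: DissimilarityMatrix, path: str | Path) -> Path:
    """Write a labeled square TSV (6 significant digits)."""
    df = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    df.to_csv(path, sep="\t", float_format="%.6g")
    return Path(path)


def read_matrix(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=np.float64)
    vals = (vals + vals.T) / 2.0  # heal 6-digit rounding asymmetry
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix([str(c) for c in df.columns], vals)
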