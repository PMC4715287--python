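"""Mantel test, PCoA and the k-mer-difference outlier statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from kspectra import (
    DissimilarityMatrix,
    PairCloud,
    bc_kmer_difference,
    mantel_test,
    matrix_correlation_table,
    pcoa,
)


def random_dissimilarity(rng, n):
    pts = rng.random((n, 3))
    vals = squareform(pdist(pts) / pdist(pts).max())
    return DissimilarityMatrix([f"s{i}" for i in range(n)], vals)


class TestMantel:
    def test_identical_matrices_give_r_one(self, rng):
        m = random_dissimilarity(rng, 12)
        res = mantel_test(m, m, "spearman", 99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_decreasing_transform_gives_minus_one(self, rng):
        m1 = random_dissimilarity(rng, 10)
        vals = 1.0 - m1.values  # strictly decreasing transform off-diagonal
        np.fill_diagonal(vals, 0.0)
        m2 = DissimilarityMatrix(m1.labels, vals)
        res = mantel_test(m1, m2, "spearman", 99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_agrees_with_scikit_bio(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        m1, m2 = random_dissimilarity(rng, 15), random_dissimilarity(rng, 15)
        m2 = DissimilarityMatrix(m1.labels, m2.values)
        ours = mantel_test(m1, m2, "spearman", 999, seed=1)
        theirs_r, _, _ = skbio_mantel(
            DistanceMatrix(m1.values, m1.labels),
            DistanceMatrix(m2.values, m2.labels),
            method="spearman",
            permutations=0,
        )
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        m1, m2 = random_dissimilarity(rng, 10), random_dissimilarity(rng, 10)
        m2 = DissimilarityMatrix(m1.labels, m2.values)
        base = mantel_test(m1, m2, "spearman", 199, seed=3)
        perm = rng.permutation(10)
        relabel = [m1.labels[i] for i in perm]
        m1p = DissimilarityMatrix(relabel, m1.values[np.ix_(perm, perm)])
        m2p = DissimilarityMatrix(relabel, m2.values[np.ix_(perm, perm)])
        again = mantel_test(m1p, m2p, "spearman", 199, seed=3)
        assert again.r == pytest.approx(base.r)

    def test_p_value_seeded_and_bounded(self, rng):
        m1, m2 = random_dissimilarity(rng, 10), random_dissimilarity(rng, 10)
        m2 = DissimilarityMatrix(m1.labels, m2.values)
        a = mantel_test(m1, m2, "spearman", 999, seed=5)
        b = mantel_test(m1, m2, "spearman", 999, seed=5)
        assert a.p == b.p >= 1 / 1000

    def test_null_calibration(self):
        # independent random matrices: p should be ~uniform, so the
        # rejection fraction at 0.05 stays near 0.05
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            m1 = random_dissimilarity(rng, 12)
            m2 = DissimilarityMatrix(m1.labels, random_dissimilarity(rng, 12).values)
            res = mantel_test(m1, m2, "spearman", 99, seed=int(rng.integers(2**31)))
            if res.p <= 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_errors(self, rng):
        m1 = random_dissimilarity(rng, 8)
        other = DissimilarityMatrix(
            [f"x{i}" for i in range(8)], random_dissimilarity(rng, 8).values
        )
        with pytest.raises(ValueError):
            mantel_test(m1, other)  # label mismatch
        flat = DissimilarityMatrix(
            m1.labels, np.ones((8, 8)) * 0.5 - np.eye(8) * 0.5
        )
        with pytest.raises(ValueError):
            mantel_test(m1, flat, "spearman", 99, seed=0)


class TestMatrixCorrelationTable:
    def test_duplicated_matrix_gives_unit_offdiagonal(self, rng):
        m = random_dissimilarity(rng, 10)
        t = matrix_correlation_table({"a": m, "b": m}, 99, seed=0)
        assert t.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal_and_matches_mantel(self, rng):
        ms = {}
        base = random_dissimilarity(rng, 10)
        for name in "abc":
            other = random_dissimilarity(rng, 10)
            ms[name] = DissimilarityMatrix(base.labels, other.values)
        t = matrix_correlation_table(ms, 99, seed=1)
        assert np.allclose(t.values, t.values.T)
        assert np.allclose(np.diag(t.values), 1.0)
        expected = mantel_test(ms["a"], ms["c"], "spearman", 99, seed=1).r
        assert t.loc["a", "c"] == pytest.approx(expected)


class TestPcoa:
    def test_two_samples_separated_by_d(self):
        d = 0.42
        m = DissimilarityMatrix(["a", "b"], [[0, d], [d, 0]])
        res = pcoa(m, 1)
        assert abs(res.coordinates[0, 0] - res.coordinates[1, 0]) == pytest.approx(d)

    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((5, 2))
        m = DissimilarityMatrix(
            [f"s{i}" for i in range(5)], squareform(pdist(pts))
        )
        res = pcoa(m, 2)
        # classical scaling is exact for Euclidean input: compare distances
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, m.values, atol=1e-9)

    def test_identical_samples_collapse_to_origin(self):
        m = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            res = pcoa(m, 2)
        assert res.truncated
        assert res.coordinates.size == 0

    def test_explained_fractions_nonincreasing_sum_le_one(self, rng):
        m = random_dissimilarity(rng, 12)
        with pytest.warns(UserWarning):  # 3D points -> only 3 positive axes
            res = pcoa(m, 5)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert res.explained.sum() <= 1.0 + 1e-12

    def test_agrees_with_scikit_bio(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        m = random_dissimilarity(rng, 10)
        ours = pcoa(m, 3)
        theirs = skbio_pcoa(DistanceMatrix(m.values, m.labels), method="eigh")
        their_coords = theirs.samples.to_numpy()[:, :3]
        for axis in range(3):  # sign of each axis is arbitrary
            a, b = ours.coordinates[:, axis], their_coords[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_n_axes_bound(self, rng):
        with pytest.raises(ValueError):
            pcoa(random_dissimilarity(rng, 5), 5)


def line_cloud(n=100, noise=0.0, rng=None, hi=0.45):
    # y stays below the 0.5 extreme-outlier threshold by construction
    rng = rng or np.random.default_rng(0)
    x = np.linspace(0.05, hi, n)
    y = x + (rng.normal(0, noise, n) if noise else 0.0)
    return PairCloud(
        pd.DataFrame(
            {
                "sample_a": [f"s{i}" for i in range(n)],
                "sample_b": [f"t{i}" for i in range(n)],
                "x": x,
                "y": y,
            }
        )
    )


class TestBcKmerDifference:
    def test_perfect_line_gives_zero_differences(self):
        report = bc_kmer_difference(line_cloud(200), n_bins=20)
        inner = report.pairs.iloc[5:-5]  # flat extrapolation beyond end bins
        assert np.abs(inner["difference"]).max() < 0.03

    def test_single_outlier_detected_and_flagged(self):
        cloud = line_cloud(200)
        df = cloud.pairs.copy()
        df.loc[len(df)] = ["sX", "sY", 0.3, 0.9]
        report = bc_kmer_difference(PairCloud(df), n_bins=20)
        row = report.pairs.iloc[-1]
        assert row["flagged"]
        assert row["difference"] == pytest.approx(0.6, abs=0.05)
        assert set(report.flagged_samples.index) == {"sX", "sY"}

    def test_threshold_is_strict(self):
        df = line_cloud(100).pairs.copy()
        df.loc[50, "y"] = 0.50
        report = bc_kmer_difference(PairCloud(df), n_bins=10, threshold=0.5)
        assert not report.pairs.loc[50, "flagged"]
        flagged = report.pairs[report.pairs["flagged"]]
        assert (flagged["y"] > 0.5).all()

    def test_constant_y_shift_absorbed_by_trend(self, rng):
        cloud = line_cloud(300, noise=0.02, rng=rng)
        base = bc_kmer_difference(cloud, n_bins=15)
        shifted = PairCloud(cloud.pairs.assign(y=cloud.pairs["y"] + 0.1))
        after = bc_kmer_difference(shifted, n_bins=15)
        assert np.allclose(
            base.pairs["difference"], after.pairs["difference"], atol=1e-9
        )

    def test_too_few_pairs_or_degenerate_x(self):
        with pytest.raises(ValueError):
            bc_kmer_difference(line_cloud(10), n_bins=20)
        df = line_cloud(100).pairs.assign(x=0.5)
        with pytest.raises(ValueError):
            bc_kmer_difference(PairCloud(df), n_bins=10)
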