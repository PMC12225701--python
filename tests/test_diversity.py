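"""Diversity statistics: dissimilarity formulas, ordination recovery, and
permutation tests against exact-enumeration oracles."""

from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from sedacomp import diversity as div


def table(rows, index=None):
    return pd.DataFrame(rows, index=index or [f"S{i}" for i in range(len(rows))])


class TestRichness:
    def test_positive_count(self):
        t = table([[0, 0, 5, 1], [0, 0, 0, 0]])
        out = div.richness(t)
        assert out["S0"] == 2 and out["S1"] == 0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        t = table(rng.integers(0, 3, (6, 20)))
        out = div.richness(t)
        for s in t.index:
            assert out[s] == sum(1 for v in t.loc[s] if v > 0)


class TestCompareRichness:
    def test_exact_linear_relation(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        res = div.compare_richness(x, -2 * x + 7)
        assert res.slope == pytest.approx(-2.0)
        assert res.r == pytest.approx(-1.0)

    def test_constant_series_zero_slope(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        res = div.compare_richness(x, pd.Series([5.0] * 4))
        assert res.slope == pytest.approx(0.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=11), rng.normal(size=11)
        res = div.compare_richness(pd.Series(x), pd.Series(y))
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean())

    def test_unpaired_series_rejected(self):
        with pytest.raises(ValueError):
            div.compare_richness(pd.Series([1, 2]), pd.Series([1, 2, 3]))


def test_standardize_relfreq():
    t = table([[2, 2, 4], [1, 0, 0]])
    out = div.standardize_relfreq(t)
    assert list(out.loc["S0"]) == [0.25, 0.25, 0.5]
    assert list(out.loc["S1"]) == [1.0, 0.0, 0.0]
    with pytest.raises(ValueError, match="all-zero"):
        div.standardize_relfreq(table([[0, 0, 0]]))


class TestDissimilarities:
    def test_bray_curtis_formula(self):
        t = table([[1, 2, 3], [2, 2, 0]])
        d = div.bray_curtis(t)
        assert d["S0", "S1"] == pytest.approx(0.4)  # 4/10

    def test_jaccard_formula(self):
        t = table([[1, 0, 1], [1, 1, 0]])
        d = div.jaccard(t)
        assert d["S0", "S1"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("metric", [div.bray_curtis, div.jaccard])
    def test_identical_zero_disjoint_one(self, metric):
        same = table([[1, 2, 0], [1, 2, 0]])
        assert metric(same)["S0", "S1"] == pytest.approx(0.0)
        disjoint = table([[1, 2, 0], [0, 0, 5]])
        assert metric(disjoint)["S0", "S1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", [div.bray_curtis, div.jaccard])
    def test_symmetry_diagonal_range(self, metric):
        rng = np.random.default_rng(3)
        t = table(rng.integers(0, 10, (7, 15)))
        d = metric(t).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_jaccard_triangle_inequality(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = table(rng.integers(0, 2, (3, 12)))
            if (t.sum(axis=1) == 0).any():
                continue
            d = div.jaccard(t).data
            for i, j, k in iter_permutations(range(3)):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestOrdinate:
    def _euclidean_dm(self, coords):
        return DistanceMatrix(squareform(pdist(coords)),
                              ids=[str(i) for i in range(len(coords))])

    def test_mds_recovers_planar_configuration(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(9, 2))
        res = div.ordinate(self._euclidean_dm(coords), method="mds")
        _, _, m2 = scipy_procrustes(coords, res.coords.to_numpy())
        assert m2 < 1e-9
        assert res.stress < 1e-6

    def test_nmds_near_zero_stress_on_exact_embedding(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(9, 2))
        res = div.ordinate(self._euclidean_dm(coords), method="nmds", seed=0)
        assert res.stress < 0.01

    def test_nmds_no_worse_than_metric_start(self):
        """Initialised at the PCoA solution, SMACOF can only improve it."""
        rng = np.random.default_rng(7)
        t = table(rng.integers(0, 20, (11, 25)))
        d = div.bray_curtis(t)
        nmds = div.ordinate(d, method="nmds", seed=0)
        mds = div.ordinate(d, method="mds")
        assert nmds.stress <= mds.stress * 1.01 + 1e-9

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            div.ordinate(d, k=2)


class TestProcrustesTest:
    def test_perfect_concordance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.0 * x @ rot + 5.0
        res = div.procrustes_test(x, y, n_perm=99, seed=0)
        assert res.m12_squared < 1e-9
        assert res.t == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        r1 = div.procrustes_test(x, y, n_perm=49, seed=1)
        r2 = div.procrustes_test(x + 10.0, y - 3.0, n_perm=49, seed=1)
        assert r1.m12_squared == pytest.approx(r2.m12_squared)

    def test_exact_p_matches_enumeration_oracle(self):
        """4 samples: the reported p equals brute-force enumeration of all
        24 row permutations, computed independently here."""
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        res = div.procrustes_test(x, y, n_perm=999, seed=0)
        assert res.exact
        _, _, observed = scipy_procrustes(x, y)
        count = sum(
            scipy_procrustes(x, y[list(p)])[2] <= observed + 1e-12
            for p in iter_permutations(range(4)))
        assert res.p == pytest.approx(count / 24)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            div.procrustes_test(np.zeros((4, 2)), np.zeros((5, 2)))


class TestMantelTest:
    def _dm(self, mat, ids=None):
        return DistanceMatrix(mat, ids=ids or [str(i) for i in range(len(mat))])

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(11)
        t = table(rng.integers(0, 10, (7, 12)))
        d = div.bray_curtis(t)
        res = div.mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(12)
        t = table(rng.integers(0, 10, (6, 12)))
        d1 = div.bray_curtis(t)
        d2 = div.jaccard(t)
        r1 = div.mantel_test(d1, d2, n_perm=99, seed=3)
        # same permutation of both matrices: statistic unchanged
        order = list(reversed(d1.ids))
        r2 = div.mantel_test(d1.filter(order), d2.filter(order), n_perm=99, seed=3)
        assert r1.r == pytest.approx(r2.r)

    def test_label_alignment(self):
        rng = np.random.default_rng(13)
        t = table(rng.integers(0, 10, (6, 12)))
        d1 = div.bray_curtis(t)
        d2 = div.bray_curtis(t).filter(list(reversed(t.index.astype(str))))
        res = div.mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)  # realigned before comparing

    def test_exact_p_matches_enumeration_oracle(self):
        """4x4 matrices: p equals exhaustive 24-permutation enumeration."""
        rng = np.random.default_rng(14)
        a = squareform(rng.uniform(0.1, 1.0, 6))
        b = squareform(rng.uniform(0.1, 1.0, 6))
        d1, d2 = self._dm(a), self._dm(b)
        res = div.mantel_test(d1, d2, n_perm=10000, seed=0)
        assert res.exact
        iu = np.triu_indices(4, k=1)
        observed = stats.pearsonr(a[iu], b[iu]).statistic
        count = 0
        for p in iter_permutations(range(4)):
            idx = np.asarray(p)
            count += stats.pearsonr(a[iu], b[np.ix_(idx, idx)][iu]).statistic >= observed - 1e-12
        assert res.p == pytest.approx(count / 24)

    def test_statistic_matches_independent_implementation(self):
        """r agrees with scikit-bio's own Mantel implementation."""
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(15)
        t = table(rng.integers(0, 10, (8, 12)))
        d1 = div.bray_curtis(t)
        d2 = div.jaccard(t)
        ours = div.mantel_test(d1, d2, n_perm=99, seed=0)
        theirs_r, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert ours.r == pytest.approx(float(theirs_r))

    def test_disjoint_labels_rejected(self):
        d1 = self._dm(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        d2 = self._dm(np.array([[0, 1.0], [1.0, 0]]), ids=["c", "d"])
        with pytest.raises(ValueError):
            div.mantel_test(d1, d2)
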