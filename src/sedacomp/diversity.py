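"""Alpha/beta-diversity comparison statistics between sequencing arms.

Community tables are sample x feature matrices: for the metabarcoding arm
the features are ASVs and the abundances positive-replicate counts; for the
metagenomic arm the features are genera and the abundances read counts.
Both are standardised to relative frequencies before dissimilarity
computation.  The battery:

* per-sample richness and ordinary least-squares regression between the two
  arms' richness series;
* Bray-Curtis and Jaccard dissimilarities;
* metric (principal-coordinates) and non-metric (stress-minimising)
  multidimensional scaling;
* a Procrustes permutation test (protest) between two ordinations;
* a Mantel permutation test between two distance matrices (10,000
  permutations by default).

Permutation p-values use the add-one estimator p = (1 + #extreme) /
(1 + n_perm), except in exact mode (n! <= n_perm) where all permutations
are enumerated and p = #extreme / n! (the identity permutation makes this
positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "richness",
    "compare_richness",
    "standardize_relfreq",
    "bray_curtis",
    "jaccard",
    "ordinate",
    "procrustes_test",
    "mantel_test",
    "OrdinationResult",
    "ProcrustesResult",
    "MantelResult",
    "RegressionResult",
]


def richness(table: pd.DataFrame) -> pd.Series:
    """Number of features with a positive value, per sample (row)."""
    return (table > 0).sum(axis=1).rename("richness")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float


def compare_richness(series1: pd.Series, series2: pd.Series) -> RegressionResult:
    """Ordinary least-squares regression of series2 on series1 with the
    two-sided slope test (series must be paired over the same samples)."""
    if len(series1) != len(series2):
        raise ValueError("richness series must be paired")
    res = stats.linregress(np.asarray(series1, float), np.asarray(series2, float))
    return RegressionResult(res.slope, res.intercept, res.rvalue, res.pvalue)


def standardize_relfreq(table: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise to relative frequencies (each sample sums to 1)."""
    sums = table.sum(axis=1)
    if (sums == 0).any():
        bad = list(table.index[sums == 0])
        raise ValueError(f"all-zero samples cannot be standardised: {bad}")
    return table.div(sums, axis=0)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x-y| / sum(x+y) between
    sample rows."""
    d = pdist(table.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in table.index])


def jaccard(table: pd.DataFrame) -> DistanceMatrix:
    """Presence/absence Jaccard dissimilarity d = 1 - |shared| / |union|."""
    d = pdist(table.to_numpy(dtype=float) > 0, metric="jaccard")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in table.index])


@dataclass
class OrdinationResult:
    coords: pd.DataFrame
    stress: float
    method: str
    converged: bool = True


def _stress1(dvec: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity vector
    (disparities by monotone regression on the dissimilarity ranks)."""
    emb = pdist(coords)
    iso = IsotonicRegression(increasing=True)
    dhat = iso.fit_transform(dvec, emb)
    denom = (emb ** 2).sum()
    return float(np.sqrt(((emb - dhat) ** 2).sum() / denom)) if denom > 0 else 0.0


def ordinate(dm: DistanceMatrix, k: int = 2, method: str = "nmds",
             seed: int = 0, n_restarts: int = 20,
             max_iter: int = 300, eps: float = 1e-6) -> OrdinationResult:
    """Embed a dissimilarity matrix in k dimensions.

    ``mds`` is classical principal-coordinates analysis; ``nmds`` minimises
    Kruskal stress-1 by SMACOF with monotone regression, taking the best of
    ``n_restarts`` seeded random starts plus one start at the metric (PCoA)
    solution.  Reported stress is stress-1 in both cases, so the two methods
    are directly comparable.
    """
    n = dm.shape[0]
    if n <= k:
        raise ValueError("need more samples than dimensions")
    diss = dm.data
    ids = list(dm.ids)

    pcoa_res = pcoa(dm, number_of_dimensions=min(k, n - 1))
    pcoa_coords = pcoa_res.samples.to_numpy()[:, :k]
    if pcoa_coords.shape[1] < k:  # degenerate: pad with zeros
        pad = np.zeros((n, k - pcoa_coords.shape[1]))
        pcoa_coords = np.hstack([pcoa_coords, pad])

    if method == "mds":
        stress = _stress1(squareform(diss, checks=False), pcoa_coords)
        return OrdinationResult(
            pd.DataFrame(pcoa_coords, index=ids,
                         columns=[f"axis{i + 1}" for i in range(k)]),
            stress, "mds")
    if method != "nmds":
        raise ValueError(f"unknown ordination method {method!r}")

    best_coords, best_stress = None, np.inf
    coords, stress = smacof(diss, metric=False, n_components=k,
                            init=pcoa_coords, n_init=1, max_iter=max_iter,
                            eps=eps, normalized_stress=True,
                            random_state=seed)
    best_coords, best_stress = coords, stress
    if n_restarts > 0:
        coords, stress = smacof(diss, metric=False, n_components=k,
                                n_init=n_restarts, max_iter=max_iter, eps=eps,
                                normalized_stress=True, random_state=seed)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    return OrdinationResult(
        pd.DataFrame(best_coords, index=ids,
                     columns=[f"axis{i + 1}" for i in range(k)]),
        float(best_stress), "nmds")


@dataclass
class ProcrustesResult:
    m12_squared: float
    t: float              # sqrt(1 - m12_squared), the protest statistic
    p: float
    n_permutations: int
    exact: bool = False


def _as_array(coords) -> np.ndarray:
    if isinstance(coords, OrdinationResult):
        return coords.coords.to_numpy(dtype=float)
    if isinstance(coords, pd.DataFrame):
        return coords.to_numpy(dtype=float)
    return np.asarray(coords, dtype=float)


def procrustes_test(X, Y, n_perm: int = 999, seed: int = 0) -> ProcrustesResult:
    """Procrustes superimposition with permutation significance (protest).

    Both configurations are centred and scaled, Y is optimally rotated onto
    X; the statistic is the residual sum of squares m12^2 (0 = perfect
    concordance).  Significance permutes the rows of Y; the p-value counts
    permutations at least as concordant (m12^2 <= observed).  When the
    number of samples is small enough that n! <= n_perm, all permutations
    are enumerated and the p-value is exact.
    """
    x = _as_array(X)
    y = _as_array(Y)
    if x.shape != y.shape:
        raise ValueError("configurations must have identical shape")
    n = x.shape[0]
    _, _, observed = _scipy_procrustes(x, y)

    if factorial(n) <= n_perm:
        count = total = 0
        for perm in iter_permutations(range(n)):
            _, _, m2 = _scipy_procrustes(x, y[list(perm)])
            count += m2 <= observed + 1e-12
            total += 1
        p = count / total
        return ProcrustesResult(float(observed),
                                float(np.sqrt(max(0.0, 1 - observed))),
                                float(p), total, exact=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, m2 = _scipy_procrustes(x, y[perm])
        count += m2 <= observed + 1e-12
    p = (1 + count) / (1 + n_perm)
    return ProcrustesResult(float(observed),
                            float(np.sqrt(max(0.0, 1 - observed))),
                            float(p), n_perm)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    exact: bool = False


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix,
                n_perm: int = 10000, seed: int = 0,
                alternative: str = "greater") -> MantelResult:
    """Mantel test between two distance matrices over matching labels.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    null permutes rows and columns of the second matrix simultaneously.
    One-sided by default (greater).  Small matrices (n! <= n_perm) are
    enumerated exactly.
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices have different labels")
        d2 = d2.filter(d1.ids)
    m1, m2 = d1.data, d2.data
    n = m1.shape[0]
    v1 = _upper(m1)
    observed = stats.pearsonr(v1, _upper(m2)).statistic

    def extreme(r: float) -> bool:
        if alternative == "greater":
            return r >= observed - 1e-12
        if alternative == "less":
            return r <= observed + 1e-12
        return abs(r) >= abs(observed) - 1e-12

    if factorial(n) <= n_perm:
        count = total = 0
        for perm in iter_permutations(range(n)):
            idx = np.asarray(perm)
            r = stats.pearsonr(v1, _upper(m2[np.ix_(idx, idx)])).statistic
            count += extreme(r)
            total += 1
        return MantelResult(float(observed), count / total, total, exact=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r = stats.pearsonr(v1, _upper(m2[np.ix_(idx, idx)])).statistic
        count += extreme(r)
    return MantelResult(float(observed), (1 + count) / (1 + n_perm), n_perm)
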