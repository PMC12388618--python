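"""Permutation tests on distance matrices: Mantel and PERMANOVA.

Both are implemented with an explicit per-call random generator so results
are reproducible given a seed. The Mantel statistic is the (Pearson or
Spearman) correlation between the upper triangles of two distance matrices,
with a one-sided permutation p-value (positive association). PERMANOVA uses
Anderson's pseudo-F from the within/between sum-of-squares decomposition of
a distance matrix, with group labels permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = ["DistanceMatrix", "mantel", "permanova", "bray_curtis_matrix", "euclidean_matrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered id list."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids),) * 2:
            raise ValueError("shape does not match ids")
        if np.any(np.isnan(v)):
            raise ValueError("NaN distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)


def bray_curtis_matrix(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples of a community table."""
    from .data_io import to_relative

    rel = to_relative(table)
    return DistanceMatrix(table.sample_ids, squareform(pdist(rel.counts, metric="braycurtis")))


def euclidean_matrix(ids, covariates: np.ndarray, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distances on (optionally z-scored) environmental covariates."""
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(ids):
        x = x.T
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(ids, squareform(pdist(x, metric="euclidean")))


def _check_ids(dx: DistanceMatrix, dy: DistanceMatrix):
    if dx.ids != dy.ids:
        raise KeyError("distance matrices must share identical ids in identical order")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_permutations: int = 999,
    method: str = "pearson",
    seed: int = 0,
) -> tuple:
    """Mantel correlation between two distance matrices.

    Returns (r, p) with p one-sided for positive association:
    p = (1 + #{permuted r >= observed r}) / (1 + n_permutations), permuting
    rows and columns of ``dy`` jointly.
    """
    _check_ids(dx, dy)
    n = dx.n
    if n < 4:
        raise ValueError("need at least 4 ids for a Mantel test")
    iu = np.triu_indices(n, 1)
    x = dx.values[iu]
    if method == "spearman":
        x = rankdata(x)
    if x.std() == 0:
        raise ValueError("zero variance in the upper triangle of dx")
    x_std = (x - x.mean()) / x.std()

    def corr(matrix) -> float:
        y = matrix[iu]
        if method == "spearman":
            y = rankdata(y)
        sd = y.std()
        if sd == 0:
            raise ValueError("zero variance in the upper triangle of dy")
        return float(x_std @ ((y - y.mean()) / sd)) / x.size

    r_obs = corr(dy.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(dy.values[np.ix_(perm, perm)]) >= r_obs - 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return r_obs, p


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    k = groups.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        raise ValueError("zero within-group sum of squares; pseudo-F undefined")
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: DistanceMatrix,
    groups: dict,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple:
    """PERMANOVA on a distance matrix; returns (pseudo_F, p)."""
    labels_raw = [groups[i] for i in d.ids]
    uniq = sorted(set(labels_raw))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    labels = np.array([uniq.index(l) for l in labels_raw])
    counts = np.bincount(labels)
    if counts.min() < 2:
        singles = [uniq[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"singleton groups not allowed: {singles}")
    d2 = d.values ** 2
    if d2.sum() == 0:
        raise ValueError("all distances zero; total sum of squares is zero")
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if _pseudo_f(d2, rng.permutation(labels)) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return f_obs, p
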