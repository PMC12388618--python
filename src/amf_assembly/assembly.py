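"""Null-model partitioning of community assembly processes.

Two complementary null models are computed for every unordered sample pair:

* **betaMNTD / betaNTI** — the abundance-weighted between-community mean
  nearest taxon distance, and its z-score against a null in which tip labels
  are randomly permuted across the whole OTU pool of the table. ``betaNTI >
  2`` signals variable selection, ``betaNTI < -2`` homogeneous selection.

* **RC_Bray** — a Raup-Crick style standardization of Bray-Curtis
  dissimilarity under a probabilistic assembly null: each community is
  reassembled by drawing its observed richness worth of OTUs (probability
  proportional to occupancy across all samples) and allocating its observed
  read total among them (probability proportional to mean relative
  abundance). Rescaled to [-1, 1]; ``> 0.95`` indicates dispersal
  limitation, ``< -0.95`` homogenizing dispersal.

Pairs with ``|betaNTI| < 2`` and ``|RC_Bray| < 0.95`` are "undominated".
The stochastic fraction is dispersal limitation + homogenizing dispersal +
undominated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .data_io import CommunityTable, PhylogeneticDistances

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseAssembly",
    "AssemblySummary",
    "PROCESSES",
    "bmntd",
    "bmntd_matrix",
    "bnti",
    "bnti_matrix",
    "rc_bray",
    "rc_bray_matrix",
    "partition_processes",
    "pairwise_assembly",
    "summarize_assembly",
    "phylo_mantel_correlogram",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

STOCHASTIC_PROCESSES = ("dispersal_limitation", "homogenizing_dispersal", "undominated")


@dataclass(frozen=True)
class PairwiseAssembly:
    sample_a: str
    sample_b: str
    bmntd_obs: float
    bnti: float
    rc_bray: float
    process: str | None  # None when the pair is flagged (degenerate null)
    flag: str | None = None


@dataclass(frozen=True)
class AssemblySummary:
    fractions: dict
    stochastic_fraction: float
    n_pairs: int


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _aligned(table: CommunityTable, dist: PhylogeneticDistances):
    """Distance matrix reordered to the table's OTU order."""
    if dist.otu_ids != table.otu_ids:
        dist = dist.reorder(table.otu_ids)
    return dist.matrix


def _weights(row: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    pres = row > 0
    w = np.zeros_like(row, dtype=float)
    if abundance_weighted:
        w[pres] = row[pres] / row[pres].sum()
    else:
        w[pres] = 1.0 / pres.sum()
    return w


def _bmntd_pair(d: np.ndarray, row_a, row_b, abundance_weighted=True) -> float:
    pa = np.flatnonzero(row_a > 0)
    pb = np.flatnonzero(row_b > 0)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("empty sample in betaMNTD")
    wa = _weights(row_a, abundance_weighted)[pa]
    wb = _weights(row_b, abundance_weighted)[pb]
    min_a = d[np.ix_(pa, pb)].min(axis=1)  # nearest taxon in b for each taxon in a
    min_b = d[np.ix_(pb, pa)].min(axis=1)
    return 0.5 * (float(wa @ min_a) + float(wb @ min_b))


def bmntd(table, dist, pair, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance for one sample pair."""
    d = _aligned(table, dist)
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    a, b = pair
    return _bmntd_pair(d, table.counts[idx[a]], table.counts[idx[b]], abundance_weighted)


def bmntd_matrix(table, dist, abundance_weighted: bool = True, _d: np.ndarray = None) -> np.ndarray:
    """All-pairs betaMNTD (n_samples x n_samples, zero diagonal), vectorized.

    For sample b let ``dmin_b(i) = min over OTUs j present in b of d(i, j)``;
    then betaMNTD(a, b) = 0.5 * (sum_i w_ia dmin_b(i) + sum_j w_jb dmin_a(j)),
    computed for all pairs with one matrix product.
    """
    d = _aligned(table, dist) if _d is None else _d
    counts = table.counts
    n_samp, n_otu = counts.shape
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("empty sample in betaMNTD")
    if abundance_weighted:
        w = counts / counts.sum(axis=1, keepdims=True)
    else:
        pres = counts > 0
        w = pres / pres.sum(axis=1, keepdims=True)
    m = np.empty((n_otu, n_samp))
    for s in range(n_samp):
        m[:, s] = d[:, counts[s] > 0].min(axis=1)
    g = w @ m  # g[a, b] = sum_i w_ia * dmin_b(i)
    return 0.5 * (g + g.T)


def bnti_matrix(
    table, dist, n_null: int = 999, seed: int = 0, abundance_weighted: bool = True
) -> tuple:
    """All-pairs betaNTI with a shared tip-label-shuffling null.

    Each null draw permutes tip identities across the whole OTU pool (rows
    and columns of the patristic matrix jointly) and recomputes betaMNTD for
    every pair.

    Returns
    -------
    (bmntd_obs, bnti) : two (n_samples x n_samples) arrays; bnti is NaN where
    the null standard deviation is zero.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    d = _aligned(table, dist)
    obs = bmntd_matrix(table, dist, abundance_weighted, _d=d)
    rng = np.random.default_rng(seed)
    n_otu = table.n_otus
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_otu)
        null = bmntd_matrix(table, dist, abundance_weighted, _d=d[np.ix_(perm, perm)])
        acc += null
        acc2 += null * null
    mean = acc / n_null
    var = acc2 / n_null - mean * mean
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / sd, np.nan)
    np.fill_diagonal(z, 0.0)
    return obs, z


def bnti(
    table,
    dist,
    pair,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    exhaustive: bool = False,
) -> float:
    """betaNTI z-score for one sample pair.

    With ``exhaustive=True`` the null enumerates every permutation of the OTU
    pool (feasible only for small pools) instead of sampling ``n_null`` draws.
    """
    d = _aligned(table, dist)
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    row_a = table.counts[idx[pair[0]]]
    row_b = table.counts[idx[pair[1]]]
    if int((row_a > 0).sum() + (row_b > 0).sum()) < 2:
        raise ValueError("need at least 2 OTUs present in the pair")
    obs = _bmntd_pair(d, row_a, row_b, abundance_weighted)
    n_otu = table.n_otus
    if exhaustive:
        if n_otu > 8:
            raise ValueError("exhaustive null only supported for <= 8 OTUs")
        nulls = [
            _bmntd_pair(d[np.ix_(p, p)], row_a, row_b, abundance_weighted)
            for p in itertools.permutations(range(n_otu))
        ]
    else:
        if n_null < 99:
            raise ValueError("n_null must be >= 99")
        rng = np.random.default_rng(seed)
        nulls = []
        for _ in range(n_null):
            p = rng.permutation(n_otu)
            nulls.append(_bmntd_pair(d[np.ix_(p, p)], row_a, row_b, abundance_weighted))
    nulls = np.asarray(nulls)
    sd = nulls.std()
    if sd <= 1e-12:
        logger.warning("degenerate betaNTI null (sd=0) for pair %s", pair)
        return float("nan")
    return float((obs - nulls.mean()) / sd)


# ---------------------------------------------------------------------------
# RC_Bray


def _integer_counts(table: CommunityTable) -> np.ndarray:
    counts = table.counts
    if table.is_relative or not np.allclose(counts, np.round(counts), atol=1e-6):
        raise ValueError("RC_Bray requires integer (or integerizable) counts")
    return np.round(counts).astype(np.int64)


def _pool_probabilities(counts: np.ndarray):
    """Occupancy-frequency and mean-relative-abundance weights over the pool."""
    occ = (counts > 0).sum(axis=0).astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    if occ.sum() == 0:
        raise ValueError("empty table")
    return occ / occ.sum(), mean_rel / mean_rel.sum()


def _assemble_null_sample(rng, richness, total, p_occ, p_abund):
    """One probabilistic community draw (Stegen-style two-stage assembly)."""
    n_otu = p_occ.size
    if richness > n_otu:
        raise ValueError("sample richness exceeds OTU pool size")
    drawn = rng.choice(n_otu, size=richness, replace=False, p=p_occ)
    w = p_abund[drawn]
    if w.sum() <= 0:
        w = np.ones(richness)
    comm = np.zeros(n_otu)
    comm[drawn] = rng.multinomial(total, w / w.sum())
    return comm


def _bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * np.minimum(a, b).sum() / denom


def _rc_from_counts(n_less: int, n_equal: int, n_null: int) -> float:
    return 2.0 * (n_less + 0.5 * n_equal) / n_null - 1.0


def rc_bray(table, pair, n_null: int = 999, seed: int = 0) -> float:
    """Raup-Crick standardized Bray-Curtis for one sample pair, in [-1, 1]."""
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = _integer_counts(table)
    p_occ, p_abund = _pool_probabilities(counts)
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = [counts[idx[pair[0]]], counts[idx[pair[1]]]]
    obs = _bray_curtis(*rows)
    rich = [int((r > 0).sum()) for r in rows]
    tot = [int(r.sum()) for r in rows]
    rng = np.random.default_rng(seed)
    n_less = n_equal = 0
    for _ in range(n_null):
        na = _assemble_null_sample(rng, rich[0], tot[0], p_occ, p_abund)
        nb = _assemble_null_sample(rng, rich[1], tot[1], p_occ, p_abund)
        bc = _bray_curtis(na, nb)
        if np.isclose(bc, obs, atol=1e-12):
            n_equal += 1
        elif bc < obs:
            n_less += 1
    return _rc_from_counts(n_less, n_equal, n_null)


def rc_bray_matrix(table, n_null: int = 999, seed: int = 0) -> np.ndarray:
    """All-pairs RC_Bray; per null draw every sample is reassembled once and
    Bray-Curtis is evaluated for all pairs of that draw."""
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = _integer_counts(table)
    p_occ, p_abund = _pool_probabilities(counts)
    rich = (counts > 0).sum(axis=1)
    tot = counts.sum(axis=1)
    obs = squareform(pdist(counts, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    n_samp = table.n_samples
    n_less = np.zeros((n_samp, n_samp))
    n_equal = np.zeros((n_samp, n_samp))
    for _ in range(n_null):
        null = np.stack(
            [
                _assemble_null_sample(rng, int(rich[s]), int(tot[s]), p_occ, p_abund)
                for s in range(n_samp)
            ]
        )
        bc = squareform(pdist(null, metric="braycurtis"))
        eq = np.isclose(bc, obs, atol=1e-12)
        n_equal += eq
        n_less += (~eq) & (bc < obs)
    rc = _rc_from_counts(n_less, n_equal, n_null)
    np.fill_diagonal(rc, 0.0)
    return rc


# ---------------------------------------------------------------------------
# Partitioning


def partition_processes(bnti_value: float, rc: float) -> str:
    """Five-way process assignment from (betaNTI, RC_Bray).

    Selection dominates when |betaNTI| > 2 (variable if positive, homogeneous
    if negative); otherwise RC_Bray > 0.95 -> dispersal limitation, RC_Bray <
    -0.95 -> homogenizing dispersal, else undominated. Boundary values fall
    to the stochastic / undominated side (strict inequalities).
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc)):
        raise ValueError("non-finite betaNTI or RC_Bray; exclude flagged pairs upstream")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(
    table: CommunityTable,
    dist: PhylogeneticDistances,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> list:
    """betaNTI + RC_Bray + process label for every unordered sample pair."""
    obs, z = bnti_matrix(table, dist, n_null=n_null, seed=seed, abundance_weighted=abundance_weighted)
    rc = rc_bray_matrix(table, n_null=n_null, seed=int(seed) + 1)
    out = []
    ids = table.sample_ids
    for a in range(table.n_samples):
        for b in range(a + 1, table.n_samples):
            if np.isnan(z[a, b]):
                out.append(PairwiseAssembly(ids[a], ids[b], obs[a, b], float("nan"),
                                            rc[a, b], None, flag="degenerate_null_sd0"))
            else:
                out.append(
                    PairwiseAssembly(
                        ids[a], ids[b], obs[a, b], z[a, b], rc[a, b],
                        partition_processes(z[a, b], rc[a, b]),
                    )
                )
    return out


def summarize_assembly(pairs) -> AssemblySummary:
    """Process fractions over valid (unflagged) pairs; flagged pairs are
    excluded from the denominator."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to summarize")
    valid = [p for p in pairs if p.process is not None]
    if not valid:
        raise ValueError("all pairs flagged; nothing to summarize")
    n = len(valid)
    fractions = {proc: sum(p.process == proc for p in valid) / n for proc in PROCESSES}
    stochastic = sum(fractions[p] for p in STOCHASTIC_PROCESSES)
    return AssemblySummary(fractions=fractions, stochastic_fraction=stochastic, n_pairs=n)


# ---------------------------------------------------------------------------
# Phylogenetic signal (Mantel correlogram)


def phylo_mantel_correlogram(
    dist: PhylogeneticDistances,
    niche_values: dict,
    n_classes: int = 6,
    n_permutations: int = 999,
    seed: int = 0,
) -> list:
    """Mantel correlogram of phylogenetic distance vs niche differences.

    Phylogenetic distances are split into ``n_classes`` equal-frequency
    classes; for each class the Mantel correlation between the class
    membership indicator and pairwise absolute niche differences is computed
    (sign flipped so that positive r = niche similarity within the class),
    with permutation p-values corrected sequentially (Holm).

    Returns a list of dicts with keys class_index, d_lower, d_upper, n_pairs,
    r, p_value, p_corrected.
    """
    otus = [o for o in dist.otu_ids if o in niche_values]
    if len(otus) < 3:
        raise ValueError("need at least 3 OTUs with niche values")
    if len(otus) < 10:
        logger.warning("only %d OTUs with niche values; correlogram may be unstable", len(otus))
    d = dist.reorder(otus).matrix
    vals = np.array([niche_values[o] for o in otus], dtype=float)
    n = len(otus)
    iu = np.triu_indices(n, 1)
    dx = d[iu]
    edges = np.quantile(dx, np.linspace(0, 1, n_classes + 1))
    indicators, bounds = [], []
    for k in range(n_classes):
        if k < n_classes - 1:
            mask = (dx >= edges[k]) & (dx < edges[k + 1])
        else:
            mask = (dx >= edges[k]) & (dx <= edges[k + 1])
        if mask.sum() < 2:
            logger.warning("distance class %d has <2 pairs; dropped", k)
            continue
        indicators.append(mask.astype(float))
        bounds.append((k, float(edges[k]), float(edges[k + 1]), int(mask.sum())))
    if not indicators:
        raise ValueError("no usable distance classes")
    ind = np.stack(indicators)
    ind_std = (ind - ind.mean(axis=1, keepdims=True)) / ind.std(axis=1, keepdims=True)

    def class_r(values: np.ndarray) -> np.ndarray:
        dy = np.abs(values[:, None] - values[None, :])[iu]
        sd = dy.std()
        if sd == 0:
            return np.zeros(ind.shape[0])
        dy_std = (dy - dy.mean()) / sd
        # sign flipped: within-class similarity reads as positive correlation
        return -(ind_std @ dy_std) / dx.size

    r_obs = class_r(vals)
    rng = np.random.default_rng(seed)
    exceed = np.ones_like(r_obs)  # +1 pseudo-count for the observed
    for _ in range(n_permutations):
        r_perm = class_r(rng.permutation(vals))
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-15
    p = exceed / (n_permutations + 1)
    p_corr = multipletests(p, method="holm")[1]
    return [
        {
            "class_index": b[0],
            "d_lower": b[1],
            "d_upper": b[2],
            "n_pairs": b[3],
            "r": float(r_obs[i]),
            "p_value": float(p[i]),
            "p_corrected": float(p_corr[i]),
        }
        for i, b in enumerate(bounds)
    ]
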