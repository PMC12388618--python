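"""Co-occurrence network construction and stability/complexity metrics.

Per salinity level, OTUs with mean relative abundance > 0.1% are correlated
pairwise (Spearman, tie-corrected); edges are pairs with |rho| above a
threshold and a Benjamini-Hochberg-adjusted p below alpha. On the resulting
graph:

* **robustness** — the proportion of taxa that still have at least one edge
  after removing a fraction of nodes (uniformly at random, repeated; or
  targeted by descending degree), mean +/- sd over repetitions;
* **vulnerability** — max over nodes of the relative drop in global
  efficiency (mean inverse shortest-path length over node pairs) when that
  node is deleted;
* **cohesion** — per sample, the abundance-weighted sum of each OTU's mean
  positive (resp. negative) null-corrected correlation with the other OTUs;
  network complexity = positive cohesion + |negative cohesion|.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_io import CommunityTable, to_relative

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "StabilityReport",
    "CohesionResult",
    "filter_abundant_otus",
    "build_network",
    "robustness",
    "vulnerability",
    "cohesion",
    "topological_properties",
]


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Undirected OTU co-occurrence graph plus its build parameters."""

    graph: nx.Graph = field(repr=False)
    rho_threshold: float
    alpha: float
    p_adjust_method: str
    abundance_filter: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"otu_a": a, "otu_b": b, "rho": d["rho"], "p_adjusted": d["p_adjusted"],
             "sign": d["sign"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_adjusted", "sign"])


@dataclass(frozen=True)
class StabilityReport:
    robustness_mean: float
    robustness_sd: float
    vulnerability: float
    removal_fraction: float
    n_repetitions: int


@dataclass(frozen=True)
class CohesionResult:
    """Per-sample cohesion and per-OTU connectedness."""

    sample_ids: tuple
    positive_cohesion: np.ndarray
    negative_cohesion: np.ndarray
    positive_connectedness: dict
    negative_connectedness: dict

    @property
    def complexity(self) -> np.ndarray:
        return self.positive_cohesion + np.abs(self.negative_cohesion)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "positive_cohesion": self.positive_cohesion,
                "negative_cohesion": self.negative_cohesion,
                "complexity": self.complexity,
            },
            index=pd.Index(list(self.sample_ids), name="sample_id"),
        )


def filter_abundant_otus(table: CommunityTable, min_mean_relative_abundance: float = 0.001) -> CommunityTable:
    """Keep OTUs whose mean relative abundance exceeds the threshold (strict >)."""
    rel = to_relative(table)
    means = rel.counts.mean(axis=0)
    keep = means > min_mean_relative_abundance
    if not keep.any():
        raise ValueError("no OTU passes the abundance filter")
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.subset_otus(kept)


def build_network(
    table: CommunityTable,
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
    p_adjust: str = "fdr_bh",
    min_samples: int = 5,
) -> CooccurrenceNetwork:
    """Spearman co-occurrence network over the table's OTUs.

    All pairwise tie-corrected Spearman correlations are tested; p-values are
    adjusted across every tested pair; an edge is kept when |rho| >=
    rho_threshold and adjusted p < alpha. Zero-variance OTUs are skipped with
    a warning. Isolated OTUs are not nodes.
    """
    if table.n_samples < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {table.n_samples}")
    if table.n_otus < 3:
        raise ValueError("need at least 3 OTUs to build a network")
    x = table.counts
    variable = x.std(axis=0) > 0
    if not variable.all():
        logger.warning("skipping %d constant OTU vectors", int((~variable).sum()))
    cols = np.flatnonzero(variable)
    if cols.size < 2:
        raise ValueError("fewer than 2 variable OTUs")
    sub = x[:, cols]
    rho, p = sps.spearmanr(sub, axis=0)
    if cols.size == 2:  # spearmanr returns scalars for 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    iu = np.triu_indices(cols.size, 1)
    p_flat = p[iu]
    p_adj = multipletests(p_flat, method=p_adjust)[1]
    g = nx.Graph()
    for (ii, jj), r_val, q in zip(zip(*iu), rho[iu], p_adj):
        if abs(r_val) >= rho_threshold and q < alpha:
            a, b = table.otu_ids[cols[ii]], table.otu_ids[cols[jj]]
            g.add_edge(a, b, rho=float(r_val), p_adjusted=float(q),
                       sign="+" if r_val > 0 else "-")
    return CooccurrenceNetwork(
        graph=g, rho_threshold=rho_threshold, alpha=alpha,
        p_adjust_method=p_adjust, abundance_filter=0.001,
    )


def robustness(
    net: CooccurrenceNetwork,
    removal_fraction: float = 0.5,
    n_repetitions: int = 100,
    mode: str = "random",
    seed: int = 0,
) -> StabilityReport:
    """Proportion of taxa remaining connected after node removal.

    Per repetition, floor(removal_fraction * n) nodes are removed (uniformly
    at random, or by descending degree for ``mode="targeted_by_degree"``,
    which is deterministic so repetitions collapse to one); a surviving node
    "remains" if it retains >= 1 edge; robustness = remaining / original n.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    g = net.graph
    n = g.number_of_nodes()
    if n < 4:
        raise ValueError("need at least 4 nodes")
    nodes = sorted(g.nodes())
    k = int(np.floor(removal_fraction * n))
    if mode == "targeted_by_degree":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
        removal_sets = [order[:k]]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        removal_sets = [
            [nodes[i] for i in rng.choice(n, size=k, replace=False)]
            for _ in range(n_repetitions)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = []
    for removed in removal_sets:
        h = g.copy()
        h.remove_nodes_from(removed)
        remaining = sum(1 for v in h.nodes() if h.degree(v) > 0)
        values.append(remaining / n)
    values = np.asarray(values)
    vuln = vulnerability(net)
    return StabilityReport(
        robustness_mean=float(values.mean()),
        robustness_sd=float(values.std()),
        vulnerability=vuln,
        removal_fraction=removal_fraction,
        n_repetitions=len(removal_sets),
    )


def _global_efficiency(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return nx.global_efficiency(g)


def vulnerability(net: CooccurrenceNetwork) -> float:
    """Max over nodes of the relative global-efficiency drop on deletion.

    V_i = (E - E_i) / E with E the global efficiency (mean inverse unweighted
    shortest-path length over unordered pairs; disconnected pairs contribute
    0) and E_i the efficiency after deleting node i.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    e = _global_efficiency(g)
    if e == 0:
        raise ValueError("edgeless network has zero global efficiency")
    worst = -np.inf
    for v in sorted(g.nodes()):
        h = g.copy()
        h.remove_node(v)
        worst = max(worst, (e - _global_efficiency(h)) / e)
    return float(worst)


def cohesion(table: CommunityTable, n_null: int = 200, seed: int = 0) -> CohesionResult:
    """Null-corrected cohesion (positive and negative) per sample.

    Pairwise Pearson correlations between OTU abundance profiles are
    corrected by subtracting their expectation under a taxa-shuffle null
    (each OTU's abundances independently permuted across samples, ``n_null``
    shuffles). Each OTU's positive (negative) connectedness is the mean of
    its positive (negative) corrected correlations; per-sample cohesion is
    the relative-abundance-weighted sum of connectedness values.

    Each OTU's null permutation stream is seeded from (seed, otu_id), and
    permutations act on the sorted sample order, so the result does not
    depend on row or column ordering of the table.
    """
    if table.n_samples < 2:
        raise ValueError("cohesion needs at least 2 samples")
    rel = to_relative(table)
    x = rel.counts
    n_samp, n_otu = x.shape
    variable = x.std(axis=0) > 0
    obs = np.zeros((n_otu, n_otu))
    if variable.sum() >= 2:
        sub = np.corrcoef(x[:, variable], rowvar=False)
        obs[np.ix_(np.flatnonzero(variable), np.flatnonzero(variable))] = sub
    np.fill_diagonal(obs, 0.0)
    null_mean = np.zeros_like(obs)
    vidx = np.flatnonzero(variable)
    sample_order = np.argsort(np.asarray(table.sample_ids))
    rank_of = np.empty(n_samp, dtype=int)
    rank_of[sample_order] = np.arange(n_samp)
    perms = np.empty((n_null, n_samp, vidx.size), dtype=int)
    for col, j in enumerate(vidx):
        rng_j = np.random.default_rng([int(seed), zlib.crc32(table.otu_ids[j].encode())])
        for k in range(n_null):
            # permute in canonical (sorted-id) sample order, map back to rows
            perms[k, :, col] = sample_order[rng_j.permutation(n_samp)][rank_of]
    for k in range(n_null):
        shuffled = np.take_along_axis(x[:, vidx], perms[k], axis=0)
        c = np.corrcoef(shuffled, rowvar=False)
        np.fill_diagonal(c, 0.0)
        null_mean[np.ix_(vidx, vidx)] += c
    null_mean /= n_null
    corrected = obs - null_mean
    np.fill_diagonal(corrected, 0.0)
    pos_conn = np.zeros(n_otu)
    neg_conn = np.zeros(n_otu)
    for j in range(n_otu):
        row = np.delete(corrected[j], j)
        pos = row[row > 0]
        neg = row[row < 0]
        pos_conn[j] = pos.mean() if pos.size else 0.0
        neg_conn[j] = neg.mean() if neg.size else 0.0
    pos_cohesion = x @ pos_conn
    neg_cohesion = x @ neg_conn
    return CohesionResult(
        sample_ids=table.sample_ids,
        positive_cohesion=pos_cohesion,
        negative_cohesion=neg_cohesion,
        positive_connectedness={o: float(pos_conn[j]) for j, o in enumerate(table.otu_ids)},
        negative_connectedness={o: float(neg_conn[j]) for j, o in enumerate(table.otu_ids)},
    )


def topological_properties(net: CooccurrenceNetwork) -> dict:
    """Standard descriptors: size, density, clustering, modularity, path length."""
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    props = {
        "n_nodes": n,
        "n_edges": m,
        "positive_edge_fraction": (
            sum(1 for *_, d in g.edges(data=True) if d.get("sign") == "+") / m if m else float("nan")
        ),
        "mean_degree": 2 * m / n if n else float("nan"),
        "density": nx.density(g) if n > 1 else float("nan"),
        "clustering_coefficient": nx.average_clustering(g) if n else float("nan"),
    }
    if m:
        communities = nx.community.greedy_modularity_communities(g)
        props["modularity"] = nx.community.modularity(g, communities)
        largest = g.subgraph(max(nx.connected_components(g), key=len))
        props["average_path_length"] = (
            nx.average_shortest_path_length(largest) if largest.number_of_nodes() > 1 else float("nan")
        )
    else:
        props["modularity"] = float("nan")
        props["average_path_length"] = float("nan")
    return props
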