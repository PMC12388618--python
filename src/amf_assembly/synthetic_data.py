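"""Synthetic AM-fungal-like datasets with known ground truth.

Emulates the study design every analysis stage expects: ~54 samples in ~11
sites along a 0-11 mS/cm soil-salinity gradient, ~428 OTUs in ~12 genera,
uniform read depth. Six scenarios plant different assembly mechanisms:

* ``neutral`` — local communities drawn from the Sloan stationary Beta
  around a log-series metacommunity (ground truth for the neutral-model fit;
  ``migration_rate=1`` gives the well-mixed limit with no habitat structure,
  the reference condition for niche-classification calibration).
* ``selection`` — Gaussian niche kernels around salinity optima evolved by
  Brownian motion on the simulated phylogeny (variable selection across the
  gradient, detectable phylogenetic signal).
* ``dispersal_limited`` — per-site endemic OTU pools with small overlap and
  no salinity coupling (dispersal limitation between sites).
* ``planted_generalist`` / ``planted_specialist`` — an aggregated background
  community plus one engineered OTU occupying every sample evenly (or only
  one site's samples).
* ``mid_salinity_coupling`` — a latent-factor copula that makes inter-OTU
  correlation broadest and network topology most fragile in the middle
  salinity bin: extremes get few tight cliques (robust), the middle gets
  many near-deterministic pairs plus a broad moderate factor (high cohesion,
  fragile matching-like graph).

Every generator is bit-reproducible given the seed and returns objects that
pass data_io validation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .data_io import (
    CommunityTable,
    PhylogeneticDistances,
    SampleMetadata,
    SalinityBinning,
    patristic_distances,
)

__all__ = ["ScenarioConfig", "SimulatedDataset", "simulate", "simulate_tree"]

SCENARIOS = (
    "neutral",
    "selection",
    "dispersal_limited",
    "planted_generalist",
    "planted_specialist",
    "mid_salinity_coupling",
)


@dataclass
class ScenarioConfig:
    """Study-design parameters; defaults mirror the field survey's scale."""

    seed: int
    scenario: str = "neutral"
    n_samples: int = 54
    n_sites: int = 11
    n_otus: int = 428
    n_genera: int = 12
    reads_per_sample: int = 10000
    salinity_range: tuple = (0.0, 11.0)
    # metacommunity rank-abundance shape (log-series-like)
    logseries_x: float = 0.998
    # neutral scenario; well_mixed skips the Sloan drift stage (each sample a
    # pure multinomial draw from the metacommunity -> no habitat structure,
    # the reference condition for occupancy-null calibration)
    migration_rate: float = 0.1
    well_mixed: bool = False
    # selection scenario: Gaussian niche kernel width (mS/cm) and BM rate
    niche_breadth_sd: float = 1.5
    brownian_rate: float = 1.0
    # dispersal scenario: fraction of the pool shared by all sites, and the
    # probability that a pool member occurs in any one sample of its site
    site_overlap: float = 0.05
    within_site_presence: float = 0.8
    # planted scenarios: planted OTU's expected relative abundance
    planted_abundance: float = 0.01
    # mid-salinity coupling scenario
    broad_set_size: int = 80
    broad_loading: float = 0.7
    n_strong_pairs: int = 8
    clique_size: int = 5
    n_cliques: int = 3
    factor_log_sd: float = 1.2
    noise_log_sd: float = 0.3
    coupled_abundance_floor: float = 0.012
    broad_abundance_floor: float = 0.004
    # steeper background rank-abundance for the network scenario keeps the
    # number of OTUs passing the 0.1% filter (hence the number of tested
    # pairs) moderate at ~11 samples per bin
    background_logseries_x: float = 0.99

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        for name in ("n_samples", "n_sites", "n_otus", "n_genera", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.salinity_range
        if not hi > lo:
            raise ValueError("salinity_range must be non-degenerate")


@dataclass
class SimulatedDataset:
    table: CommunityTable
    metadata: list
    newick: str
    distances: PhylogeneticDistances
    taxonomy: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks


def _otu_labels(n: int) -> list:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def simulate_tree(n_otus: int, seed: int):
    """Birth-death phylogeny with positive branch lengths.

    Returns (newick string, PhylogeneticDistances) with tips OTU_0001..;
    deterministic given seed.
    """
    if n_otus < 3:
        raise ValueError("need at least 3 OTUs")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_otus, rng=random.Random(int(seed))
    )
    labels = _otu_labels(n_otus)
    for tip, label in zip(tree.leaf_node_iter(), labels):
        tip.taxon.label = label
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 1e-6:
            edge.length = 1e-6  # birth-death trees can emit zero-length branches
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, patristic_distances(tree, labels), tree


def _metacommunity(n_otus: int, x: float, rng) -> np.ndarray:
    """Log-series-like rank abundances, randomly assigned to OTU indices."""
    ranks = np.arange(1, n_otus + 1, dtype=float)
    p = x ** ranks / ranks
    p /= p.sum()
    return p[rng.permutation(n_otus)]


def _sites_along_gradient(cfg: ScenarioConfig, rng):
    """Sites evenly spread over the salinity range; samples round-robin."""
    lo, hi = cfg.salinity_range
    span = hi - lo
    site_sal = np.linspace(lo + 0.02 * span, hi - 0.02 * span, cfg.n_sites)
    site_of = np.arange(cfg.n_samples) % cfg.n_sites
    sal = np.clip(site_sal[site_of] + rng.normal(0, 0.02 * span, cfg.n_samples), lo, hi)
    return site_of, sal


def _metadata(cfg, site_of, sal) -> list:
    return [
        SampleMetadata(f"S{i + 1:02d}", f"site_{site_of[i] + 1:02d}", float(sal[i]))
        for i in range(cfg.n_samples)
    ]


def _taxonomy(tree: dendropy.Tree, n_genera: int) -> dict:
    """Genera as contiguous clades of the tip ordering, nested in 4 families
    and 3 orders (the study's taxonomic backbone)."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    chunks = np.array_split(np.arange(len(tips)), n_genera)
    tax = {}
    for g, idx in enumerate(chunks):
        family = g * 4 // n_genera + 1
        order = g * 3 // n_genera + 1
        for i in idx:
            tax[tips[i]] = (f"Genus_{g + 1:02d}", f"Family_{family}", f"Order_{order}")
    return tax


def _multinomial_rows(expected: np.ndarray, reads: int, rng) -> np.ndarray:
    counts = np.empty_like(expected, dtype=np.int64)
    for i in range(expected.shape[0]):
        p = expected[i] / expected[i].sum()
        counts[i] = rng.multinomial(reads, p)
    return counts


def _finalize(cfg, counts, meta, newick, dist, tree, truth) -> SimulatedDataset:
    table = CommunityTable(
        tuple(m.sample_id for m in meta), tuple(_otu_labels(cfg.n_otus)), counts
    )
    return SimulatedDataset(
        table=table,
        metadata=meta,
        newick=newick,
        distances=dist,
        taxonomy=_taxonomy(tree, cfg.n_genera),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# scenarios


def simulate_neutral(cfg: ScenarioConfig) -> SimulatedDataset:
    """Sloan stationary sampling around a log-series metacommunity."""
    m = cfg.migration_rate
    if not 0 < m <= 1:
        raise ValueError("migration_rate must be in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    newick, dist, tree = simulate_tree(cfg.n_otus, cfg.seed)
    meta_p = _metacommunity(cfg.n_otus, cfg.logseries_x, rng)
    site_of, sal = _sites_along_gradient(cfg, rng)
    N = cfg.reads_per_sample
    a = N * m * meta_p
    b = N * m * (1.0 - meta_p)
    counts = np.empty((cfg.n_samples, cfg.n_otus), dtype=np.int64)
    for i in range(cfg.n_samples):
        if cfg.well_mixed:
            local = meta_p
        else:
            local = rng.beta(a, b)
        total = local.sum()
        if total <= 0:
            local = meta_p
            total = 1.0
        counts[i] = rng.multinomial(N, local / total)
    meta = _metadata(cfg, site_of, sal)
    truth = {
        "scenario": "neutral",
        "m": m,
        "N": N,
        "well_mixed": cfg.well_mixed,
        "metacommunity": meta_p.tolist(),
    }
    return _finalize(cfg, counts, meta, newick, dist, tree, truth)


def _brownian_optima(tree: dendropy.Tree, rate: float, rng) -> dict:
    """Trait values evolved along branches: child = parent + N(0, rate*length)."""
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            length = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(0, np.sqrt(rate * max(length, 1e-9)))
    return {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}


def simulate_selection(cfg: ScenarioConfig) -> SimulatedDataset:
    """Gaussian niche filtering around phylogenetically conserved optima."""
    rng = np.random.default_rng(cfg.seed)
    newick, dist, tree = simulate_tree(cfg.n_otus, cfg.seed)
    raw = _brownian_optima(tree, cfg.brownian_rate, rng)
    labels = _otu_labels(cfg.n_otus)
    vals = np.array([raw[o] for o in labels])
    lo, hi = cfg.salinity_range
    # rescale optima to span the gradient so selection is detectable but not saturated
    optima = lo + (vals - vals.min()) / (vals.max() - vals.min()) * (hi - lo)
    meta_p = _metacommunity(cfg.n_otus, cfg.logseries_x, rng)
    site_of, sal = _sites_along_gradient(cfg, rng)
    kernel = np.exp(-((sal[:, None] - optima[None, :]) ** 2) / (2 * cfg.niche_breadth_sd**2))
    expected = meta_p[None, :] * kernel * rng.lognormal(0, cfg.noise_log_sd, kernel.shape)
    expected += 1e-12
    counts = _multinomial_rows(expected, cfg.reads_per_sample, rng)
    meta = _metadata(cfg, site_of, sal)
    truth = {
        "scenario": "selection",
        "optima": {o: float(v) for o, v in zip(labels, optima)},
        "niche_breadth_sd": cfg.niche_breadth_sd,
    }
    return _finalize(cfg, counts, meta, newick, dist, tree, truth)


def simulate_dispersal_limited(cfg: ScenarioConfig) -> SimulatedDataset:
    """Nearly disjoint per-site OTU pools, no salinity-abundance coupling."""
    rng = np.random.default_rng(cfg.seed)
    newick, dist, tree = simulate_tree(cfg.n_otus, cfg.seed)
    meta_p = _metacommunity(cfg.n_otus, cfg.logseries_x, rng)
    site_of, sal = _sites_along_gradient(cfg, rng)
    n_shared = max(1, int(round(cfg.site_overlap * cfg.n_otus)))
    # only rare taxa are shared between sites, so between-site pairs overlap
    # in (at most) taxa that carry almost no abundance
    by_abundance = np.argsort(meta_p)
    shared = by_abundance[:n_shared]
    endemic = np.array_split(rng.permutation(by_abundance[n_shared:]), cfg.n_sites)
    pools = [np.concatenate([shared, e]) for e in endemic]
    expected = np.zeros((cfg.n_samples, cfg.n_otus))
    for i in range(cfg.n_samples):
        pool = pools[site_of[i]]
        # each sample holds a random subset of its site pool, so presence
        # varies between same-site samples
        present = pool[rng.random(pool.size) < cfg.within_site_presence]
        if present.size < 2:
            present = pool[:2]
        expected[i, present] = meta_p[present] * rng.lognormal(0, cfg.noise_log_sd, present.size)
    counts = _multinomial_rows(expected, cfg.reads_per_sample, rng)
    meta = _metadata(cfg, site_of, sal)
    truth = {
        "scenario": "dispersal_limited",
        "site_pools": {f"site_{s + 1:02d}": sorted(int(j) for j in pools[s]) for s in range(cfg.n_sites)},
        "site_overlap": cfg.site_overlap,
    }
    return _finalize(cfg, counts, meta, newick, dist, tree, truth)


def _planted_background(cfg, rng):
    """Aggregated background: each OTU occupies a random sample subset."""
    meta_p = _metacommunity(cfg.n_otus, cfg.logseries_x, rng)
    expected = np.zeros((cfg.n_samples, cfg.n_otus))
    for j in range(cfg.n_otus):
        k = rng.integers(3, max(4, cfg.n_samples // 3))
        occupied = rng.choice(cfg.n_samples, size=k, replace=False)
        expected[occupied, j] = meta_p[j] * rng.lognormal(0, 0.5, k)
    return expected


def _simulate_planted(cfg: ScenarioConfig, kind: str) -> SimulatedDataset:
    rng = np.random.default_rng(cfg.seed)
    newick, dist, tree = simulate_tree(cfg.n_otus, cfg.seed)
    site_of, sal = _sites_along_gradient(cfg, rng)
    expected = _planted_background(cfg, rng)
    planted = 0  # OTU_0001 carries the engineered distribution
    expected[:, planted] = 0.0
    row_mass = expected.sum(axis=1)
    target = cfg.planted_abundance / (1 - cfg.planted_abundance)
    if kind == "specialist":
        home_site = 0
        members = np.flatnonzero(site_of == home_site)
        # concentrated and abundant within one site's samples
        expected[members, planted] = 20 * target * row_mass[members]
        counts = _multinomial_rows(expected + 1e-12, cfg.reads_per_sample, rng)
    else:
        # generalist: deterministically even occupancy — the same count in
        # every sample, injected after sampling the background community
        c = max(1, int(round(cfg.planted_abundance * cfg.reads_per_sample)))
        counts = np.empty((cfg.n_samples, cfg.n_otus), dtype=np.int64)
        background = _multinomial_rows(expected + 1e-12, cfg.reads_per_sample - c, rng)
        counts[:] = background
        counts[:, planted] = c
    meta = _metadata(cfg, site_of, sal)
    truth = {"scenario": f"planted_{kind}", "planted_otu": _otu_labels(cfg.n_otus)[planted]}
    return _finalize(cfg, counts, meta, newick, dist, tree, truth)


def simulate_planted_generalist(cfg):
    return _simulate_planted(cfg, "generalist")


def simulate_planted_specialist(cfg):
    return _simulate_planted(cfg, "specialist")


def simulate_network_scenario(cfg: ScenarioConfig) -> SimulatedDataset:
    """Latent-factor copula with bin-dependent correlation structure.

    Middle salinity bin: many near-deterministic OTU pairs (a fragile,
    matching-like graph) plus a broad moderate factor over many abundant
    OTUs (high cohesion without exceeding the edge threshold). Outer bins:
    a few tight cliques (robust graphs, little broad coupling). Shoulder
    bins interpolate.
    """
    rng = np.random.default_rng(cfg.seed)
    newick, dist, tree = simulate_tree(cfg.n_otus, cfg.seed)
    lo, hi = cfg.salinity_range
    binning = SalinityBinning(tuple(np.linspace(lo, hi, 6))) if (lo, hi) != (0.0, 11.0) else SalinityBinning()
    edges = np.asarray(binning.bin_edges)
    n_bins = len(binning.bin_labels)
    # samples spread evenly over bins; 2-3 sites per bin
    bin_of = np.arange(cfg.n_samples) % n_bins
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = edges[1:] - edges[:-1]
    sal = np.clip(
        centers[bin_of] + rng.uniform(-0.4, 0.4, cfg.n_samples) * widths[bin_of],
        lo, hi,
    )
    site_of = bin_of * 2 + (np.arange(cfg.n_samples) // n_bins) % 2
    meta_p = _metacommunity(cfg.n_otus, cfg.background_logseries_x, rng)
    # coupled structure lives in moderately abundant OTUs: the dominant taxa
    # are left uncoupled so shared factors do not shock the compositional
    # denominator, and coupled OTUs get an abundance floor so they pass the
    # 0.1% mean-relative-abundance network filter in every bin
    ranked = np.argsort(meta_p)[::-1]
    candidates = rng.permutation(ranked[20:240])
    cursor = 0

    def take(k):
        nonlocal cursor
        out = candidates[cursor : cursor + k]
        cursor += k
        return out

    mid = n_bins // 2
    structures = {b: [] for b in range(n_bins)}  # (otu indices, loading)
    broad_sets = {}
    strong, broad = [], []
    for b in range(n_bins):
        dist_to_mid = abs(b - mid)
        if dist_to_mid == 0:
            for _ in range(cfg.n_strong_pairs):
                pair = take(2)
                structures[b].append((pair, 0.995))
                strong.append(pair)
            broad_sets[b] = (take(cfg.broad_set_size), cfg.broad_loading)
            broad.append(broad_sets[b][0])
        elif dist_to_mid == 1:
            for _ in range(max(1, cfg.n_cliques - 1)):
                clique = take(max(3, cfg.clique_size - 1))
                structures[b].append((clique, 0.995))
                strong.append(clique)
            broad_sets[b] = (take(cfg.broad_set_size // 2), cfg.broad_loading * 0.85)
            broad.append(broad_sets[b][0])
        else:
            for _ in range(cfg.n_cliques):
                clique = take(cfg.clique_size)
                structures[b].append((clique, 0.995))
                strong.append(clique)
            broad_sets[b] = (np.array([], dtype=int), 0.0)
    meta_p = meta_p.copy()
    strong_idx = np.concatenate(strong)
    meta_p[strong_idx] = np.maximum(meta_p[strong_idx], cfg.coupled_abundance_floor)
    broad_idx = np.concatenate(broad)
    meta_p[broad_idx] = np.maximum(meta_p[broad_idx], cfg.broad_abundance_floor)
    meta_p /= meta_p.sum()

    z = rng.normal(0, 1, (cfg.n_samples, cfg.n_otus))  # idiosyncratic log-noise
    log_expected = np.log(meta_p)[None, :] + cfg.noise_log_sd * z
    for b in range(n_bins):
        rows = np.flatnonzero(bin_of == b)
        for otus, w in structures[b]:
            factor = rng.normal(0, 1, rows.size)
            log_expected[np.ix_(rows, otus)] = (
                np.log(meta_p[otus])[None, :]
                + cfg.factor_log_sd * (w * factor[:, None] + np.sqrt(1 - w**2) * rng.normal(0, 1, (rows.size, otus.size)))
            )
        otus, w = broad_sets[b]
        if otus.size:
            factor = rng.normal(0, 1, rows.size)
            log_expected[np.ix_(rows, otus)] = (
                np.log(meta_p[otus])[None, :]
                + cfg.factor_log_sd * (w * factor[:, None] + np.sqrt(1 - w**2) * rng.normal(0, 1, (rows.size, otus.size)))
            )
    expected = np.exp(log_expected)
    counts = _multinomial_rows(expected, cfg.reads_per_sample, rng)
    meta = _metadata(cfg, site_of, sal)
    truth = {
        "scenario": "mid_salinity_coupling",
        "bin_labels": list(binning.bin_labels),
        "mid_bin": binning.bin_labels[mid],
        "structures": {
            binning.bin_labels[b]: [sorted(int(j) for j in otus) for otus, _ in structures[b]]
            for b in range(n_bins)
        },
    }
    return _finalize(cfg, counts, meta, newick, dist, tree, truth)


_DISPATCH = {
    "neutral": simulate_neutral,
    "selection": simulate_selection,
    "dispersal_limited": simulate_dispersal_limited,
    "planted_generalist": simulate_planted_generalist,
    "planted_specialist": simulate_planted_specialist,
    "mid_salinity_coupling": simulate_network_scenario,
}


def simulate(cfg: ScenarioConfig) -> SimulatedDataset:
    """Dispatch on cfg.scenario."""
    return _DISPATCH[cfg.scenario](cfg)


def config_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    d["salinity_range"] = list(cfg.salinity_range)
    return d
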