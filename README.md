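# amf-assembly

Community-assembly inference for arbuscular mycorrhizal (AM) fungal OTU
tables along an environmental (soil-salinity) gradient.

Soil microbial ecologists routinely ask whether a community is structured
by *deterministic* processes (environmental selection) or *stochastic* ones
(drift, dispersal), and how that balance changes along a stress gradient.
This package implements the standard null-model toolkit for answering that
question from an OTU abundance table, a rooted phylogeny of the OTUs, and
per-sample metadata (site and salinity in mS/cm):

- **Habitat generalists and specialists** — Levins niche breadth
  `B_j = 1 / Σ_i P_ij²` per OTU, classified against the 95% interval of a
  fixed-row-and-column-sum permutation null (1000 matrices).
- **Assembly-process partitioning** — per sample pair, the abundance-weighted
  β-mean-nearest-taxon distance (βMNTD), its z-score βNTI under a
  tip-label-shuffling null (999 draws), and the Raup–Crick–Bray metric
  RC_Bray under a probabilistic community-assembly null. Pairs are assigned
  to variable selection (βNTI > 2), homogeneous selection (βNTI < −2),
  dispersal limitation (RC_Bray > 0.95), homogenizing dispersal
  (RC_Bray < −0.95), or undominated processes; the last three count as
  stochastic.
- **Sloan neutral community model** — occurrence frequency vs mean relative
  abundance, fitted by bounded least squares of the stationary-Beta
  occupancy with a single migration parameter `m` (finite-read
  beta-binomial occupancy for count tables); reports `m`, `Nm`, `R²`, and
  per-OTU above/within/below partitions.
- **Co-occurrence network stability per salinity level** — Spearman networks
  over OTUs with mean relative abundance > 0.1% (|ρ| ≥ 0.6, BH-adjusted
  p < 0.05), with robustness (taxa retaining ≥ 1 edge after removing 50% of
  nodes, 100 repetitions), vulnerability (maximal relative drop in global
  efficiency on single-node deletion), cohesion (abundance-weighted
  null-corrected connectedness), and complexity = positive + |negative|
  cohesion.
- **Permutation tests** — Mantel (community vs environmental distance) and
  PERMANOVA (Anderson's pseudo-F) with explicit seeds.
- **Synthetic data with known ground truth** — generators for neutral,
  selection-driven, dispersal-limited, planted-generalist/specialist, and
  salinity-dependent network-coupling communities at the study's scale
  (54 samples, 11 sites, 428 OTUs, 12 genera, 0–11 mS/cm in five levels),
  so every stage is testable without sequence data.

## Worked example

Simulate a selection-structured community and contrast it with a neutral
one:

```python
from amf_assembly import (ScenarioConfig, simulate, fit_ncm,
                          pairwise_assembly, summarize_assembly)

ds = simulate(ScenarioConfig(seed=42, scenario="selection"))
print(fit_ncm(ds.table).summary())
pairs = pairwise_assembly(ds.table, ds.distances, n_null=999, seed=42)
print(summarize_assembly(pairs).fractions)
```

prints

```
Sloan neutral community model
=============================================
OTUs                                      428
community size N                     10000.00
migration rate m                     0.189152
N*m                                   1891.52
R-squared                             -1.0654
detection limit                     1.000e-04
above prediction                           67
within prediction                         183
below prediction                          178

{'variable_selection': 0.7386, 'homogeneous_selection': 0.0,
 'dispersal_limitation': 0.0776, 'homogenizing_dispersal': 0.0433,
 'undominated': 0.1405}
```

The negative `R²` says occurrence frequencies are far from the neutral
expectation, and 74% of sample pairs fall to variable selection — the
salinity filter that generated the data. The same pipeline on a neutral
simulation (`scenario="neutral"`, same seed) instead recovers the
generating migration rate and a clean neutral fit (`m = 0.1045`,
`R² = 0.932`) with 93% of pairs undominated (stochastic fraction 0.93).

The same stages are available from the shell:

```bash
amf-assembly simulate --scenario selection --seed 42 --out data/
amf-assembly assembly --table data/otu_table.tsv --tree data/tree.nwk \
    --nulls 999 --seed 42 --out pairs.tsv
amf-assembly run --config config.yaml   # full pipeline with manifest
```

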