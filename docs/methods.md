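# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and what the synthetic ground-truth generators do and
do not emulate.

## Niche breadth and the generalist/specialist test

For OTU *j* with per-sample proportions `P_ij = x_ij / Σ_i x_ij`, the Levins
breadth `B_j = 1 / Σ_i P_ij²` is the effective number of samples the OTU
occupies (1 = point niche, n = perfectly even). `B_j` is invariant to
rescaling OTU *j*'s abundance vector, so counts and relative abundances give
identical breadths.

The classification null conserves every sample total and every OTU total.
Null matrices are sampled *exactly* — rows drawn sequentially from the
multivariate hypergeometric distribution over the remaining column totals
(Patefield's r2dtable scheme) — rather than through a swap Markov chain.
This distribution is precisely the conditional law of an independence-model
count matrix given its margins, which gives the test its calibration: for a
community with no habitat structure the observed matrix is exchangeable with
the null draws and the non-neutral label rate sits at the nominal 5%
(2.5% per tail, 1000 matrices, percentile bounds, strict inequalities; ties
with a bound are labelled neutral). An alternative null
(`null_model="shuffle_rows"`, each sample's abundances permuted across
OTUs) is available for non-integer tables.

Consequence worth knowing: an OTU whose expected occupancy is even but
which carries ordinary sampling noise is *typical* under this null. Only
sub-sampling evenness (or genuine concentration) is flagged. The planted
generalist in the synthetic data is therefore deterministically even —
that is what "engineered generalist" means here.

## βMNTD, βNTI and RC_Bray

βMNTD between samples A and B is the abundance-weighted mean distance from
each OTU present in one sample to its nearest taxon in the other (shared
OTUs contribute zero). The vectorized form computes, per sample B, the
vector `dmin_B(i) = min_{j present in B} d(i, j)` and assembles all pairs
with one matrix product; it is tested to 1e-12 against a nested-loop
oracle.

βNTI is the z-score of observed βMNTD against a null in which tip
identities are permuted across the entire OTU pool of the table (the
"taxa-labels" scheme), abundances fixed, 999 draws by default, one shared
draw sequence for all pairs of a table. A pair whose null has zero standard
deviation (e.g. under a star phylogeny, or when the two presence sets
coincide so βMNTD is identically zero) is returned as NaN with a flag and
excluded from process counts. An exhaustive variant enumerates all
permutations for pools of ≤ 8 OTUs and is used as the oracle in tests.

RC_Bray follows the probabilistic-assembly form: per null draw each of the
two communities is rebuilt by (1) drawing its observed richness of OTUs
without replacement with probability proportional to occupancy frequency
across all samples, then (2) allocating its observed read total with
probability proportional to mean relative abundance; Bray–Curtis is
computed per draw and `RC = 2·[(#null < obs) + 0.5·(#null = obs)]/n_null − 1`,
bounded in [−1, 1]. For all-pairs work each sample is reassembled once per
draw and all pairwise Bray–Curtis values share that draw, which cuts the
cost from O(pairs·nulls) to O(samples·nulls) assemblies.

Process assignment uses strict thresholds: βNTI > 2 variable selection,
βNTI < −2 homogeneous selection, otherwise RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else undominated. Boundary values fall
to the stochastic/undominated side. The stochastic fraction is the sum of
the last three classes over valid pairs.

The phylogenetic Mantel correlogram bins patristic distances into
equal-frequency classes and correlates the class-membership indicator with
pairwise absolute niche differences (sign flipped so that within-class
niche similarity reads as positive autocorrelation), with permutation
p-values and Holm correction. The default niche value is the
abundance-weighted mean salinity of occupied samples.

## Sloan neutral model

The stationary distribution of a taxon's local relative abundance under
neutral drift with immigration is `Beta(N·m·p, N·m·(1−p))`, with `p` the
metacommunity mean relative abundance, `N` the community size (taken as the
mean per-sample read total) and `m` the migration rate — the single fitted
parameter, bounded in (1e-6, 1], estimated by least squares of predicted
vs observed occurrence frequency over OTUs; `R² = 1 − SSE/SST`.

For count tables the default occupancy form is the finite-read tail
`P(count ≥ k)` of the beta-binomial obtained by integrating the stationary
Beta over sampling of `N` reads, with detection count
`k = max(1, round(N·d))` and `d` the detection limit (default `1/N`, one
read). The continuous Beta tail `P(x > d)` — the form usually written for
this model — systematically under-estimates `m` on data that include read
sampling (≈ −30% at 10k reads) because taxa above the detection limit can
still draw zero reads; the beta-binomial form recovers the generating `m`
to within a few percent on simulation and is therefore the default where
read counts are available. Relative-abundance tables (no read information)
use the continuous form; `occupancy="beta"` forces it. Per-OTU 95% bounds
on the predicted frequency are Wilson intervals at n = number of samples;
OTUs are partitioned above/within/below.

## Co-occurrence networks and stability

Per salinity level, OTUs with mean relative abundance strictly above 0.1%
are correlated pairwise (Spearman, tie-corrected t-approximation);
p-values are Benjamini–Hochberg adjusted across all tested pairs of the
level, and edges require |ρ| ≥ 0.6 and adjusted p < 0.05 (both recorded on
the network object; the thresholds are conventions, configurable).
Zero-variance OTUs are skipped; isolated OTUs are not nodes.

- **Robustness**: remove ⌊f·n⌋ nodes (uniform random, default f = 0.5, 100
  repetitions; or by descending degree, deterministic) and report the mean
  ± sd proportion of original taxa that still have at least one edge.
  Under this definition denser graphs are mechanically more robust —
  a clique barely suffers, a matching of pairs loses half its survivors —
  which is what lets planted topology control the robustness gradient.
- **Vulnerability**: global efficiency E = mean inverse unweighted
  shortest-path length over unordered pairs (0 for disconnected pairs);
  per node `V_i = (E − E_i)/E` after deleting node i; the network value is
  `max_i V_i` (≤ 1; can be negative for no node being critical).
- **Cohesion**: pairwise Pearson correlations on relative abundances,
  corrected by subtracting the mean correlation over a taxa-shuffle null
  (each OTU independently permuted across samples, 200 shuffles; each
  OTU's permutation stream is seeded from its identifier, so the result is
  invariant to row/column order). Positive (negative) connectedness of an
  OTU is the mean of its positive (negative) corrected correlations;
  per-sample cohesion is the abundance-weighted sum; complexity =
  positive + |negative| cohesion. With few samples the sampling spread of
  correlations (~1/√n) leaves a noise floor in connectedness, so absolute
  cohesion values are comparable only at fixed n.

## Synthetic data: what it emulates and what it does not

All generators mirror the study design: 54 samples in 11 sites, 428 OTUs in
12 genera (4 families, 3 orders as contiguous clades), 10k reads per
sample, salinity 0–11 mS/cm binned as [0,1), [1,2), [2,4), [4,7), [7,11].
The phylogeny is a birth–death tree (birth 1, death 0) with a 1e-6 branch
length floor; the metacommunity is a log-series rank-abundance curve
(`p_k ∝ x^k/k`, x = 0.998) assigned to random tips.

- *neutral*: local Beta draws around the metacommunity then multinomial
  reads; `well_mixed=True` skips the drift stage (pure multinomial — the
  structureless reference for the niche-test calibration, since Sloan
  drift at any m < ∞ produces genuine occupancy aggregation that an
  occupancy null correctly flags).
- *selection*: salinity optima evolved by Brownian motion on the tree,
  linearly rescaled to span the gradient; expected abundance is the
  metacommunity weight times a Gaussian kernel of |salinity − optimum|
  with width 1.5 mS/cm — wide enough that communities overlap, narrow
  enough that cross-extreme pairs are phylogenetically disjoint.
- *dispersal_limited*: per-site endemic pools; only the rarest 5% of taxa
  are shared between sites (so between-site pairs overlap only in taxa
  carrying almost no abundance), and each sample holds a random 80% subset
  of its site pool (so same-site presence sets differ and the βNTI null is
  non-degenerate).
- *planted_generalist / planted_specialist*: an aggregated background
  (each OTU occupies a random subset of samples) plus one engineered OTU:
  exactly equal counts in every sample (generalist, ~1% relative
  abundance) or high abundance confined to one site (specialist).
- *mid_salinity_coupling*: a latent-factor log-normal copula whose
  structure depends on the salinity bin. The middle bin gets eight
  near-deterministic OTU pairs (loading 0.995 — a fragile, matching-like
  graph) plus a broad factor over 80 moderately abundant OTUs at loading
  0.7 (widespread correlations ≈ 0.5 that raise cohesion but stay below
  the edge threshold); the extreme bins get three tight cliques of five;
  shoulders interpolate. Coupled OTUs receive abundance floors (1.2% for
  strong structures, 0.4% for the broad set) so they pass the 0.1% filter,
  and the background uses a steeper rank-abundance curve (x = 0.99) to
  keep the number of BH-tested pairs moderate at ~11 samples per bin.
  This yields the hump-shaped complexity and U-shaped robustness gradient
  as a property of the generator; note it deliberately does *not* make the
  middle bin's edge count highest — under the "retains ≥ 1 edge"
  robustness definition a denser middle network could not also be the
  least robust.

Not emulated: sequencing error, chimeras, OTU-clustering artifacts,
variable read depth (available as an option nowhere — depth is uniform by
design to isolate method behavior), spatial autocorrelation beyond the
site structure, and real AM-fungal taxonomic composition. Passing tests
demonstrate correctness and calibration of the statistics on communities
with known generating mechanisms, not that any particular real dataset is
dominated by those mechanisms.

## Numerical choices and problem sizes

- Null replicate defaults: 999 (βNTI, RC_Bray, Mantel, PERMANOVA), 1000
  (niche), 200 (cohesion), 100 repetitions (robustness). All stages take
  explicit seeds; the pipeline derives per-stage seeds from one master
  seed via CRC-tagged SeedSequences, making reruns byte-identical.
- Ties: RC_Bray null values equal to the observed Bray–Curtis (within
  1e-12) count half; βNTI with null sd ≤ 1e-12 is NaN-flagged; niche
  breadths exactly on a CI bound are neutral.
- The acceptance script runs each scenario at full study scale (54 × 428,
  999 nulls) with 2–10 replicate seeds per quantity — sizes chosen so the
  whole script completes in a few minutes on one CPU while keeping
  Monte-Carlo error well inside the tolerances asserted in tests.
- Degenerate inputs raise informative errors rather than propagating NaNs:
  all-zero samples, singleton PERMANOVA groups, zero-variance Mantel
  triangles, edgeless graphs for vulnerability, sub-minimum sample counts.

## Known limitations

- The fixed-margin niche null is exact but O(samples · OTUs) per draw;
  very large tables may prefer fewer permutations.
- RC_Bray requires integer (or integerizable) counts; purely relative
  tables cannot be assembled probabilistically.
- Vulnerability recomputes global efficiency per node deletion (O(n·m)
  BFS per node), fine for the ≤ few-hundred-node networks this pipeline
  produces.
- PERMANOVA is the one-factor form; no nested or multi-factor designs.
- The Mantel correlogram uses equal-frequency distance classes; with very
  skewed patristic distributions the last class can span a long tail.
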