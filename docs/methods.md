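# Methods

This note documents the models implemented in `ecoassembly`, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Assembly null models

**Weighted βMNTD.** For samples *k*, *m* with within-sample relative
abundances *f* and patristic distance *d* on a rooted, branch-length
tree,

    βMNTD(k, m) = ½ [ Σᵢ fᵢᵏ · min_{j∈m} d(i, j) + Σⱼ fⱼᵐ · min_{i∈k} d(j, i) ],

where the minimum runs over taxa present (count > 0) in the other
sample. A taxon present in both samples contributes 0 (its nearest
neighbour is itself), so βMNTD measures the phylogenetic distance of the
*turnover* between communities. The implementation is validated against
an independently coded double loop to 1e-12 on random instances.

**βNTI.** Each null replicate applies one uniform random permutation of
tip labels to the whole tree (equivalently, a joint row/column
permutation of the distance matrix) and recomputes βMNTD for every pair;
abundances are untouched. βNTI = (obs − mean_null)/sd_null with the
sample standard deviation (ddof = 1). Default 999 replicates; the
validation suite uses 199, which is sufficient for a z-score. Pairs with
null sd ≤ 1e-12 (e.g. a star phylogeny, where permutation changes
nothing) are flagged degenerate and carry NaN — never ±∞ — and are
excluded from process fractions with a warning. One permutation per
replicate serves all pairs; with a fixed seed the full matrix is
bit-reproducible.

**Raup–Crick (Bray–Curtis).** Per pair, each of `reps` null replicates
rebuilds both communities preserving their observed richness and total
abundance: richness taxa are drawn without replacement with probability
proportional to occupancy (fraction of samples in which the taxon
occurs), each receives one individual, and the remaining individuals are
allocated multinomially with probability proportional to mean relative
abundance across samples (an unweighted variant allocates uniformly).
RC = 2·[(#null < obs) + ½·(#null = obs)]/reps − 1 ∈ [−1, 1], with
equality judged at 1e-10. Each pair consumes an independent RNG
substream spawned from the seed in (i, j) order, so results do not
depend on evaluation order.

**Five-process classification.** βNTI > +2 → heterogeneous selection;
βNTI < −2 → homogeneous selection; otherwise RC > +0.95 → dispersal
limitation, RC < −0.95 → homogenizing dispersal, else drift
(undominated). All five thresholds are strict inequalities; boundary
values fall through to drift. Summaries count only within-group pairs
(per season), and the five fractions sum to 1 over defined pairs.

## SparCC

Counts carry only relative information; closure induces spurious
negative covariance among proportions. SparCC estimates basis
correlations from log-ratio variances t_ij = Var[log(x_i/x_j)] =
ω_i + ω_j − 2ρ_ij√(ω_iω_j). Assuming sparse correlations, row sums of t
give the linear system (1·1ᵀ + (D−2)I)ω = t·1 for the basis variances ω,
and ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)), clipped to [−1, 1].

- *Exclusion iterations* (default 10, threshold 0.1): the strongest
  not-yet-excluded |ρ| above threshold violates sparsity; its t_ij is
  removed from the system (diagonal and off-diagonal M entries and the
  t row sums are decremented) and the system re-solved. A component may
  lose at most D−3 pairs, after which it is saturated and skipped —
  beyond that the system degenerates.
- *Estimation iterations* (default 20): per iteration, fractions are
  re-drawn from a Dirichlet posterior with a unit prior given the counts
  (gamma sampling), propagating count uncertainty and handling zeros
  without a fixed pseudocount; a deterministic +1 pseudocount variant is
  available. The reported matrix is the element-wise median, with unit
  diagonal restored. Basis variances are floored at 1e-10.
- *Bootstrap p-values* (default 100 permutations): each bootstrap
  permutes every taxon's counts across samples independently and re-runs
  the full estimator; two-sided p = (1 + #{|r_boot| ≥ |r_obs|})/(n_boot
  + 1), so p ∈ (0, 1].

At a read depth typical of rarefied 16S data (the generator default is
25,110 reads/sample), the estimator recovers an engineered basis
correlation of 0.8 to within ±0.06 over seeds (the acceptance band is
±0.15); shallow depths attenuate estimates for rare taxa because the
Dirichlet posterior shrinks their log-ratio variance contributions.

The closure artifact that motivates SparCC is only visible when
composition variance is concentrated: with 50 taxa of comparable
abundance the per-pair bias (~1/D) drowns in sampling noise, while with
a few consistently dominant, strongly fluctuating taxa (the usual shape
of real OTU tables) Pearson-on-proportions shows mean |r| ≈ 0.12–0.20
against SparCC's ≈ 0.05. The generator's `n_dominant` option produces
that regime for validation.

## Networks

Edges require |r| > r_min AND p < p_max (and q < q_max where an FDR
column exists), all strict; isolated nodes are dropped. Topology uses
standard unweighted definitions; path length and diameter are computed
on the largest connected component; betweenness is unnormalised raw
path counts (an absolute keystone cut-off such as "betweenness < 5,000"
is meaningless on normalised values); "clustering" is the mean local
clustering coefficient and the global transitivity (triangle-to-triple
ratio) is reported alongside, both per network and per per-sample
subnetwork. Degree distributions are fit by least squares of
log(frequency) on log(degree) over occupied positive-degree bins,
reporting R².

Louvain modules (networkx implementation, seeded) are renamed M1…Mk in
decreasing size; modularity Q is reported on the unweighted simple
graph. The Erdős–Rényi baseline draws `n_random` G(n, m) graphs — m
exact by construction — and reports distributions and z-scores for mean
local clustering, transitivity, path length and (optionally) Louvain
modularity. Note the two clustering flavours differ even under the null:
E[transitivity] equals the edge density 2m/(n(n−1)), while mean local
clustering sits below it because degree-<2 nodes count as zero.

Spearman association networks (taxa–environment, prokaryote–
microeukaryote) use midrank ties, skip constant vectors with a warning,
and control FDR by Benjamini–Hochberg over all tested pairs. Bipartite
incidence/count matrices require every pair to span the two node sets.

## Environmental statistics

Heterogeneity H(group) is the mean of the upper-triangle Euclidean
distances between the group's samples. Variables are z-scored across
*all* samples (not per group) so that mixed units contribute comparably
while between-group spread differences — the signal — survive;
zero-variance variables are dropped with a warning, and an exclusion
list accommodates variables collinear with temperature (e.g. dissolved
oxygen). Because H depends on the standardisation convention and the
variable set, absolute H values are comparable only within a study.

The Mantel test correlates upper triangles and permutes rows/columns of
the second matrix jointly; p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1),
one-sided, default 999 permutations. Distance–distance regression
(slope, intercept, R²) is descriptive only — distance pairs are
dependent — and significance statements are left to the Mantel
permutation.

## Synthetic metacommunities

The generator emulates a seasonal multi-site survey: a regional pool of
`n_taxa` on an ultrametric birth–death phylogeny (dendropy; pure birth
by default); a single dominant environmental axis ("temperature",
degC-like units) with per-season site means and spreads (defaults:
winter 6±2.4, spring 16±1.6, summer 27±0.8, autumn 24±1.4 — spread
peaks in winter); niche optima evolved along the tree by Brownian motion
(rate 12 per unit branch length, root 16) with an optional early-burst
decay `exp(−decay·t)` that concentrates trait divergence at deep splits,
i.e. strengthens niche conservatism; local communities of J individuals
(default 1,000) drawn multinomially with Gaussian filter weight
exp(−(optimum−E)²/2w²) (w = None disables filtering), then G Moran
generations of zero-sum drift (J uniform kill/replace steps per
generation, parent may equal victim). All randomness flows from one
seed through SeedSequence substreams.

Canonical regime presets (used for validation and by
`scripts/acceptance.py`):

- *heterogeneous selection*: w = 2, G = 0, sites spread ±8 around 16,
  J = 1,000, early-burst optima. Divergent environments select
  phylogenetically distinct communities → βNTI ≫ +2.
- *homogeneous selection*: w = 0.5, G = 0, all sites at the 0.9
  quantile of the realised optima, J = 30, early-burst optima. The
  upper trait tail is occupied by a single clade, so the niche is
  clade-pure; J below the eligible-clade size makes community
  membership turn over between replicate sites while staying inside the
  clade → βNTI ≪ −2. Both properties are necessary: convergent
  non-clade taxa or saturated membership each erase the negative
  signal.
- *drift*: w = None, G = 100, identical environments, J = 1,000. Long
  drift prunes occupancy, which widens the Raup–Crick null enough that
  observed turnover sits inside it (short drift produces turnover the
  null cannot reproduce and is read as dispersal limitation — the
  framework's documented behaviour, since drift without dispersal *is*
  dispersal-limited divergence).

What the generator does **not** emulate: immigration/speciation,
spatially explicit dispersal, multi-trait niches, read-depth variation
between samples, chimeras/contamination, or taxonomic annotation error.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated on communities with known assembly history; they
do not certify behaviour on real amplicon data, whose richness
(~31,000 OTUs in a typical survey) and noise structure are far beyond
these desk-scale simulations (15–52 samples, 150 taxa, 199 null
replicates — sizes chosen so the full validation chain runs in about a
minute).

## Numerical conventions

Strict inequalities at every published threshold; degenerate βNTI pairs
flagged, not zeroed; RC ties counted half at 1e-10 tolerance; SparCC
variances floored at 1e-10 and components saturated after D−3
exclusions; rarefaction via multivariate hypergeometric (without
replacement); prevalence filter keeps taxa with total count strictly
greater than the threshold (default 10), applied after rarefaction by
default (the order is configurable); seeds are required arguments on
every stochastic operation, and pipeline manifests record them all.
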