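# ecoassembly

Community-assembly inference and co-occurrence network analysis for
microbial OTU tables, with a synthetic metacommunity simulator that
provides ground truth for every stage.

Microbial ecologists routinely ask two linked questions about a set of
community profiles: *which ecological processes assembled these
communities* — deterministic environmental selection, dispersal, or
neutral drift — and *how are the taxa associated with one another*.
`ecoassembly` implements the standard quantitative chain for both, as a
tested Python library:

- **Assembly processes.** The abundance-weighted β-nearest-taxon distance
  (βMNTD) between samples *k* and *m*,

      βMNTD = ½ [ Σᵢ fᵢᵏ · min_{j∈m} d(i,j) + Σⱼ fⱼᵐ · min_{i∈k} d(j,i) ],

  is standardised against a tip-shuffling null to give βNTI. Pairs with
  βNTI > +2 are assigned to heterogeneous selection, βNTI < −2 to
  homogeneous selection; the remainder are split by the Raup–Crick metric
  on Bray–Curtis distances (RC, rescaled to [−1, 1]): RC > +0.95 →
  dispersal limitation, RC < −0.95 → homogenizing dispersal, |RC| < 0.95
  → drift. Per-group (e.g. per-season) process fractions summarise the
  result.
- **Co-occurrence networks.** SparCC correlations (log-ratio variance
  decomposition with iterative exclusion, implemented here from scratch)
  with permutation-bootstrap p-values; networks built with the strict
  retention rule |r| > 0.5 and p < 0.05; topology (degree, unnormalised
  betweenness, clustering, path length, diameter), power-law degree fit
  R², Louvain modules (M1…Mk), 1,000-graph Erdős–Rényi G(n, m)
  baselines, a keystone screen (degree > 100, betweenness < 5,000),
  per-sample subnetworks, and Spearman-based taxa–environment and
  cross-domain bipartite networks with BH-FDR control.
- **Environment.** Per-season environmental heterogeneity (mean pairwise
  Euclidean distance between sites on z-scored variables), Mantel tests
  and distance–distance regressions.
- **Synthetic metacommunities.** Birth–death phylogenies, (early-burst)
  Brownian niche-optimum evolution, Gaussian environmental filtering
  exp(−(optimum−E)²/2w²) and zero-sum Moran drift, so each downstream
  statistic can be validated against a known assembly regime.

## Worked example

`examples/02_assembly_processes.py` simulates one metacommunity per
canonical regime (15 sites, 150 taxa) and runs the full βNTI + RC chain
with 199 null replicates:

```
process fractions (columns = true generator regime):

                         heterogeneous_sel  homogeneous_sel  drift
process
dispersal_limitation                  0.04             0.00   0.00
drift                                 0.04             0.44   0.92
heterogeneous_selection               0.86             0.00   0.06
homogeneous_selection                 0.00             0.51   0.02
homogenizing_dispersal                0.07             0.05   0.00
```

Each column is a dataset whose true assembly regime is known; the
largest fraction sits on the diagonal. Strong filtering across divergent
sites is read as heterogeneous selection (86% of pairs), identical-site
filtering as homogeneous selection (51%), and unfiltered drift as drift
(92%) — the in-silico analogue of contrasting high-heterogeneity
(winter) and low-heterogeneity (summer) seasons.

The other examples cover the simulator itself (`01`), SparCC network
construction (`03` — recovers an engineered basis correlation of 0.8 as
r = 0.83 with p = 0.01 while the background median |r| stays at 0.045),
and environmental heterogeneity plus Mantel tests (`04`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
ecoassembly simulate --n-taxa 150 --n-sites 13 --seed 1 --outdir sim/
ecoassembly assembly --table sim/otu_table.tsv --tree sim/tree.nwk \
    --groups sim/env.csv --reps 999 --seed 2 --outdir assembly/
ecoassembly network  --table sim/otu_table.tsv --method sparcc \
    --boot 100 --seed 3 --outdir network/
ecoassembly envstats --env sim/env.csv --table sim/otu_table.tsv \
    --perm 999 --seed 4 --outdir envstats/
ecoassembly run --config run.yaml     # all stages, manifest-driven
```

Exit codes: 0 ok, 2 configuration error, 3 data error. `run` writes a
`manifest.json` with versions, seeds, parameters and input hashes;
rerunning the same config reproduces byte-identical tables.

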