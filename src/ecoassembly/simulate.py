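"""Synthetic metacommunities with known assembly regime.

The generator produces everything the inference chain consumes — an OTU
table, a phylogeny, an environment table — with ground truth attached:

* a birth-death phylogeny whose tips are the regional species pool;
* a single dominant environmental axis ("temperature"); per-taxon
  environmental optima evolve along the tree under Brownian motion, so
  the niche trait carries phylogenetic signal (the prerequisite for
  betaNTI to be informative);
* local communities of fixed size J assembled in two stages:
  environmental filtering — individuals drawn from a uniform regional
  pool with weight exp(-(optimum - E)^2 / (2 w^2)) for local environment
  E and niche width w (w = None disables filtering) — followed by G
  generations of zero-sum neutral drift (Moran birth-death steps, J
  steps per generation).

Small w with divergent site environments yields heterogeneous selection;
small w with identical environments yields homogeneous selection; no
filtering plus drift yields stochastic assembly.  ``REGIMES`` holds the
three canonical presets used for parameter-recovery checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import skbio

from .otu import OtuTable, EnvTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "REGIMES",
    "simulate_phylogeny",
    "evolve_optima",
    "generate_environments",
    "assemble_metacommunity",
    "simulate_dataset",
    "simulate_regime",
    "lognormal_compositions",
]

# Per-season mean and between-site spread of the temperature axis
# (degrees C).  Spread is highest in winter and lowest in summer,
# emulating a temperate bay whose environmental heterogeneity peaks in
# the cold season.
DEFAULT_SEASONS: dict[str, tuple[float, float]] = {
    "winter": (6.0, 2.4),
    "spring": (16.0, 1.6),
    "summer": (27.0, 0.8),
    "autumn": (24.0, 1.4),
}


@dataclass
class SimulationConfig:
    """Knobs of the metacommunity generator.

    ``niche_width`` (w, same units as the environmental axis) sets the
    strength of environmental filtering — smaller is stronger; ``None``
    disables filtering entirely.  ``drift_generations`` (G) counts Moran
    generations (J birth-death steps each) of neutral drift after the
    filtered draw, so G = 0 is pure filtering and large G is
    drift-dominated.  ``phylo_signal`` is the Brownian rate of optimum
    evolution per unit branch length.
    """

    n_taxa: int = 150
    n_sites: int = 13
    community_size: int = 1000
    niche_width: float | None = 2.0
    drift_generations: int = 0
    phylo_signal: float = 12.0
    phylo_signal_decay: float = 0.0
    root_optimum: float = 16.0
    seasons: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEASONS)
    )
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_aux_vars: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_sites < 1 or self.community_size < 1:
            raise ValueError("taxa, site and community-size counts must be positive")
        if self.niche_width is not None and self.niche_width <= 0:
            raise ValueError("niche width must be positive (or None for no filtering)")
        if self.drift_generations < 0:
            raise ValueError("drift generations must be >= 0")


@dataclass
class SyntheticDataset:
    """A simulated study: OTU table, tree, environment and ground truth."""

    otu_table: OtuTable
    tree: skbio.TreeNode
    env: EnvTable
    optima: pd.Series
    true_regime: pd.Series
    config: SimulationConfig


def simulate_phylogeny(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 20,
) -> skbio.TreeNode:
    """Ultrametric birth-death tree with exactly ``n_taxa`` extant tips,
    labelled T001..Tn."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not birth_rate > death_rate or death_rate < 0:
        raise ValueError("require birth_rate > death_rate >= 0")
    rng = random.Random(seed)
    last_error: Exception | None = None
    for _ in range(max_retries):
        try:
            dtree = dendropy.model.birthdeath.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_taxa,
                rng=rng,
            )
            break
        except Exception as exc:  # lineage died out before reaching n_taxa
            last_error = exc
    else:
        raise RuntimeError(f"birth-death simulation failed after {max_retries} tries: {last_error}")
    width = len(str(n_taxa))
    for k, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{k:0{width}d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = skbio.TreeNode.read([newick], convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def evolve_optima(
    tree: skbio.TreeNode,
    brownian_rate: float,
    root_value: float = 0.0,
    seed: int = 0,
    decay: float = 0.0,
) -> pd.Series:
    """Brownian-motion trait evolution along the tree.

    Each branch adds an independent zero-mean normal increment whose
    variance is the integral of the evolutionary rate over the branch, so
    a tip's optimum is root_value plus the sum over its root path, and
    sibling tips covary through their shared path length.

    With ``decay`` = 0 (default) the rate is constant (``brownian_rate``
    per unit branch length).  A positive ``decay`` gives an early-burst
    clock, rate(t) = brownian_rate * exp(-decay * t) with t the distance
    from the root: trait divergence is then dominated by the deep splits,
    i.e. niches are strongly phylogenetically conserved and clades occupy
    distinct regions of the environmental axis.
    """
    if brownian_rate < 0:
        raise ValueError("brownian rate must be >= 0")
    if decay < 0:
        raise ValueError("rate decay must be >= 0")
    rng = np.random.default_rng(seed)
    # value and root-distance per visited node
    state: dict[int, tuple[float, float]] = {id(tree): (root_value, 0.0)}
    out = {}
    for node in tree.preorder(include_self=False):
        parent_val, depth = state[id(node.parent)]
        length = node.length or 0.0
        if decay > 0:
            var = brownian_rate / decay * (
                np.exp(-decay * depth) - np.exp(-decay * (depth + length))
            )
        else:
            var = brownian_rate * length
        val = parent_val + rng.normal(0.0, np.sqrt(var))
        state[id(node)] = (val, depth + length)
        if node.is_tip():
            out[node.name] = val
    return pd.Series(out, name="optimum").sort_index()


def generate_environments(
    n_sites: int,
    seasons: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_aux_vars: int = 2,
    aux_noise: float = 0.5,
) -> EnvTable:
    """Site-by-season environment table.

    Per season, site temperatures are N(mean, spread).  ``n_aux_vars``
    auxiliary variables (nutrient-like covariates) are affine in the
    standardized temperature plus N(0, aux_noise) noise, giving the
    heterogeneity index a realistic multivariate input.  Sample ids are
    "<season>_s<site>".
    """
    seasons = dict(DEFAULT_SEASONS) if seasons is None else seasons
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    groups = []
    for season, (mean, spread) in seasons.items():
        temps = rng.normal(mean, spread, size=n_sites)
        for s, temp in enumerate(temps, start=1):
            aux = [
                -0.6 * (temp - mean) + rng.normal(0.0, aux_noise * spread)
                for _ in range(n_aux_vars)
            ]
            rows.append([temp] + aux)
            index.append(f"{season}_s{s:02d}")
            groups.append((season, f"s{s:02d}"))
    cols = ["temperature"] + [f"aux{k+1}" for k in range(n_aux_vars)]
    data = pd.DataFrame(rows, index=index, columns=cols)
    grouping = pd.DataFrame(groups, index=index, columns=["season", "site"])
    return EnvTable(data, grouping)


def _moran_drift(counts: np.ndarray, generations: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-sum neutral drift: each step kills one uniformly chosen
    individual and replaces it with the offspring of another (possibly the
    same) uniformly chosen individual; J steps = one generation."""
    if generations == 0:
        return counts
    individuals = np.repeat(np.arange(counts.size), counts)
    j = individuals.size
    n_steps = generations * j
    deaths = rng.integers(0, j, size=n_steps)
    births = rng.integers(0, j, size=n_steps)
    for d, b in zip(deaths, births):
        individuals[d] = individuals[b]
    return np.bincount(individuals, minlength=counts.size)


def assemble_metacommunity(
    cfg: SimulationConfig,
    tree: skbio.TreeNode,
    optima: pd.Series,
    env: EnvTable | None = None,
) -> SyntheticDataset:
    """Assemble one local community per site x season row of ``env``.

    Stage 1 (filtering): J individuals drawn multinomially from the
    regional pool with weight exp(-(optimum - E)^2 / (2 w^2)); stage 2
    (drift): G Moran generations.  Every community holds exactly J
    individuals at all times.  ``true_regime`` labels each sample
    "selection" when filtering is active (finite w) and "drift" otherwise.
    """
    taxa = sorted(t.name for t in tree.tips())
    if sorted(optima.index) != taxa:
        raise ValueError("optima index must match the tree's tip set")
    ss = np.random.SeedSequence(cfg.seed)
    env_ss, comm_ss = ss.spawn(2)
    if env is None:
        env = generate_environments(
            cfg.n_sites, cfg.seasons, seed=int(env_ss.generate_state(1)[0] % 2**31),
            n_aux_vars=cfg.n_aux_vars,
        )
    opt = optima.loc[taxa].to_numpy()
    rows = {}
    rng = np.random.default_rng(comm_ss)
    for sid in env.sample_ids:
        e_val = float(env.data.loc[sid, "temperature"])
        if cfg.niche_width is None:
            weights = np.ones_like(opt)
        else:
            weights = np.exp(-((opt - e_val) ** 2) / (2.0 * cfg.niche_width**2))
        total = weights.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(f"empty community at {sid}: no taxon within niche reach")
        community = rng.multinomial(cfg.community_size, weights / total)
        community = _moran_drift(community, cfg.drift_generations, rng)
        rows[sid] = community
    table = OtuTable(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))
    regime = "selection" if cfg.niche_width is not None else "drift"
    true_regime = pd.Series(regime, index=env.sample_ids, name="true_regime")
    return SyntheticDataset(table, tree, env, optima.loc[taxa], true_regime, cfg)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """End-to-end generation: tree, optima, environments, communities.

    All randomness flows from ``cfg.seed`` through per-stage substreams.
    """
    ss = np.random.SeedSequence(cfg.seed)
    tree_ss, opt_ss = ss.spawn(2)
    tree = simulate_phylogeny(
        cfg.n_taxa, cfg.birth_rate, cfg.death_rate,
        seed=int(tree_ss.generate_state(1)[0] % 2**31),
    )
    optima = evolve_optima(
        tree, cfg.phylo_signal, cfg.root_optimum,
        seed=int(opt_ss.generate_state(1)[0] % 2**31),
        decay=cfg.phylo_signal_decay,
    )
    return assemble_metacommunity(cfg, tree, optima)


def lognormal_compositions(
    n_taxa: int = 50,
    n_samples: int = 200,
    depth: int = 25110,
    correlated_pairs: dict[tuple[int, int], float] | None = None,
    sigma_range: tuple[float, float] = (0.5, 1.5),
    mu_range: tuple[float, float] = (0.0, 3.0),
    n_dominant: int = 0,
    dominant_mu: float = 6.0,
    dominant_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[OtuTable, np.ndarray]:
    """Compositional count data with a known log-normal basis.

    Absolute (basis) abundances are log-normal with per-taxon location
    and scale drawn from ``mu_range`` / ``sigma_range``; selected taxon
    pairs get a prescribed correlation on the log scale via
    ``correlated_pairs`` (all other pairs independent).  Counts are a
    multinomial read-out of the closed compositions at ``depth`` reads —
    the closure is what makes naive proportion correlations biased and
    compositionally-aware estimators necessary.

    ``n_dominant`` makes the last ``n_dominant`` taxa consistently
    abundant and strongly fluctuating (location ``dominant_mu``, scale
    ``dominant_sigma``), mimicking the few-dominant-taxa structure of
    real OTU tables; their fluctuations propagate through the closure to
    every other proportion, which is the classic spurious-correlation
    regime.

    Returns the OTU table and the basis log-abundance matrix
    (samples x taxa) for ground-truth checks.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(*mu_range, size=n_taxa)
    sigma = rng.uniform(*sigma_range, size=n_taxa)
    if n_dominant:
        if n_dominant >= n_taxa:
            raise ValueError("n_dominant must be smaller than n_taxa")
        mu[-n_dominant:] = dominant_mu
        sigma[-n_dominant:] = dominant_sigma
    z = rng.standard_normal((n_samples, n_taxa))
    if correlated_pairs:
        for (i, j), rho in correlated_pairs.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation for pair ({i},{j}) outside [-1, 1]")
            z[:, j] = rho * z[:, i] + np.sqrt(1.0 - rho**2) * z[:, j]
    logs = mu + sigma * z
    basis = np.exp(logs)
    fracs = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in fracs])
    width = len(str(n_taxa))
    taxa = [f"T{k:0{width}d}" for k in range(1, n_taxa + 1)]
    samples = [f"s{k:03d}" for k in range(1, n_samples + 1)]
    table = OtuTable(pd.DataFrame(counts, index=samples, columns=taxa))
    return table, logs


# Canonical single-season presets for the three contrasted assembly
# regimes, all under a strongly conserved (early-burst) niche trait:
#
# * heterogeneous_selection — strong filtering, sites spread widely along
#   the temperature axis, no drift: divergent deterministic assembly.
# * homogeneous_selection — strong narrow filtering, every site at the
#   same environment placed in the upper tail of the trait distribution
#   (so the selected niche is occupied by a single clade), small
#   communities so membership turns over between replicate sites.
# * drift — no filtering, long neutral drift, identical environments:
#   purely stochastic assembly.
REGIMES: dict[str, dict] = {
    "heterogeneous_selection": dict(
        niche_width=2.0, drift_generations=0, community_size=1000,
        env_spread=8.0, env_quantile=None,
    ),
    "homogeneous_selection": dict(
        niche_width=0.5, drift_generations=0, community_size=30,
        env_spread=0.0, env_quantile=0.9,
    ),
    "drift": dict(
        niche_width=None, drift_generations=100, community_size=1000,
        env_spread=0.0, env_quantile=None,
    ),
}


def simulate_regime(
    name: str,
    n_taxa: int = 150,
    n_samples: int = 15,
    seed: int = 0,
) -> SyntheticDataset:
    """One single-season dataset under a named canonical regime."""
    if name not in REGIMES:
        raise ValueError(f"unknown regime {name!r}; choose from {sorted(REGIMES)}")
    preset = REGIMES[name]
    ss = np.random.SeedSequence(seed)
    tree_ss, opt_ss = ss.spawn(2)
    tree = simulate_phylogeny(n_taxa, seed=int(tree_ss.generate_state(1)[0] % 2**31))
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        n_sites=n_samples,
        community_size=preset["community_size"],
        niche_width=preset["niche_width"],
        drift_generations=preset["drift_generations"],
        phylo_signal_decay=1.0,
        seed=seed,
    )
    optima = evolve_optima(
        tree, cfg.phylo_signal, cfg.root_optimum,
        seed=int(opt_ss.generate_state(1)[0] % 2**31),
        decay=cfg.phylo_signal_decay,
    )
    if preset["env_quantile"] is not None:
        env_mean = float(optima.quantile(preset["env_quantile"]))
    else:
        env_mean = cfg.root_optimum
    cfg.seasons = {"one": (env_mean, preset["env_spread"])}
    return assemble_metacommunity(cfg, tree, optima)
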