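"""Phylogenetic and taxonomic null models for community assembly.

Implements the standard two-step partitioning of pairwise community
turnover into five ecological processes:

1. betaNTI — the standardised effect size of abundance-weighted betaMNTD
   against a tip-label-shuffling null.  |betaNTI| > 2 indicates selection
   (positive: heterogeneous selection between divergent environments;
   negative: homogeneous selection under uniform conditions).
2. For |betaNTI| < 2, the Raup-Crick metric on Bray-Curtis distances
   (RC, rescaled to [-1, 1]) separates dispersal limitation (RC > +0.95),
   homogenizing dispersal (RC < -0.95) and drift/undominated processes
   (|RC| < 0.95).

betaMNTD between samples k and m is

    0.5 * [ sum_i f_ik * min_{j in m} d(i, j)
          + sum_j f_jm * min_{i in k} d(j, i) ]

with f the within-sample relative abundances and d the patristic
distance; the minimum runs over taxa present in the other sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .otu import OtuTable
from .trees import patristic_distances

__all__ = [
    "PROCESSES",
    "NullModelResult",
    "bray_curtis_matrix",
    "weighted_beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_pairs",
    "summarize_processes",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelResult:
    """betaNTI and RC matrices over the same samples.

    ``degenerate`` flags pairs whose null betaMNTD distribution had zero
    standard deviation (no phylogenetic structure to standardise against);
    their betaNTI is NaN, never +/-inf.
    """

    bnti: pd.DataFrame
    rc: pd.DataFrame
    degenerate: pd.DataFrame
    reps: int
    seed: int


def bray_curtis_matrix(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), in [0, 1]."""
    counts = table.counts.astype(float)
    if np.any(counts.sum(axis=1) == 0):
        bad = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    mat = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


def _beta_mntd_matrix(freq: np.ndarray, present: list[np.ndarray], dist: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given relative abundances, per-sample
    present-taxon index arrays and a taxa x taxa distance matrix."""
    n = freq.shape[0]
    out = np.zeros((n, n))
    for k in range(n):
        ik = present[k]
        fk = freq[k, ik]
        for m in range(k + 1, n):
            im = present[m]
            sub = dist[np.ix_(ik, im)]
            val = 0.5 * (fk @ sub.min(axis=1) + freq[m, im] @ sub.min(axis=0))
            out[k, m] = out[m, k] = val
    return out


def weighted_beta_mntd(table: OtuTable, tree) -> pd.DataFrame:
    """Abundance-weighted between-sample mean nearest-taxon distance."""
    freq = table.relative_abundance().to_numpy()
    dist = patristic_distances(tree, table.taxon_ids).to_numpy()
    present = [np.flatnonzero(row > 0) for row in table.counts]
    mat = _beta_mntd_matrix(freq, present, dist)
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


def beta_nti(
    table: OtuTable,
    tree,
    reps: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """betaNTI: (betaMNTD_obs - mean(null)) / sd(null).

    Each null replicate shuffles tip labels uniformly across the whole
    tree (equivalently, jointly permutes rows/columns of the patristic
    matrix) and recomputes betaMNTD for every pair; abundances are left
    untouched.  Returns (betaNTI matrix, degenerate-flag matrix); pairs
    with null sd == 0 carry NaN and are flagged, never +/-inf.
    """
    if reps < 2:
        raise ValueError("need at least 2 null replicates")
    freq = table.relative_abundance().to_numpy()
    dist = patristic_distances(tree, table.taxon_ids).to_numpy()
    present = [np.flatnonzero(row > 0) for row in table.counts]
    obs = _beta_mntd_matrix(freq, present, dist)

    rng = np.random.default_rng(seed)
    n_taxa = dist.shape[0]
    nulls = np.empty((reps,) + obs.shape)
    for r in range(reps):
        perm = rng.permutation(n_taxa)
        nulls[r] = _beta_mntd_matrix(freq, present, dist[np.ix_(perm, perm)])
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)

    degenerate = null_sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(degenerate, False)
    ids = table.sample_ids
    return (
        pd.DataFrame(z, index=ids, columns=ids),
        pd.DataFrame(degenerate, index=ids, columns=ids),
    )


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom else 0.0


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occupancy: np.ndarray,
    mean_abund: np.ndarray,
) -> np.ndarray:
    """One Raup-Crick null community: draw ``richness`` taxa without
    replacement with probability ~ occupancy, then allocate the remaining
    ``total - richness`` individuals among them ~ mean relative abundance."""
    n_taxa = occupancy.size
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occupancy / occupancy.sum())
    counts = np.zeros(n_taxa)
    counts[chosen] = 1.0
    remaining = total - richness
    if remaining > 0:
        w = mean_abund[chosen]
        wsum = w.sum()
        p = w / wsum if wsum > 0 else np.full(richness, 1.0 / richness)
        counts[chosen] += rng.multinomial(remaining, p)
    return counts


def raup_crick_bray(
    table: OtuTable,
    reps: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Raup-Crick turnover metric on Bray-Curtis distances, in [-1, 1].

    Per pair, each null replicate rebuilds both communities preserving
    observed richness and total abundance: taxa are drawn without
    replacement with probability proportional to occupancy (fraction of
    samples where the taxon occurs), then the remaining individuals are
    allocated proportionally to mean relative abundance across samples
    (``weighted=False`` allocates uniformly instead).  RC is the fraction
    of null Bray-Curtis values below the observed one (ties count half),
    rescaled as 2*RC - 1.  Nulls for each pair use an independent
    substream spawned from ``seed`` in (i, j) order, so full-matrix
    results are reproducible regardless of evaluation order.
    """
    if reps < 2:
        raise ValueError("need at least 2 null replicates")
    counts = table.counts.astype(float)
    richness = (counts > 0).sum(axis=1)
    if np.any(richness == 0):
        bad = [s for s, r in zip(table.sample_ids, richness) if r == 0]
        raise ValueError(f"zero-richness sample(s): {bad}")
    totals = counts.sum(axis=1)
    occupancy = (counts > 0).mean(axis=0)
    mean_abund = (counts / totals[:, None]).mean(axis=0)
    if not weighted:
        mean_abund = np.ones_like(mean_abund)

    n = counts.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    out = np.zeros((n, n))
    for (i, j), ss in zip(pairs, streams):
        rng = np.random.default_rng(ss)
        obs = _bray_curtis_pair(counts[i], counts[j])
        below = ties = 0
        for _ in range(reps):
            a = _null_community(rng, int(richness[i]), int(totals[i]), occupancy, mean_abund)
            b = _null_community(rng, int(richness[j]), int(totals[j]), occupancy, mean_abund)
            bc = _bray_curtis_pair(a, b)
            if abs(bc - obs) <= 1e-10:
                ties += 1
            elif bc < obs:
                below += 1
        rc = 2.0 * ((below + 0.5 * ties) / reps) - 1.0
        out[i, j] = out[j, i] = rc
    ids = table.sample_ids
    return pd.DataFrame(out, index=ids, columns=ids)


def classify_pairs(result: NullModelResult) -> pd.DataFrame:
    """Assign each unordered sample pair to one of the five processes.

    betaNTI > +2 -> heterogeneous selection; betaNTI < -2 -> homogeneous
    selection; otherwise RC > +0.95 -> dispersal limitation, RC < -0.95 ->
    homogenizing dispersal, else drift.  Degenerate pairs are labelled
    "undefined" with a warning and excluded from downstream fractions.
    """
    if not result.bnti.index.equals(result.rc.index):
        raise ValueError("betaNTI and RC matrices must share sample ids")
    ids = list(result.bnti.index)
    records = []
    n_undef = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = result.bnti.iloc[i, j]
            r = result.rc.iloc[i, j]
            if bool(result.degenerate.iloc[i, j]) or np.isnan(b):
                label = "undefined"
                n_undef += 1
            elif b > 2:
                label = "heterogeneous_selection"
            elif b < -2:
                label = "homogeneous_selection"
            elif r > 0.95:
                label = "dispersal_limitation"
            elif r < -0.95:
                label = "homogenizing_dispersal"
            else:
                label = "drift"
            records.append((ids[i], ids[j], b, r, label))
    if n_undef:
        warnings.warn(f"{n_undef} pair(s) had degenerate nulls; labelled 'undefined'")
    return pd.DataFrame(records, columns=["sample_a", "sample_b", "bnti", "rc", "process"])


def summarize_processes(labels: pd.DataFrame, grouping: pd.Series | None = None) -> pd.DataFrame:
    """Per-group fractions of pairs assigned to each process.

    ``grouping`` maps sample id -> group label (e.g. season); only pairs
    whose two samples share a group are counted, matching per-season
    summaries.  With ``grouping=None`` all pairs form one group "all".
    Undefined pairs are excluded; fractions sum to 1 per group.
    """
    df = labels[labels["process"] != "undefined"].copy()
    if grouping is None:
        df["group"] = "all"
    else:
        ga = df["sample_a"].map(grouping)
        gb = df["sample_b"].map(grouping)
        df = df[ga.values == gb.values].copy()
        df["group"] = ga[ga.values == gb.values].values
    if grouping is not None:
        sizes = pd.Series(grouping).value_counts()
        small = sizes.index[sizes < 2].tolist()
        if small:
            raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    rows = []
    for group, sub in df.groupby("group"):
        n = len(sub)
        fracs = {p: float((sub["process"] == p).mean()) for p in PROCESSES}
        rows.append({"group": group, "n_pairs": n, **fracs})
    if not rows:  # every pair undefined (or no within-group pair)
        rows = [{"group": "all", "n_pairs": 0, **{p: np.nan for p in PROCESSES}}]
    return pd.DataFrame(rows).set_index("group")
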