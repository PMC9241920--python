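"""Co-occurrence networks: construction, topology, modules, keystones.

Edges are retained on strict thresholds (|r| > r_min AND p < p_max, both
strict) from a long correlation table; graphs are simple and undirected
with the correlation kept as edge weight and its sign recorded.
Betweenness centrality is reported unnormalised (raw shortest-path
counts) so that absolute keystone cut-offs (degree > 100, betweenness
< 5,000) are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu import OtuTable, EnvTable

__all__ = [
    "NetworkStats",
    "ModulePartition",
    "ErEnsemble",
    "correlation_table",
    "build_network",
    "write_graph",
    "read_graph",
    "topology_stats",
    "fit_powerlaw_r2",
    "louvain_partition",
    "er_random_ensemble",
    "identify_keystones",
    "sample_subnetworks",
    "spearman_network",
    "bipartite_incidence",
]


# ---------------------------------------------------------------------------
# construction & I/O

def correlation_table(
    corr: pd.DataFrame, pvals: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten square correlation / p-value matrices into a long table of
    unordered pairs (id_a, id_b, estimate[, p_value])."""
    ids = list(corr.index)
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rec = [ids[i], ids[j], float(corr.iloc[i, j])]
            if pvals is not None:
                rec.append(float(pvals.iloc[i, j]))
            records.append(rec)
    cols = ["id_a", "id_b", "estimate"] + (["p_value"] if pvals is not None else [])
    return pd.DataFrame(records, columns=cols)


def build_network(
    corr: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.05,
    q_max: float | None = None,
    taxonomy: pd.Series | None = None,
) -> nx.Graph:
    """Build the co-occurrence graph from a long correlation table.

    An edge is kept iff |estimate| > r_min (strict) and, when the table
    carries them, p_value < p_max and q_value < q_max (strict).  Nodes
    without a retained edge never enter the graph.
    """
    g = nx.Graph()
    for row in corr.itertuples(index=False):
        r = row.estimate
        if not abs(r) > r_min:
            continue
        if hasattr(row, "p_value") and not row.p_value < p_max:
            continue
        if q_max is not None and hasattr(row, "q_value") and not row.q_value < q_max:
            continue
        attrs = {"weight": float(r), "sign": "+" if r > 0 else "-"}
        if hasattr(row, "p_value"):
            attrs["p"] = float(row.p_value)
        if hasattr(row, "q_value"):
            attrs["q"] = float(row.q_value)
        g.add_edge(row.id_a, row.id_b, **attrs)
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.index and pd.notna(taxonomy[node]):
                g.nodes[node]["taxonomy"] = str(taxonomy[node])
    return g


def write_graph(net: nx.Graph, path: str | Path, dialect: str | None = None) -> None:
    """Write GML (default) or GraphML, chosen by ``dialect`` or extension."""
    if dialect is None:
        dialect = "graphml" if str(path).endswith(".graphml") else "gml"
    if dialect == "gml":
        nx.write_gml(net, str(path))
    elif dialect == "graphml":
        nx.write_graphml(net, str(path))
    else:
        raise ValueError(f"unknown graph dialect {dialect!r}")


def read_graph(path: str | Path, dialect: str | None = None) -> nx.Graph:
    if dialect is None:
        dialect = "graphml" if str(path).endswith(".graphml") else "gml"
    if dialect == "gml":
        return nx.read_gml(str(path))
    if dialect == "graphml":
        return nx.read_graphml(str(path))
    raise ValueError(f"unknown graph dialect {dialect!r}")


# ---------------------------------------------------------------------------
# topology

@dataclass
class NetworkStats:
    """Network-level topological features plus per-node centralities.

    ``average_path_length`` and ``diameter`` are computed on the largest
    connected component; ``clustering_coefficient`` is the mean local
    clustering; ``transitivity`` is the global triangle ratio; per-node
    betweenness is unnormalised.
    """

    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float
    transitivity: float
    average_path_length: float
    diameter: float
    positive_edge_fraction: float
    node_stats: pd.DataFrame = field(repr=False)


def topology_stats(net: nx.Graph) -> NetworkStats:
    n, m = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        empty = pd.DataFrame(columns=["degree", "betweenness", "clustering"])
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan, empty)
    degree = dict(net.degree())
    betweenness = nx.betweenness_centrality(net, normalized=False)
    clustering = nx.clustering(net)
    node_stats = pd.DataFrame(
        {"degree": degree, "betweenness": betweenness, "clustering": clustering}
    )
    if m:
        signs = [d.get("sign", "+") for _, _, d in net.edges(data=True)]
        pos_frac = signs.count("+") / m
    else:
        pos_frac = np.nan
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    giant = net.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        apl, diam = np.nan, np.nan
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        average_degree=2.0 * m / n,
        clustering_coefficient=float(np.mean(list(clustering.values()))),
        transitivity=float(nx.transitivity(net)),
        average_path_length=apl,
        diameter=diam,
        positive_edge_fraction=pos_frac,
        node_stats=node_stats,
    )


def fit_powerlaw_r2(net: nx.Graph) -> float:
    """R^2 of a least-squares line through log(frequency) vs log(degree)
    over the occupied positive-degree bins (the scale-free-ness check)."""
    degrees = np.array([d for _, d in net.degree() if d > 0])
    values, freqs = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValueError("need at least 3 distinct positive degree values")
    fit = stats.linregress(np.log(values), np.log(freqs))
    return float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# modules & random ensembles

@dataclass
class ModulePartition:
    """Louvain modules named M1..Mk in decreasing size, with modularity Q."""

    membership: pd.Series
    sizes: pd.Series
    modularity: float

    def nodes_in(self, module: str) -> list:
        return list(self.membership.index[self.membership == module])


def louvain_partition(net: nx.Graph, resolution: float = 1.0, seed: int = 0) -> ModulePartition:
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    communities = nx.community.louvain_communities(
        net, weight=None, resolution=resolution, seed=seed
    )
    q = nx.community.modularity(net, communities, weight=None, resolution=resolution)
    ordered = sorted(communities, key=lambda c: (-len(c), sorted(map(str, c))))
    membership = {}
    sizes = {}
    for k, comm in enumerate(ordered, start=1):
        name = f"M{k}"
        sizes[name] = len(comm)
        for node in comm:
            membership[node] = name
    return ModulePartition(
        membership=pd.Series(membership, name="module"),
        sizes=pd.Series(sizes, name="size"),
        modularity=float(q),
    )


@dataclass
class ErEnsemble:
    """Statistics of an Erdős–Rényi G(n, m) ensemble and z-scores of the
    observed network against it.

    ``clustering`` is the mean local clustering coefficient (nodes of
    degree < 2 count as 0, so its ER mean sits slightly below the edge
    density); ``transitivity`` is the global triangle-to-triple ratio,
    whose ER expectation is the edge density 2m/(n(n-1)).
    """

    clustering: np.ndarray
    transitivity: np.ndarray
    average_path_length: np.ndarray
    modularity: np.ndarray
    z_scores: dict[str, float]


def er_random_ensemble(
    net: nx.Graph,
    n_random: int = 1000,
    seed: int = 0,
    with_modularity: bool = True,
) -> ErEnsemble:
    """Compare a network against ``n_random`` G(n, m) graphs with the same
    number of nodes and edges (uniform over graphs with exactly m edges)."""
    n, m = net.number_of_nodes(), net.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("more edges than a simple graph allows")
    obs = topology_stats(net)
    clus = np.empty(n_random)
    trans = np.empty(n_random)
    apl = np.empty(n_random)
    mod = np.full(n_random, np.nan)
    rng = np.random.default_rng(seed)
    for k in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        clus[k] = nx.average_clustering(g)
        trans[k] = nx.transitivity(g)
        components = max(nx.connected_components(g), key=len)
        giant = g.subgraph(components)
        apl[k] = (
            nx.average_shortest_path_length(giant)
            if giant.number_of_nodes() > 1
            else np.nan
        )
        if with_modularity:
            comms = nx.community.louvain_communities(
                g, weight=None, seed=int(rng.integers(2**31))
            )
            mod[k] = nx.community.modularity(g, comms, weight=None)
    z_scores = {}
    obs_mod = louvain_partition(net, seed=seed).modularity if (with_modularity and m) else np.nan
    metrics = [
        ("clustering", obs.clustering_coefficient, clus),
        ("transitivity", obs.transitivity, trans),
        ("average_path_length", obs.average_path_length, apl),
    ]
    if with_modularity:
        metrics.append(("modularity", obs_mod, mod))
    for name, obs_val, sample in metrics:
        sd = np.nanstd(sample, ddof=1)
        z_scores[name] = float((obs_val - np.nanmean(sample)) / sd) if sd > 0 else np.nan
    return ErEnsemble(clus, trans, apl, mod, z_scores)


def identify_keystones(
    net: nx.Graph,
    degree_min: float = 100.0,
    betweenness_max: float = 5000.0,
) -> list:
    """Keystone nodes: degree strictly above ``degree_min`` and
    unnormalised betweenness strictly below ``betweenness_max``."""
    stats_ = topology_stats(net).node_stats
    mask = (stats_["degree"] > degree_min) & (stats_["betweenness"] < betweenness_max)
    return list(stats_.index[mask])


def sample_subnetworks(net: nx.Graph, table: OtuTable) -> pd.DataFrame:
    """Per-sample induced subgraphs of the metacommunity network.

    Each sample's subnetwork keeps the network nodes with a nonzero count
    in that sample.  Returns one row per sample with node/edge counts and
    mean degree, mean (unnormalised) betweenness, mean local clustering
    and global transitivity — the quantities regressed on temperature.
    """
    missing = [node for node in net.nodes if node not in table.data.columns]
    if missing:
        raise KeyError(f"network node(s) absent from table: {missing[:5]}")
    rows = []
    for sid in table.sample_ids:
        present = set(table.data.columns[table.data.loc[sid] > 0])
        sub = net.subgraph([v for v in net.nodes if v in present])
        if sub.number_of_nodes():
            st = topology_stats(sub)
            rows.append(
                {
                    "sample": sid,
                    "n_nodes": st.n_nodes,
                    "n_edges": st.n_edges,
                    "mean_degree": st.node_stats["degree"].mean(),
                    "mean_betweenness": st.node_stats["betweenness"].mean(),
                    "mean_clustering": st.node_stats["clustering"].mean(),
                    "transitivity": st.transitivity,
                }
            )
        else:
            rows.append(
                {
                    "sample": sid,
                    "n_nodes": 0,
                    "n_edges": 0,
                    "mean_degree": np.nan,
                    "mean_betweenness": np.nan,
                    "mean_clustering": np.nan,
                    "transitivity": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# rank-correlation networks

def spearman_network(
    table_a: OtuTable,
    other: OtuTable | EnvTable | pd.DataFrame,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    fdr_method: str = "fdr_bh",
) -> tuple[pd.DataFrame, nx.Graph]:
    """Spearman cross-correlation network between two tables on shared samples.

    Computes midrank-tie Spearman rho between every column of ``table_a``
    and every column of ``other`` (a second OTU table, an environment
    table, or a bare DataFrame), Benjamini-Hochberg-adjusts the p-values
    over all tested pairs, and keeps edges with |rho| > rho_min and
    q < q_max (both strict).  Constant columns are skipped with a warning.
    """
    a = table_a.data
    if isinstance(other, OtuTable):
        b = other.data
    elif isinstance(other, EnvTable):
        b = other.data
    else:
        b = other
    if not a.index.equals(b.index):
        raise ValueError("tables must share identically ordered samples")
    overlap = set(a.columns) & set(b.columns)
    if overlap:
        raise ValueError(f"column sets must be disjoint; shared: {sorted(overlap)[:5]}")
    records = []
    skipped = []
    for ca in a.columns:
        x = a[ca].to_numpy(float)
        if np.all(x == x[0]):
            skipped.append(ca)
            continue
        for cb in b.columns:
            y = b[cb].to_numpy(float)
            if np.all(y == y[0]):
                skipped.append(cb)
                continue
            rho, p = stats.spearmanr(x, y)
            records.append((ca, cb, float(rho), float(p)))
    if skipped:
        warnings.warn(f"skipped constant column(s): {sorted(set(skipped))[:5]}")
    corr = pd.DataFrame(records, columns=["id_a", "id_b", "estimate", "p_value"])
    if len(corr):
        corr["q_value"] = multipletests(corr["p_value"], method=fdr_method)[1]
    else:
        corr["q_value"] = pd.Series(dtype=float)
    net = build_network(corr, r_min=rho_min, p_max=np.inf, q_max=q_max)
    return corr, net


def bipartite_incidence(
    corr: pd.DataFrame,
    set_a: list[str],
    set_b: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary incidence and edge-count matrices of a bipartite association
    table (rows = ``set_b``, e.g. microeukaryote groups; columns =
    ``set_a``, e.g. prokaryote groups).

    Every pair in ``corr`` must span the two sets; a within-set pair is an
    error.  The incidence cell is 1 iff at least one retained association
    links the pair of groups; the count matrix tallies associations.
    """
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ValueError("node sets must be disjoint")
    counts = pd.DataFrame(0, index=list(set_b), columns=list(set_a), dtype=int)
    for row in corr.itertuples(index=False):
        if row.id_a in sa and row.id_b in sb:
            ai, bi = row.id_a, row.id_b
        elif row.id_a in sb and row.id_b in sa:
            ai, bi = row.id_b, row.id_a
        else:
            raise ValueError(f"pair ({row.id_a}, {row.id_b}) does not span the two sets")
        counts.loc[bi, ai] += 1
    incidence = (counts > 0).astype(int)
    return incidence, counts
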