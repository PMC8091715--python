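"""Co-occurrence networks: construction, topology, keystones, robustness.

Networks are built from Spearman rank correlations between OTU abundance
profiles: an edge connects two OTUs when |ρ| exceeds a threshold (default
0.6) and the BH/FDR-corrected p-value is below a cutoff (default 0.01).
The correlation sign is kept as edge metadata, but all topology metrics
treat the graph as simple, undirected and unweighted.

On top of the graph the module provides: Table-style global topology
(degree, clustering, path length, diameter, density, modularity, power-law
fit), node centralities, Louvain modules with Zi–Pi role classification
(network hubs / module hubs / connectors = keystone taxa), matched
Erdős–Rényi G(n,m) baselines, and natural-connectivity robustness curves
under node removal.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as _ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io import OtuTable

logger = logging.getLogger(__name__)

ROLES = ("network_hub", "module_hub", "connector", "peripheral")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def filter_for_network(
    table: OtuTable, min_occupancy: float = 0.5, top_n: int = 300
) -> OtuTable:
    """Keep OTUs present in ≥ ``min_occupancy`` of samples, then the
    ``top_n`` most abundant (ties at the cutoff broken by OTU id)."""
    occ = (table.matrix > 0).mean(axis=0)
    survivors = table.counts.loc[:, occ >= min_occupancy]
    if survivors.shape[1] > top_n:
        totals = survivors.sum(axis=0)
        order = sorted(survivors.columns, key=lambda o: (-totals[o], o))
        survivors = survivors[order[:top_n]]
        survivors = survivors[[c for c in table.counts.columns if c in survivors.columns]]
    if survivors.shape[1] < 4:
        raise ValueError(
            f"only {survivors.shape[1]} OTUs survive filtering; no meaningful network"
        )
    return OtuTable(survivors)


def build_network(table: OtuTable, rho_min: float = 0.6, q_max: float = 0.01) -> nx.Graph:
    """Spearman/FDR co-occurrence graph.

    Midrank-tie Spearman ρ over all OTU pairs, two-sided p-values, BH
    correction over the full upper triangle; an edge is kept iff
    |ρ| > ``rho_min`` and q < ``q_max``.  Constant OTU profiles have no
    defined correlation and are dropped (logged).  Node attributes carry
    total abundance; edge attributes carry ``rho``, ``q`` and ``sign``.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    mat = table.counts
    const = mat.nunique(axis=0) <= 1
    if const.any():
        logger.info(
            "build_network: dropping %d constant OTUs (undefined correlation)",
            int(const.sum()),
        )
        mat = mat.loc[:, ~const]
    otus = list(mat.columns)
    n = len(otus)
    rho, pval = stats.spearmanr(mat.to_numpy())
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(n, k=1)
    qvals = multipletests(pval[iu], method="fdr_bh")[1]

    g = nx.Graph()
    totals = mat.sum(axis=0)
    for o in otus:
        g.add_node(o, abundance=int(totals[o]))
    keep = (np.abs(rho[iu]) > rho_min) & (qvals < q_max)
    for (i, j), r, q in zip(
        zip(iu[0][keep], iu[1][keep]), rho[iu][keep], qvals[keep]
    ):
        g.add_edge(
            otus[i], otus[j], rho=float(r), q=float(q), sign="+" if r > 0 else "-"
        )
    return g


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class GraphTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    diameter: int
    density: float
    average_path_length: float
    modularity: float
    n_modules: int
    powerlaw_r2: float
    powerlaw_exponent: float
    positive_edge_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _path_stats(g: nx.Graph):
    """(average path length, diameter) over connected node pairs."""
    total = 0.0
    n_pairs = 0
    diam = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target == source:
                continue
            total += dist
            n_pairs += 1
            diam = max(diam, dist)
    if n_pairs == 0:
        return 0.0, 0
    return total / n_pairs, diam


def powerlaw_fit(degrees) -> tuple[float, float]:
    """(OLS R² on the log-log degree histogram, ML exponent).

    The histogram regression uses degrees ≥ 1 and drops zero-count bins;
    the exponent is the continuous maximum-likelihood estimate with
    ``k_min = 1``.
    """
    k = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if len(k) == 0:
        return float("nan"), float("nan")
    values, counts = np.unique(k, return_counts=True)
    if len(values) < 3:
        return float("nan"), float("nan")
    x = np.log10(values)
    y = np.log10(counts)
    slope, intercept, r, *_ = stats.linregress(x, y)
    alpha = 1.0 + len(k) / np.sum(np.log(k / 0.5))
    return float(r**2), float(alpha)


def detect_modules(
    g: nx.Graph, seed=None, resolution: float = 1.0, n_restarts: int = 10
):
    """Louvain modules, best of ``n_restarts`` seeded runs by modularity Q.

    Returns ``(module_of_node: dict, Q: float)``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(g.nodes))}, 0.0
    rng = np.random.default_rng(seed)
    best_q, best_comms = -np.inf, None
    for _ in range(n_restarts):
        s = int(rng.integers(2**31 - 1))
        comms = nx.community.louvain_communities(g, resolution=resolution, seed=s)
        q = nx.community.modularity(g, comms, resolution=resolution)
        if q > best_q:
            best_q, best_comms = q, comms
    ordered = sorted(best_comms, key=lambda c: (-len(c), sorted(c)[0]))
    modules = {n: i for i, c in enumerate(ordered) for n in c}
    return modules, float(best_q)


def graph_topology(g: nx.Graph, seed=None) -> GraphTopology:
    """All Table-style global metrics for a co-occurrence graph."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    avg_deg = 2 * e / n
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(g)
    apl, diam = _path_stats(g)
    modules, q = detect_modules(g, seed=seed)
    r2, alpha = powerlaw_fit([d for _, d in g.degree()])
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    pos_frac = signs.count("+") / len(signs) if signs else float("nan")
    return GraphTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_deg,
        average_clustering=clustering,
        diameter=diam,
        density=density,
        average_path_length=apl,
        modularity=q,
        n_modules=len(set(modules.values())),
        powerlaw_r2=r2,
        powerlaw_exponent=alpha,
        positive_edge_fraction=pos_frac,
    )


def node_topology(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centralities per node.

    Betweenness is normalized by (N−1)(N−2)/2; closeness is computed per
    connected component as (reachable − 1)/Σ distances; eigenvector
    centrality is the principal adjacency eigenvector scaled so its
    maximum entry is 1.
    """
    nodes = list(g.nodes)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=False)
    if g.number_of_edges() > 0:
        A = nx.to_numpy_array(g, nodelist=nodes)
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, np.argmax(vals)])
        v = v / v.max() if v.max() > 0 else v
    else:
        v = np.zeros(len(nodes))
    eig = dict(zip(nodes, v))
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "eigenvector": [eig[n] for n in nodes],
        },
        index=pd.Index(nodes, name="otu_id"),
    )


# ---------------------------------------------------------------------------
# Zi-Pi keystones
# ---------------------------------------------------------------------------

def zipi_classify(
    g: nx.Graph, modules: dict, zi_cut: float = 2.5, pi_cut: float = 0.62
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Roles by threshold: Zi > ``zi_cut`` & Pi > ``pi_cut`` → network hub;
    Zi > ``zi_cut`` only → module hub; Pi > ``pi_cut`` only → connector;
    otherwise peripheral.  Hubs and connectors are flagged as keystone
    taxa.  A module whose within-degrees have zero spread gets Zi = 0 for
    its members (logged).
    """
    nodes = list(g.nodes)
    mod_of = {n: modules[n] for n in nodes}
    within = {}
    among = {}
    for n in nodes:
        counts = {}
        for nb in g.neighbors(n):
            counts[mod_of[nb]] = counts.get(mod_of[nb], 0) + 1
        within[n] = counts.get(mod_of[n], 0)
        among[n] = counts
    zi = {}
    n_degenerate = 0
    for mod in set(mod_of.values()):
        members = [n for n in nodes if mod_of[n] == mod]
        w = np.array([within[n] for n in members], dtype=float)
        sd = w.std(ddof=0)
        if sd == 0:
            n_degenerate += 1
            for n in members:
                zi[n] = 0.0
        else:
            mu = w.mean()
            for n, wn in zip(members, w):
                zi[n] = (wn - mu) / sd
    if n_degenerate:
        logger.info(
            "zipi: %d modules with zero within-degree spread; Zi set to 0 for their members",
            n_degenerate,
        )
    pi = {}
    for n in nodes:
        k = g.degree(n)
        if k == 0:
            pi[n] = 0.0
        else:
            pi[n] = 1.0 - sum((c / k) ** 2 for c in among[n].values())
    role = {}
    for n in nodes:
        if zi[n] > zi_cut and pi[n] > pi_cut:
            role[n] = "network_hub"
        elif zi[n] > zi_cut:
            role[n] = "module_hub"
        elif pi[n] > pi_cut:
            role[n] = "connector"
        else:
            role[n] = "peripheral"
    df = pd.DataFrame(
        {
            "module": [mod_of[n] for n in nodes],
            "Zi": [zi[n] for n in nodes],
            "Pi": [pi[n] for n in nodes],
            "role": [role[n] for n in nodes],
        },
        index=pd.Index(nodes, name="otu_id"),
    )
    df["keystone"] = df["role"] != "peripheral"
    return df


# ---------------------------------------------------------------------------
# Random baselines
# ---------------------------------------------------------------------------

@dataclass
class RandomEnsembleSummary:
    n_nodes: int
    n_edges: int
    reps: int
    clustering_mean: float
    clustering_sd: float
    path_length_mean: float
    path_length_sd: float
    modularity_mean: float
    modularity_sd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _gnm_edges(n: int, m: int, rng) -> list:
    """Uniform sample of m distinct undirected edges on n labelled nodes."""
    total = n * (n - 1) // 2
    idx = rng.choice(total, size=m, replace=False)
    i = np.floor((1 + np.sqrt(1 + 8 * idx)) / 2).astype(np.int64)
    j = idx - i * (i - 1) // 2
    return list(zip(i.tolist(), j.tolist()))


def random_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed=None,
    metrics: tuple = ("clustering", "path_length", "modularity"),
) -> RandomEnsembleSummary:
    """Erdős–Rényi G(n, m) baseline ensemble.

    Each replicate is a uniform random graph with exactly the reference
    network's node and edge counts; mean local clustering (degree < 2
    contributes 0), average shortest path length over connected pairs, and
    Louvain modularity are summarised as mean ± SD over the ensemble.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("more edges than the complete graph allows")
    rng = np.random.default_rng(seed)
    cl, pl, mod = [], [], []
    for r in range(reps):
        g = _ig.Graph(n_nodes, _gnm_edges(n_nodes, n_edges, rng))
        if "clustering" in metrics:
            cl.append(float(np.mean(g.transitivity_local_undirected(mode="zero"))))
        if "path_length" in metrics:
            pl.append(float(g.average_path_length(unconn=True)))
        if "modularity" in metrics:
            _ig.set_random_number_generator(_random.Random(int(rng.integers(2**31 - 1))))
            part = g.community_multilevel()
            mod.append(float(g.modularity(part)))
    _ig.set_random_number_generator(_random)

    def _ms(v):
        return (float(np.mean(v)), float(np.std(v, ddof=1))) if v else (float("nan"),) * 2

    cm, cs = _ms(cl)
    pm, ps = _ms(pl)
    mm, msd = _ms(mod)
    return RandomEnsembleSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        reps=reps,
        clustering_mean=cm,
        clustering_sd=cs,
        path_length_mean=pm,
        path_length_sd=ps,
        modularity_mean=mm,
        modularity_sd=msd,
    )


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

def natural_connectivity(g: nx.Graph) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    ``nc = ln((1/N) Σ exp(λ_i))`` on the unweighted, unsigned adjacency
    matrix, evaluated via log-sum-exp for stability.  An edgeless graph has
    all eigenvalues 0 and nc = 0.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty node set")
    if g.number_of_edges() == 0:
        return 0.0
    lam = np.linalg.eigvalsh(nx.to_numpy_array(g))
    return float(logsumexp(lam) - np.log(n))


@dataclass
class RobustnessCurve:
    strategy: str
    removal_fraction: np.ndarray
    nc_mean: np.ndarray
    nc_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "removal_fraction": self.removal_fraction,
                "nc_mean": self.nc_mean,
                "nc_sd": self.nc_sd,
            }
        )


def robustness_curve(
    g: nx.Graph,
    strategy: str = "random",
    step: float = 0.05,
    max_frac: float = 0.8,
    reps: int = 100,
    seed=None,
) -> RobustnessCurve:
    """Natural connectivity as nodes are progressively removed.

    ``strategy="random"`` removes uniform random node sets (``reps``
    replicates per fraction, mean ± SD reported); ``strategy="degree_desc"``
    removes nodes once, in order of descending degree (ties by node id).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes)
    n = len(nodes)
    fractions = np.arange(0.0, max_frac + 1e-9, step)
    if strategy == "degree_desc":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
        means, sds = [], []
        for f in fractions:
            k = int(round(f * n))
            sub = g.subgraph(nodes if k == 0 else [v for v in nodes if v not in set(order[:k])])
            means.append(natural_connectivity(sub) if sub.number_of_nodes() else 0.0)
            sds.append(0.0)
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        means, sds = [], []
        for f in fractions:
            k = int(round(f * n))
            if k == 0:
                means.append(natural_connectivity(g))
                sds.append(0.0)
                continue
            vals = []
            for _ in range(reps):
                removed = set(rng.choice(n, size=k, replace=False))
                sub = g.subgraph([v for i, v in enumerate(nodes) if i not in removed])
                vals.append(natural_connectivity(sub) if sub.number_of_nodes() else 0.0)
            means.append(float(np.mean(vals)))
            sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return RobustnessCurve(
        strategy=strategy,
        removal_fraction=fractions,
        nc_mean=np.asarray(means),
        nc_sd=np.asarray(sds),
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
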