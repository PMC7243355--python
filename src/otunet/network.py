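"""Co-occurrence networks, centralities, and keystone detection.

A network is built per OTU-table group from the SparCC stage: nodes are the
filtered OTUs, and an edge joins two OTUs whenever the correlation's
permutation p-value is below alpha (strict ``p < 0.05`` by default). Edge
weight is the absolute correlation |rho|; the sign is kept as an attribute
for reporting only — all metrics run on |rho|, so strong negative
associations count as strong connections.

Importance is quantified by weighted PageRank: a node's score grows with the
scores of its neighbours, weighted by how strongly it is connected to them.
Keystone taxa are the nodes above the 99th percentile of PageRank within
their own network — organisms whose importance to community structure
exceeds what their abundance alone would suggest. Degree, betweenness,
closeness and local clustering are computed alongside as cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("otunet")


@dataclass
class CoNetwork:
    """Weighted undirected co-occurrence graph (nodes = OTUs)."""

    graph: nx.Graph
    alpha: float = 0.05

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "otu_i": i,
                "otu_j": j,
                "rho": d["rho"],
                "abs_rho": d["weight"],
                "sign": d["sign"],
                "p": d["p"],
            }
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_i", "otu_j", "rho", "abs_rho", "sign", "p"])


@dataclass
class KeystoneSet:
    """OTUs above the PageRank percentile threshold for one network."""

    otu_ids: list
    percentile: float
    threshold_score: float


def build_network(
    rho: pd.DataFrame,
    pvals: pd.DataFrame,
    alpha: float = 0.05,
    node_abundance: pd.Series | None = None,
) -> CoNetwork:
    """Edges = OTU pairs with p < alpha; weight = |rho|, sign retained.

    Isolated nodes (no significant correlation) stay in the node set so that
    every filtered OTU has a PageRank score. Zero correlations never form
    edges (weights must be positive).
    """
    r = rho.to_numpy()
    p = pvals.to_numpy()
    if list(rho.index) != list(pvals.index) or r.shape != p.shape:
        raise ValueError("rho and pvals must share shape and OTU ids")
    if not np.allclose(r, r.T) or not np.allclose(p, p.T):
        raise ValueError("rho and pvals must be symmetric")
    otus = list(rho.index)
    g = nx.Graph()
    for k, o in enumerate(otus):
        ab = float(node_abundance.get(o, 0.0)) if node_abundance is not None else 0.0
        g.add_node(o, mean_abundance=ab)
    iu, ju = np.triu_indices(len(otus), k=1)
    sig = (p[iu, ju] < alpha) & (r[iu, ju] != 0.0)
    for i, j in zip(iu[sig], ju[sig]):
        g.add_edge(
            otus[i],
            otus[j],
            weight=float(abs(r[i, j])),
            rho=float(r[i, j]),
            sign="+" if r[i, j] > 0 else "-",
            p=float(p[i, j]),
        )
    return CoNetwork(graph=g, alpha=alpha)


def pagerank(
    net: CoNetwork | nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> pd.Series:
    """Weighted PageRank by power iteration on the undirected graph.

    Each undirected edge acts as a pair of directed edges with transition
    probability proportional to its weight. Isolated nodes are dangling:
    their mass is redistributed uniformly, and every node receives the
    (1 - d)/N teleport share. Scores sum to one; iteration stops when the L1
    change drops below ``tol``.
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    idx = {o: k for k, o in enumerate(nodes)}
    W = np.zeros((n, n))
    for i, j, d in g.edges(data=True):
        W[idx[i], idx[j]] = W[idx[j], idx[i]] = d["weight"]
    strength = W.sum(axis=1)
    dangling = strength == 0
    T = np.zeros_like(W)
    nz = ~dangling
    T[nz] = W[nz] / strength[nz, None]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (T.T @ x + x[dangling].sum() / n) + (1.0 - damping) / n
        err = np.abs(x_new - x).sum()
        x = x_new
        if err < tol:
            x /= x.sum()
            return pd.Series(x, index=nodes, name="pagerank")
    raise RuntimeError(f"PageRank did not converge in {max_iter} iterations (L1 residual {err:.2e})")


def centralities(net: CoNetwork, damping: float = 0.85) -> pd.DataFrame:
    """Per-node metrics: pagerank, degree, betweenness, closeness, transitivity.

    Betweenness and closeness use shortest paths with length 1/weight
    (strong correlation = short path), unnormalized; closeness is the
    inverse mean distance within the node's own component (0 for isolated
    nodes); transitivity is the local clustering coefficient of the
    unweighted skeleton.
    """
    g = net.graph
    for _, _, d in g.edges(data=True):
        d["dist"] = 1.0 / d["weight"]
    pr = pagerank(net, damping=damping)
    betw = nx.betweenness_centrality(g, weight="dist", normalized=False)
    close = nx.closeness_centrality(g, distance="dist", wf_improved=False)
    clust = nx.clustering(g)
    df = pd.DataFrame(
        {
            "pagerank": pr,
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
            "transitivity": pd.Series(clust, dtype=float),
            "mean_abundance": pd.Series(nx.get_node_attributes(g, "mean_abundance")),
        }
    ).loc[list(g.nodes)]
    df.index.name = "otu_id"
    return df


def identify_keystones(scores: pd.Series, percentile: float = 99.0) -> KeystoneSet:
    """Nodes strictly above the ``percentile`` of PageRank scores.

    The threshold is the linear-interpolation percentile of all node scores;
    membership is strict exceedance. With heavy ties the strict rule can
    select nobody, in which case the maximal-score nodes are returned (and
    logged) so every network has at least one keystone.
    """
    if len(scores) < 2:
        raise ValueError("need at least two nodes to take a percentile")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    threshold = float(np.percentile(scores.to_numpy(), percentile))
    members = list(scores.index[scores > threshold])
    if not members:
        top = scores.max()
        members = list(scores.index[scores == top])
        logger.info("keystone percentile tie fallback: %d maximal-score nodes", len(members))
    return KeystoneSet(otu_ids=members, percentile=percentile, threshold_score=threshold)


def rank_within_sample(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-column ranks, highest value = rank 1, ties get the average rank.

    Puts abundance and importance on a common scale so the two can be
    compared within each sample or group.
    """
    ranked = profile.apply(lambda col: rankdata(-col.to_numpy(), method="average"), axis=0)
    return pd.DataFrame(ranked, index=profile.index, columns=profile.columns)


# -- export ----------------------------------------------------------------


def node_metrics_table(
    metrics: pd.DataFrame, keystones: KeystoneSet
) -> pd.DataFrame:
    out = metrics.copy()
    out["keystone"] = out.index.isin(set(keystones.otu_ids))
    return out


def write_network(net: CoNetwork, edges_path, graphml_path=None) -> None:
    net.edge_list().to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)
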