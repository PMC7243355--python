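"""Community dissimilarities, NMDS ordination, hierarchical clustering.

Three dissimilarities drive the community comparisons:

* Bray-Curtis  BC(x, y) = sum|x_k - y_k| / sum(x_k + y_k)  on relative
  abundances (abundance-weighted);
* Jaccard     J(x, y) = 1 - |supp x ∩ supp y| / |supp x ∪ supp y|
  (presence/absence only);
* weighted UniFrac  W(A, B) = sum_i b_i |A_i - B_i|  over tree branches,
  where A_i is the fraction of community A descending from branch i; the
  normalized variant divides by sum_i b_i (A_i + B_i) so entries stay in
  [0, 1], comparable with Bray-Curtis.

The same machinery accepts per-sample OTU tables (rows of the distance
matrix are samples) or per-group profile matrices — e.g. PageRank importance
profiles versus mean-relative-abundance profiles, whose dendrograms are the
abundance-vs-importance community comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from sklearn.manifold import smacof

_LINKAGES = {"average", "complete", "single", "ward"}


def _as_profiles(data) -> pd.DataFrame:
    """Normalize input to an entities x features DataFrame.

    An OtuTable becomes samples x OTUs relative abundances; a DataFrame is
    taken as given (rows = entities to compare).
    """
    if hasattr(data, "relative_abundance"):  # OtuTable
        return data.relative_abundance().T
    return pd.DataFrame(data)


def _check_profiles(profiles: pd.DataFrame) -> None:
    arr = profiles.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("profiles must be non-negative")
    zero = profiles.index[arr.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero profiles: {zero}")


def bray_curtis(data) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (or profile rows)."""
    profiles = _as_profiles(data)
    _check_profiles(profiles)
    d = pdist(profiles.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in profiles.index])


def jaccard(data) -> DistanceMatrix:
    """Jaccard dissimilarity on presence/absence of each feature."""
    profiles = _as_profiles(data)
    _check_profiles(profiles)
    d = pdist(profiles.to_numpy(dtype=float) > 0, metric="jaccard")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in profiles.index])


# -- weighted UniFrac ------------------------------------------------------


def _branch_matrix(tree: TreeNode, feature_ids: list) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths b and leaf-membership indicator (branches x features).

    Every non-root node contributes one branch; its row marks the features
    (OTUs) descending from it. Raises if any feature id is missing a leaf.
    """
    leaf_pos = {}
    for leaf in tree.tips():
        leaf_pos[str(leaf.name)] = leaf
    missing = [f for f in feature_ids if str(f) not in leaf_pos]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing}")
    col = {str(f): k for k, f in enumerate(feature_ids)}
    nodes = [n for n in tree.postorder(include_self=False)]
    lengths = np.array([float(n.length or 0.0) for n in nodes])
    member = np.zeros((len(nodes), len(feature_ids)))
    node_row = {id(n): r for r, n in enumerate(nodes)}
    for r, n in enumerate(nodes):
        if n.is_tip():
            if str(n.name) in col:
                member[r, col[str(n.name)]] = 1.0
        else:
            for child in n.children:
                member[r] += member[node_row[id(child)]]
    return lengths, member


def weighted_unifrac(data, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac between samples given a rooted tree over the OTUs."""
    profiles = _as_profiles(data)
    _check_profiles(profiles)
    rel = profiles.to_numpy(dtype=float)
    rel = rel / rel.sum(axis=1, keepdims=True)
    lengths, member = _branch_matrix(tree, list(profiles.columns))
    desc = rel @ member.T  # entities x branches: descendant fraction per branch
    n = desc.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        diff = np.abs(desc[a] - desc[a + 1 :])  # remaining rows at once
        raw = diff @ lengths
        if normalized:
            denom = (desc[a] + desc[a + 1 :]) @ lengths
            raw = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
        out[a, a + 1 :] = raw
    out = out + out.T
    return DistanceMatrix(out, ids=[str(i) for i in profiles.index])


# -- ordination ------------------------------------------------------------


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * c @ (d**2) @ c
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS minimizing Kruskal stress-1.

    Majorization (SMACOF) with isotonic regression of the disparities; the
    first start is initialized from classical metric MDS of ``d``, the rest
    from seeded random configurations, and the lowest-stress solution wins.
    Returns (coordinates, stress-1).
    """
    dm = np.asarray(d.data if isinstance(d, DistanceMatrix) else d, dtype=float)
    ids = list(d.ids) if isinstance(d, DistanceMatrix) else [str(i) for i in range(len(dm))]
    n = dm.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n - 1:
        raise ValueError(f"k must be < n - 1 (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    inits = [_classical_mds(dm, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(max(0, n_starts - 1))]
    for init in inits:
        coords, stress = smacof(
            dm,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-8,
            normalized_stress=True,
            random_state=int(rng.integers(2**31)),
        )
        if stress < best_stress:
            best_coords, best_stress = coords, float(stress)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(best_coords, index=ids, columns=cols), best_stress


# -- hierarchical clustering ----------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge history over labelled entities."""

    merges: np.ndarray  # scipy linkage matrix (n-1 x 4)
    labels: list
    method: str

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick with branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix (default UPGMA).

    Entities are sorted lexicographically by label before linkage so that
    tie-breaking between equal merge heights is deterministic.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    ids = sorted(d.ids)
    dm = d.filter(ids)
    z = hierarchy.linkage(squareform(dm.data, checks=False), method=linkage)
    return Dendrogram(merges=z, labels=list(ids), method=linkage)


# -- abundance / importance profiles --------------------------------------


def importance_profiles(networks: dict) -> pd.DataFrame:
    """Group x OTU matrix of PageRank scores over the union of OTUs.

    ``networks`` maps a group label to that group's node-metrics frame (or
    directly to a PageRank Series); absent OTUs get 0. Rows are suitable
    inputs to the dissimilarity functions and hierarchical clustering.
    """
    if len(networks) < 2:
        raise ValueError("need at least two groups to compare profiles")
    series = {}
    for group, metrics in networks.items():
        scores = metrics["pagerank"] if isinstance(metrics, pd.DataFrame) else metrics
        series[group] = scores
    return pd.DataFrame(series).T.fillna(0.0)


def abundance_profiles(group_means: pd.DataFrame) -> pd.DataFrame:
    """Group x OTU mean relative abundances, zero-filled (pass-through)."""
    return group_means.fillna(0.0)
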