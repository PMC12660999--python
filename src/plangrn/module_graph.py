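"""Module-level graph analyses.

Four module-wise similarity layers (gene-graph cross-connections, motif
enrichment profiles, functional enrichment profiles, TF connectivity
profiles) are merged into a consensus graph keeping edges supported by at
least two layers; communities are found by weighted label propagation.
A bootstrap-style ensemble of subsampled clusterings yields a
co-occurrence tree of cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def _gini(sizes: np.ndarray) -> float:
    """Gini coefficient of a size distribution (0 = perfectly even)."""
    x = np.sort(np.asarray(sizes, dtype=float))
    n = x.size
    if n == 0 or x.sum() == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def prune_tom_graph(
    tom: pd.DataFrame, thresholds: np.ndarray | list[float] | None = None
) -> tuple[float, nx.Graph]:
    """Choose the TOM edge threshold maximising evenly-sized components.

    For each candidate threshold t, edges with TOM >= t are kept and the
    score is C(t) * (1 - Gini of component sizes) over components with at
    least two nodes.  The argmax wins, ties going to the larger threshold;
    isolated nodes are dropped from the returned graph.
    """
    vals = tom.to_numpy(float)
    n = vals.shape[0]
    off = vals[~np.eye(n, dtype=bool)]
    if thresholds is None:
        thresholds = np.quantile(off, np.linspace(0.5, 0.999, 40))
        thresholds = np.unique(thresholds)
    best_t, best_score = None, -np.inf
    for t in sorted(thresholds, reverse=True):  # larger t wins ties
        adj = (vals >= t).astype(np.int8)
        np.fill_diagonal(adj, 0)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        sizes = np.bincount(labels)
        sizes = sizes[sizes >= 2]
        score = len(sizes) * (1.0 - _gini(sizes)) if len(sizes) else 0.0
        if score > best_score:
            best_t, best_score = float(t), score
    if best_t is None:
        best_t = float(sorted(thresholds)[-1])
    adj = (vals >= best_t)
    np.fill_diagonal(adj, False)
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(adj, 1))
    names = list(tom.index)
    g.add_edges_from((names[i], names[j]) for i, j in zip(ii, jj))
    return best_t, g


def cross_connections(
    graph: nx.Graph, assignment: pd.Series
) -> pd.DataFrame:
    """Size-normalised counts of direct neighbour links between modules.

    For gene x of module M, neighbours are counted per module and divided
    by |M|; contributions are summed over the genes of M.  The result is
    symmetrised as an upper-triangle matrix (the two directed sums are
    added), diagonal set to zero.
    """
    modules = sorted(assignment.unique())
    midx = {m: i for i, m in enumerate(modules)}
    sizes = assignment.value_counts()
    mat = np.zeros((len(modules), len(modules)))
    for gene in graph.nodes:
        if gene not in assignment.index:
            continue
        m = assignment[gene]
        for nb in graph.neighbors(gene):
            if nb in assignment.index:
                mat[midx[m], midx[assignment[nb]]] += 1.0 / sizes[m]
    upper = np.triu(mat + mat.T, 1)
    return pd.DataFrame(upper, index=modules, columns=modules)


def correlation_layer(
    profile_matrix: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Module x module adjacency: Pearson r between profile rows, an edge
    kept (weight r) where r >= threshold; diagonal zero."""
    vals = profile_matrix.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    r = np.nan_to_num(r, nan=0.0)
    adj = np.where(r >= threshold, r, 0.0)
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=profile_matrix.index, columns=profile_matrix.index)


def consensus_merge(
    layers: list[pd.DataFrame], min_support: int = 2
) -> nx.Graph:
    """Merge module-wise layers; keep edges present in >= min_support
    layers, with the support count as edge weight and per-layer flags."""
    nodes = sorted(set().union(*[set(l.index) for l in layers]))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            present = [
                k
                for k, layer in enumerate(layers)
                if u in layer.index
                and v in layer.columns
                and (layer.loc[u, v] > 0 or layer.loc[v, u] > 0)
            ]
            if len(present) >= min_support:
                g.add_edge(u, v, weight=len(present), layers=tuple(present))
    return g


def communities_label_propagation(graph: nx.Graph, seed: int = 0) -> pd.Series:
    """Weighted asynchronous label propagation; deterministic given seed."""
    if graph.number_of_nodes() == 0:
        return pd.Series(dtype=int)
    comms = nx.community.asyn_lpa_communities(graph, weight="weight", seed=seed)
    labels = {}
    for k, comm in enumerate(sorted((sorted(c) for c in comms), key=lambda c: c[0])):
        for node in comm:
            labels[node] = k
    return pd.Series(labels, name="community").sort_index()


def ensemble_cooccurrence_tree(
    profile_matrix: pd.DataFrame,  # features x groups
    heights: tuple[float, ...] = (0.75, 0.9),
    n: int = 1000,
    subsample_frac: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Consensus co-clustering of groups over subsampled feature sets.

    Each iteration subsamples ceil(frac * features) features, computes the
    Pearson-correlation distance between group columns, builds an
    average-linkage tree and cuts it at each height; co-clustered group
    pairs increment the frequency matrix.  The returned consensus tree is
    average linkage on (1 - frequency).
    """
    rng = np.random.default_rng(seed)
    groups = list(profile_matrix.columns)
    G = len(groups)
    n_feat = profile_matrix.shape[0]
    k = int(np.ceil(subsample_frac * n_feat))
    if k < 3:
        raise ValueError(f"subsample of {k} features is too small (need >= 3)")
    freq = np.zeros((G, G))
    total = 0
    vals = profile_matrix.to_numpy(float)
    for _ in range(n):
        idx = rng.choice(n_feat, size=k, replace=False)
        sub = vals[idx]
        with np.errstate(invalid="ignore"):
            cor = np.corrcoef(sub.T)
        cor = np.nan_to_num(cor, nan=0.0)
        np.fill_diagonal(cor, 1.0)
        dist = 1.0 - cor
        dist = 0.5 * (dist + dist.T)
        np.fill_diagonal(dist, 0.0)
        condensed = dist[np.triu_indices(G, 1)]
        Z = linkage(condensed, method="average")
        for h in heights:
            labels = fcluster(Z, t=h, criterion="distance")
            same = labels[:, None] == labels[None, :]
            freq += same
            total += 1
    freq /= total
    np.fill_diagonal(freq, 1.0)
    freq_df = pd.DataFrame(freq, index=groups, columns=groups)
    consensus_dist = 1.0 - freq
    np.fill_diagonal(consensus_dist, 0.0)
    Z = linkage(consensus_dist[np.triu_indices(G, 1)], method="average")
    return freq_df, Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick string."""
    from scipy.cluster.hierarchy import to_tree

    def _rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = _rec(node.get_left()), _rec(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return _rec(to_tree(Z)) + ";"
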