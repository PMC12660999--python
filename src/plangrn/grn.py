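"""Transparent TF -> target interaction and influence scoring.

A fully specified additive instantiation of expression/accessibility-based
network inference: TF binding to a target gene is the accessibility of
motif-bearing open chromatin near the target's TSS under an exponential
distance decay; the interaction score averages four min-max-scaled rank
components (TF expression, target expression, binding, TF activity);
influence for a stem-cell -> fate transition combines the TF's expression
change with its scored targeting of upregulated genes, 50/50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata


@dataclass(frozen=True)
class BindingParams:
    window: float = 100_000.0  # search window W around the TSS, bp
    decay: float = 25_000.0  # exponential decay length lambda, bp


def weighted_binding(
    motif_hits: pd.DataFrame,  # region_id, motif_id, count
    ocr_accessibility: pd.Series,  # per-OCR accessibility in one cell type
    ocr2gene: pd.DataFrame,  # ocr_id, gene_id, distance (signed bp)
    tf2motif: dict[str, str],
    params: BindingParams = BindingParams(),
) -> pd.DataFrame:
    """TF x gene weighted binding B_tg = sum over motif-bearing OCRs o with
    |d(o, g)| <= W of acc(o) * exp(-|d(o, g)| / lambda).

    TFs without a motif annotation get a zero row.  B is zero whenever no
    motif-bearing OCR lies within the window of the gene's TSS.
    """
    ocr_map = ocr2gene.set_index("ocr_id")
    motif_regions = {
        m: set(g["region_id"]) for m, g in motif_hits.groupby("motif_id")
    }
    genes = sorted(ocr_map["gene_id"].unique())
    gidx = {g: j for j, g in enumerate(genes)}
    tfs = sorted(tf2motif)
    B = np.zeros((len(tfs), len(genes)))
    acc = ocr_accessibility
    kernel = {}
    for ocr_id, row in ocr_map.iterrows():
        d = abs(row["distance"])
        if d > params.window or ocr_id not in acc.index:
            continue
        kernel[ocr_id] = (gidx[row["gene_id"]], float(acc[ocr_id]) * np.exp(-d / params.decay))
    for i, tf in enumerate(tfs):
        regions = motif_regions.get(tf2motif[tf], set())
        for ocr_id in regions:
            hit = kernel.get(ocr_id)
            if hit is not None:
                B[i, hit[0]] += hit[1]
    return pd.DataFrame(B, index=tfs, columns=genes)


def _scaled_rank(x: np.ndarray) -> np.ndarray:
    """Average ranks min-max scaled to [0, 1]; constant input maps to 1."""
    r = rankdata(x, method="average")
    lo, hi = r.min(), r.max()
    if hi == lo:
        return np.ones_like(r)
    return (r - lo) / (hi - lo)


def interaction_scores(
    binding: pd.DataFrame,  # TF x gene
    expression: pd.Series,  # per-gene expression in the cell type
) -> pd.DataFrame:
    """Additive interaction score in [0, 1] for every TF -> gene pair.

    score(t, g) is the mean of four rank components, each min-max scaled
    over the network: TF expression, target expression, binding B_tg, and
    TF activity (mean binding of t over genes).  Returned as a long table
    (tf, target, score, four components), scores in [0, 1].
    """
    tfs = list(binding.index)
    genes = list(binding.columns)
    expr = expression.reindex(genes).fillna(0.0)
    tf_expr = expression.reindex(tfs).fillna(0.0)
    activity = binding.mean(axis=1)

    tf_expr_s = _scaled_rank(tf_expr.to_numpy())
    tgt_expr_s = _scaled_rank(expr.to_numpy())
    act_s = _scaled_rank(activity.to_numpy())
    bind_s = _scaled_rank(binding.to_numpy().ravel()).reshape(binding.shape)

    score = 0.25 * (
        tf_expr_s[:, None] + tgt_expr_s[None, :] + bind_s + act_s[:, None]
    )
    long = pd.DataFrame(
        {
            "tf": np.repeat(tfs, len(genes)),
            "target": np.tile(genes, len(tfs)),
            "score": score.ravel(),
            "tf_expr": np.repeat(tf_expr_s, len(genes)),
            "target_expr": np.tile(tgt_expr_s, len(tfs)),
            "binding": bind_s.ravel(),
            "tf_activity": np.repeat(act_s, len(genes)),
        }
    )
    return long


def prune_network(net: pd.DataFrame, min_score: float = 0.8) -> nx.DiGraph:
    """Directed graph of interactions with score strictly above
    ``min_score``; nodes without neighbours are absent by construction."""
    kept = net[net["score"] > min_score]
    g = nx.DiGraph()
    for row in kept.itertuples(index=False):
        g.add_edge(row.tf, row.target, score=row.score)
    return g


def network_metrics(
    graph: nx.DiGraph, relative_outdegree_literal: bool = False
) -> pd.DataFrame:
    """Per-gene degree and centrality metrics.

    relative outdegree = out / (in + out); the literal variant
    in / (in + out) is available behind a flag.  Centrality is PageRank on
    edge scores; out-centrality the same on the reversed graph.
    """
    nodes = sorted(graph.nodes)
    indeg = dict(graph.in_degree())
    outdeg = dict(graph.out_degree())
    if graph.number_of_edges():
        cent = nx.pagerank(graph, weight="score")
        out_cent = nx.pagerank(graph.reverse(copy=True), weight="score")
    else:
        cent = out_cent = {n: 0.0 for n in nodes}
    rows = []
    for n in nodes:
        i, o = indeg.get(n, 0), outdeg.get(n, 0)
        tot = i + o
        rel = np.nan if tot == 0 else (i / tot if relative_outdegree_literal else o / tot)
        rows.append((n, i, o, rel, cent.get(n, 0.0), out_cent.get(n, 0.0)))
    return pd.DataFrame(
        rows,
        columns=["gene", "indegree", "outdegree", "relative_outdegree",
                 "centrality", "out_centrality"],
    ).set_index("gene")


def active_tfs(graph: nx.DiGraph) -> int:
    """Number of genes with outdegree above zero."""
    return sum(1 for _, d in graph.out_degree() if d > 0)


def centrality_similarity(
    centrality_by_fate: pd.DataFrame,  # TF x fate
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fate x fate Pearson correlation of TF centrality profiles plus a
    Ward tree over (1 - r)."""
    vals = centrality_by_fate.to_numpy(float)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vals.T)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    fates = list(centrality_by_fate.columns)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    Z = linkage(dist[np.triu_indices(len(fates), 1)], method="ward")
    return pd.DataFrame(r, index=fates, columns=fates), Z


def influence_scores(
    net_fate: pd.DataFrame,  # interaction table of the fate network
    dge: pd.DataFrame,  # index gene, columns log2FC, padj
    top_edges: int = 250_000,
    padj_threshold: float = 0.05,
    tf_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Influence of each TF on a stem-cell -> fate transition.

    The differential network keeps the ``top_edges`` highest-scoring fate
    edges whose targets are significantly upregulated.  Per TF,
    G_t = sum over upregulated targets of score * log2FC; the influence is
    0.5 * scale01(max(0, log2FC of the TF)) + 0.5 * scale01(G_t).
    Rankings are invariant to uniformly rescaling the log2FCs.
    """
    up = dge[(dge["padj"] < padj_threshold) & (dge["log2FC"] > 0)]
    tfs = sorted(net_fate["tf"].unique())
    if up.empty:
        return pd.DataFrame(
            {"influence": 0.0, "target_score": 0.0, "expr_change": 0.0}, index=tfs
        )
    edges = net_fate[net_fate["target"].isin(up.index)]
    edges = edges.nlargest(min(top_edges, len(edges)), "score")
    lfc = up["log2FC"]
    g = (
        edges.assign(contrib=edges["score"] * edges["target"].map(lfc).to_numpy())
        .groupby("tf")["contrib"]
        .sum()
        .reindex(tfs)
        .fillna(0.0)
    )
    tf_gene = tf_gene or {}
    de = pd.Series(
        [
            max(0.0, float(dge["log2FC"].get(tf_gene.get(tf, tf), 0.0)))
            for tf in tfs
        ],
        index=tfs,
    )

    def _scale01(x: pd.Series) -> pd.Series:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return pd.Series(0.0, index=x.index)
        return (x - lo) / (hi - lo)

    influence = 0.5 * _scale01(de) + 0.5 * _scale01(g)
    return pd.DataFrame(
        {"influence": influence, "target_score": g, "expr_change": de}
    ).sort_values("influence", ascending=False)


def coinfluence_clusters(
    influence_table: pd.DataFrame,  # TF x fate influence matrix
    cut: float = 0.7,
    top_n: int = 5,
) -> pd.DataFrame:
    """Cluster TFs by Pearson correlation of influence profiles.

    Distance 1 - r, Ward linkage, tree cut at the given height; within each
    cluster TFs are sorted by correlation to the cluster's mean profile and
    the top ``top_n`` flagged.
    """
    vals = influence_table.to_numpy(float)
    if len(influence_table) == 1:
        return pd.DataFrame(
            {"tf": influence_table.index, "cluster": [1], "rank_in_cluster": [1],
             "top": [True]}
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vals)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    Z = linkage(dist[np.triu_indices(len(influence_table), 1)], method="ward")
    labels = fcluster(Z, t=cut, criterion="distance")
    rows = []
    for lab in np.unique(labels):
        members = influence_table.index[labels == lab]
        centroid = influence_table.loc[members].mean(axis=0).to_numpy()
        cors = []
        for tf in members:
            x = influence_table.loc[tf].to_numpy()
            if x.std() == 0 or centroid.std() == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(x, centroid)[0, 1]))
        order = np.argsort(-np.asarray(cors), kind="stable")
        for rank, pos in enumerate(order, start=1):
            rows.append((members[pos], int(lab), rank, rank <= top_n))
    return pd.DataFrame(rows, columns=["tf", "cluster", "rank_in_cluster", "top"])


def top_targets(
    net: pd.DataFrame, tf: str, quantile: float = 0.95
) -> pd.DataFrame:
    """Targets of ``tf`` with interaction score at or above the score
    quantile (ties at the threshold are kept)."""
    edges = net[net["tf"] == tf]
    if edges.empty:
        return edges
    thresh = edges["score"].quantile(quantile)
    return (
        edges[edges["score"] >= thresh]
        .sort_values("score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
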