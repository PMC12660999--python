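"""Weighted pseudobulk aggregation and normalisation.

Single-cell counts are aggregated into per-group columns (groups are cell
clusters, optionally crossed with condition and replicate).  Genes thinly
scattered across large clusters are down-weighted by the expression
constraint

    w_ij = 1 - exp(-a_ij / b_ij)

where a_ij is the fraction of cells of group j expressing gene i and b_ij
the fraction of cells outside group j expressing it.  Columns are
normalised by median-of-ratios size factors before weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AnnotatedCountMatrix

log = logging.getLogger(__name__)


@dataclass
class WeightedPseudobulk:
    counts: pd.DataFrame  # genes x groups, integer
    a: pd.DataFrame | None = None  # fraction expressing inside group
    b: pd.DataFrame | None = None  # fraction expressing outside group
    w: pd.DataFrame | None = None  # cell weights in [0, 1]
    size_factors: pd.Series | None = None
    normalized_weighted: pd.DataFrame | None = None
    cells_expressing: pd.DataFrame | None = None  # raw counts of expressing cells
    group_sizes: pd.Series | None = None


def _group_indicator(annotation: pd.DataFrame, keys: list[str]) -> pd.Series:
    for key in keys:
        if key not in annotation.columns:
            raise KeyError(f"annotation lacks key column '{key}'")
        if annotation[key].isna().any():
            raise ValueError(f"annotation column '{key}' has missing values")
    labels = annotation[keys].astype(str).agg("|".join, axis=1)
    return labels


def aggregate(
    acm: AnnotatedCountMatrix, keys: list[str] | tuple[str, ...] = ("cluster",)
) -> WeightedPseudobulk:
    """Sum counts of every gene over the cells of each group.

    Total mass is conserved: the sum over the pseudobulk equals the sum over
    the input matrix.  Empty groups cannot arise (groups are defined by the
    cells present); group ordering is lexicographic and deterministic.
    """
    labels = _group_indicator(acm.obs, list(keys))
    groups = sorted(labels.unique())
    gidx = {g: j for j, g in enumerate(groups)}
    col = np.array([gidx[g] for g in labels])
    # indicator cells x groups, then sparse matmul
    ind = sp.csr_matrix(
        (np.ones(len(col)), (np.arange(len(col)), col)),
        shape=(len(col), len(groups)),
    )
    summed = np.asarray((acm.values @ ind).todense())
    counts = pd.DataFrame(
        summed.astype(np.int64), index=acm.feature_ids, columns=groups
    )
    sizes = labels.value_counts().reindex(groups)
    return WeightedPseudobulk(counts=counts, group_sizes=sizes)


def expressing_fractions(
    acm: AnnotatedCountMatrix,
    keys: list[str] | tuple[str, ...] = ("cluster",),
    min_counts_per_cell: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-group fractions of cells expressing each gene, inside (a) and
    outside (b) the group.  Also returns the raw expressing-cell counts."""
    if min_counts_per_cell < 1:
        raise ValueError("min_counts_per_cell must be >= 1")
    labels = _group_indicator(acm.obs, list(keys))
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("expressing_fractions needs >= 2 groups (b is undefined)")
    gidx = {g: j for j, g in enumerate(groups)}
    col = np.array([gidx[g] for g in labels])
    ind = sp.csr_matrix(
        (np.ones(len(col)), (np.arange(len(col)), col)),
        shape=(len(col), len(groups)),
    )
    expressed = (acm.values >= min_counts_per_cell).astype(np.int64)
    n_expr = np.asarray((expressed @ ind).todense()).astype(float)
    sizes = np.array([np.sum(col == j) for j in range(len(groups))], dtype=float)
    a = n_expr / sizes[None, :]
    total_expr = n_expr.sum(axis=1, keepdims=True)
    outside = total_expr - n_expr
    b = outside / (sizes.sum() - sizes)[None, :]
    idx = acm.feature_ids
    return (
        pd.DataFrame(a, index=idx, columns=groups),
        pd.DataFrame(b, index=idx, columns=groups),
        pd.DataFrame(n_expr.astype(np.int64), index=idx, columns=groups),
    )


def cell_weights(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """w = 1 - exp(-a / b), with the continuous limits w=1 when b=0 and a>0,
    and w=0 when a=0 (a gene not expressed in the group carries no signal)."""
    av, bv = a.to_numpy(float), b.to_numpy(float)
    if (av < 0).any() or (av > 1).any() or (bv < 0).any() or (bv > 1).any():
        raise ValueError("a and b must be fractions in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 - np.exp(-np.divide(av, bv, out=np.full_like(av, np.inf), where=bv > 0))
    w[av == 0] = 0.0
    w[(bv == 0) & (av > 0)] = 1.0
    return pd.DataFrame(w, index=a.index, columns=a.columns)


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean reference.

    Genes with a zero in any column are excluded from the reference
    (standard convention); if no gene is positive in every column the
    factors fall back to column-sum scaling, which is logged.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        log.warning("no gene positive in all columns; falling back to column-sum scaling")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns, name="size_factor")
    sub = mat[positive]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / ref[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def apply_filters(
    wpb: WeightedPseudobulk, min_counts: int = 30, min_cells: int = 3
) -> WeightedPseudobulk:
    """Gene filter and per-entry support rule.

    Genes with fewer than ``min_counts`` total counts across the dataset are
    removed.  Entries (i, j) supported by fewer than ``min_cells``
    expressing cells of group j are zeroed in the weight matrix, so they
    vanish from the weighted output while the gene itself is kept (the rule
    retrieves expression information per group, it does not drop genes).
    """
    keep = wpb.counts.sum(axis=1) >= min_counts
    if not keep.any():
        raise ValueError("all genes removed by the total-count filter")
    counts = wpb.counts.loc[keep]

    def _sub(df: pd.DataFrame | None) -> pd.DataFrame | None:
        return None if df is None else df.loc[keep]

    a, b, w = _sub(wpb.a), _sub(wpb.b), _sub(wpb.w)
    n_expr = _sub(wpb.cells_expressing)
    if w is not None and n_expr is not None:
        w = w.where(n_expr >= min_cells, 0.0)
    return WeightedPseudobulk(
        counts=counts, a=a, b=b, w=w,
        size_factors=wpb.size_factors,
        cells_expressing=n_expr,
        group_sizes=wpb.group_sizes,
    )


def normalize_and_weight(wpb: WeightedPseudobulk) -> pd.DataFrame:
    """Normalise by size factors first, then multiply by the cell weights."""
    if wpb.size_factors is None:
        raise ValueError("size factors not computed")
    norm = wpb.counts / wpb.size_factors
    if wpb.w is not None:
        norm = norm * wpb.w
    return norm


def weighted_pseudobulk(
    acm: AnnotatedCountMatrix,
    keys: list[str] | tuple[str, ...] = ("cluster",),
    min_counts: int = 30,
    min_cells: int = 3,
    min_counts_per_cell: int = 1,
) -> WeightedPseudobulk:
    """Full pipeline: aggregate, weight, filter, normalise.

    Order of operations: the total-count gene filter is applied first, then
    size factors are estimated on the filtered counts, then the weighted
    normalised matrix is formed.
    """
    wpb = aggregate(acm, keys)
    a, b, n_expr = expressing_fractions(acm, keys, min_counts_per_cell)
    wpb.a, wpb.b, wpb.cells_expressing = a, b, n_expr
    wpb.w = cell_weights(a, b)
    wpb = apply_filters(wpb, min_counts=min_counts, min_cells=min_cells)
    wpb.size_factors = size_factors_median_ratio(wpb.counts)
    wpb.normalized_weighted = normalize_and_weight(wpb)
    return wpb


def supermatrix(
    acm: AnnotatedCountMatrix,
    keys: list[str] | tuple[str, ...] = ("cluster", "condition", "replicate"),
) -> pd.DataFrame:
    """Pseudobulk supermatrix: genes x (cluster x condition x replicate).

    Plain aggregated counts (no weighting): the replicated design feeds the
    negative-binomial differential tests, which model raw counts.
    """
    return aggregate(acm, keys).counts
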