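"""Weighted correlation network modules on pseudobulk profiles.

The workflow follows the standard weighted co-expression recipe: filter by
coefficient of variation, row-scale, soft-threshold the correlation matrix
to near scale-free topology, form the topological overlap matrix (TOM),
cluster 1 - TOM hierarchically and cut the tree into modules.  Modules are
classified as single-type ("s") or multi-type ("m") from the distribution
of per-group upper quartiles of member-gene expression, and renamed in a
fixed order of their peak group.

The tree cut is a simplified dynamic cut: candidate cut heights are swept
from high to low and the height that yields the largest number of
sufficiently large branches is kept; smaller leftovers stay unassigned
(the "grey" convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class WGCNAParams:
    cv_min: float = 1.25
    beta: int = 8  # soft power: 8 expression / 7 all-OCR / 8 DA-OCR
    linkage_method: str = "average"  # "average" (expression) or "ward" (OCR)
    min_module_size: int = 50  # 50 expression / 100 all-OCR / 30 DA-OCR
    min_branch_gap: float = 0.1  # merge-height gap (fraction of tree height)
    seed: int = 0


@dataclass
class ModuleAssignment:
    """feature -> module display id, with class and peak-group annotations."""

    table: pd.DataFrame  # columns: module, cls, peak_group; index: features
    module_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def assigned(self) -> pd.Series:
        return self.table.loc[self.table["module"] != "unassigned", "module"]

    def members(self, module: str) -> list[str]:
        return self.module_members[module]


def filter_by_cv(matrix: pd.DataFrame, cv_min: float = 1.25) -> pd.DataFrame:
    """Keep rows with coefficient of variation sd/mean above ``cv_min``.

    The population standard deviation is used (a one-hot profile over K
    groups has CV = sqrt(K - 1)).  Rows with non-positive mean are dropped.
    """
    vals = matrix.to_numpy(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, -np.inf)
    return matrix.loc[cv > cv_min]


def scale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-score; constant rows become zero rows."""
    vals = matrix.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mean) / sd, index=matrix.index, columns=matrix.columns)


def adjacency(matrix: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta with unit diagonal."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(matrix.to_numpy(float))
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


def soft_power_scan(
    cor_abs: pd.DataFrame | np.ndarray,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Scale-free topology fit across soft powers.

    For each power the connectivity k_i = sum_j |cor|^beta - 1 is binned and
    the R^2 of log10 p(k) vs log10 k is computed (only decreasing fits
    count).  The chosen power is the smallest one reaching ``r2_target``,
    else the argmax of the fit.
    """
    ca = np.asarray(cor_abs, dtype=float)
    rows = []
    for beta in powers:
        adj = ca**beta
        k = adj.sum(axis=1) - np.diag(adj)
        mean_k = float(k.mean())
        if np.allclose(k, k[0]):
            rows.append((beta, np.nan, np.nan, mean_k))
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = (hist > 0) & (centers > 0)
        if keep.sum() < 3:
            rows.append((beta, np.nan, np.nan, mean_k))
            continue
        x = np.log10(centers[keep])
        y = np.log10(hist[keep] / hist.sum())
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else np.nan
        rows.append((beta, r2 if slope < 0 else 0.0, slope, mean_k))
    table = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_k"])
    ok = table.dropna(subset=["r2"])
    hit = ok.loc[ok["r2"] >= r2_target, "power"]
    if len(hit):
        chosen = int(hit.iloc[0])
    elif len(ok):
        chosen = int(ok.loc[ok["r2"].idxmax(), "power"])
    else:
        chosen = int(table["power"].iloc[0])
    return table, chosen


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj, and TOM_ii = 1.
    """
    if isinstance(adj, pd.DataFrame):
        index = adj.index
        a = adj.to_numpy(float)
    else:
        a = np.asarray(adj, dtype=float)
        index = pd.RangeIndex(a.shape[0])
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    L = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (L + a0) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=index, columns=index)


def detect_modules(tom_matrix: pd.DataFrame, params: WGCNAParams) -> ModuleAssignment:
    """Cut the 1 - TOM dendrogram into modules by branch decomposition.

    A dendrogram node qualifies as a module branch when it holds at least
    ``min_module_size`` leaves and is separated from its sibling context by
    a merge-height gap of at least ``min_branch_gap`` (its parent merges at
    a height exceeding the node's own top merge by that much).  Each leaf
    is assigned to its smallest qualifying ancestor; leaves with none stay
    unassigned (the "grey" convention).  The gap criterion keeps cohesive
    branches whole — internal merges form a continuum, so no internal node
    is well separated — while refusing arbitrary slices of background
    noise, whose merges also form a continuum near the top of the tree.
    Deterministic, and invariant to feature order up to linkage ties.
    """
    features = tom_matrix.index
    n = len(features)
    table = pd.DataFrame(
        {"module": "unassigned", "cls": "", "peak_group": ""}, index=features
    )
    if n < 2 or params.min_module_size > n:
        return ModuleAssignment(table=table)
    dist = 1.0 - tom_matrix.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    method = "ward" if params.linkage_method.startswith("ward") else "average"
    Z = linkage(squareform(dist, checks=False), method=method)

    # per node: leaf count, own merge height, parent's merge height
    n_nodes = 2 * n - 1
    counts = np.ones(n_nodes)
    heights = np.zeros(n_nodes)
    parent_h = np.full(n_nodes, np.inf)
    children = {}
    for k in range(n - 1):
        left, right = int(Z[k, 0]), int(Z[k, 1])
        node = n + k
        children[node] = (left, right)
        counts[node] = counts[left] + counts[right]
        heights[node] = Z[k, 2]
        parent_h[left] = parent_h[right] = Z[k, 2]

    # the gap threshold is relative to the total tree height so the
    # criterion transfers between average and ward linkage scales
    gap = params.min_branch_gap * float(Z[:, 2].max())
    qualifies = (
        (counts >= params.min_module_size)
        & (parent_h - heights >= gap)
        & (parent_h < np.inf)  # the root is never a module on its own
    )

    labels = np.full(n, -1, dtype=int)

    def _assign(node: int, current: int) -> None:
        if qualifies[node]:
            current = node
        if node < n:
            labels[node] = current
        else:
            left, right = children[node]
            _assign(left, current)
            _assign(right, current)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 2 * n + 100))
    try:
        _assign(n_nodes - 1, -1)
    finally:
        sys.setrecursionlimit(old_limit)

    # leftovers of a branch whose leaves were mostly captured by a nested
    # qualifying branch can fall below the size floor; unassign them
    lab_series = pd.Series(labels)
    final_sizes = lab_series.value_counts()
    small = {lab for lab, s in final_sizes.items() if s < params.min_module_size}
    labels = np.where(np.isin(labels, list(small)), -1, labels)

    module_names: dict[int, str] = {}
    assigned = []
    for leaf in range(n):
        lab = labels[leaf]
        if lab == -1:
            assigned.append("unassigned")
            continue
        if lab not in module_names:
            module_names[lab] = f"module_{len(module_names) + 1:02d}"
        assigned.append(module_names[lab])
    table["module"] = assigned
    members = {
        m: list(features[[x == m for x in assigned]])
        for m in module_names.values()
    }
    return ModuleAssignment(table=table, module_members=members)


def module_profiles(
    assignment: ModuleAssignment, matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average per-group expression per module and row-normalised relative
    profiles (rows sum to 1 where the total is positive)."""
    rows = {}
    for module, members in assignment.module_members.items():
        rows[module] = matrix.loc[members].mean(axis=0)
    avg = pd.DataFrame(rows).T
    avg = avg.loc[sorted(avg.index)]
    totals = avg.sum(axis=1)
    rel = avg.div(totals.where(totals > 0, 1.0), axis=0)
    return avg, rel


def tau(profile: pd.Series | np.ndarray) -> float:
    """Specificity index in [0, 1]: 0 for uniform, 1 for one-hot profiles.

    tau = sum_i (1 - x_i / max x) / (n - 1), defined for non-negative
    profiles with a positive maximum.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("tau requires a non-negative profile")
    m = x.max()
    if m <= 0:
        raise ValueError("tau requires a positive maximum")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_table(matrix: pd.DataFrame) -> pd.Series:
    vals = matrix.to_numpy(float)
    m = vals.max(axis=1)
    ok = m > 0
    out = np.full(vals.shape[0], np.nan)
    out[ok] = (1.0 - vals[ok] / m[ok, None]).sum(axis=1) / (vals.shape[1] - 1)
    return pd.Series(out, index=matrix.index, name="tau")


def classify_modules(
    assignment: ModuleAssignment,
    gene_matrix: pd.DataFrame,
    prefix: str = "E",
) -> ModuleAssignment:
    """Specific/mixed classification and ordered renaming.

    Per module, the upper quartile (linear interpolation) of member-gene
    expression is computed for each group; groups whose quartile exceeds
    mean + 1.5 sd of that distribution are "outliers".  Exactly one outlier
    gives class "s"; two or more — and also none, since the s label needs
    positive evidence of a single peak — give "m".  Modules are renamed
    s<prefix>##/m<prefix>## ordered by peak-group position in the fixed
    group ordering, ties broken by decreasing module size.
    """
    groups = list(gene_matrix.columns)
    records = []
    for module, members in assignment.module_members.items():
        sub = gene_matrix.loc[[m for m in members if m in gene_matrix.index]]
        uq = sub.quantile(0.75, axis=0, interpolation="linear")
        thresh = uq.mean() + 1.5 * uq.std(ddof=1)
        outliers = uq.index[uq > thresh]
        cls = "s" if len(outliers) == 1 else "m"
        peak = uq.idxmax()
        records.append((module, cls, peak, len(members)))
    rec = pd.DataFrame(records, columns=["old", "cls", "peak_group", "size"])
    rec["peak_pos"] = rec["peak_group"].map({g: i for i, g in enumerate(groups)})
    new_names = {}
    for cls in ("s", "m"):
        sub = rec[rec["cls"] == cls].sort_values(
            ["peak_pos", "size"], ascending=[True, False], kind="mergesort"
        )
        for i, (_, row) in enumerate(sub.iterrows(), start=1):
            new_names[row["old"]] = f"{cls}{prefix}{i:02d}"
    table = assignment.table.copy()
    table["module"] = [
        new_names.get(m, "unassigned") for m in assignment.table["module"]
    ]
    cls_of = dict(zip(rec["old"].map(new_names), rec["cls"]))
    peak_of = dict(zip(rec["old"].map(new_names), rec["peak_group"]))
    table["cls"] = [cls_of.get(m, "") for m in table["module"]]
    table["peak_group"] = [peak_of.get(m, "") for m in table["module"]]
    members = {
        new_names[old]: mem for old, mem in assignment.module_members.items()
    }
    return ModuleAssignment(table=table, module_members=members)


def tf_connectivity(
    tf_matrix: pd.DataFrame, module_avg: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each TF profile with each module average
    profile (kME-style connectivity); constant profiles give NaN."""
    tf_vals = tf_matrix.to_numpy(float)
    mod_vals = module_avg.to_numpy(float)

    def _center(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1))
        return c, norm

    tf_c, tf_n = _center(tf_vals)
    mod_c, mod_n = _center(mod_vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tf_c @ mod_c.T) / np.outer(tf_n, mod_n)
    r[~np.isfinite(r)] = np.nan
    return pd.DataFrame(r, index=tf_matrix.index, columns=module_avg.index)


def expression_modules(
    normalized: pd.DataFrame, params: WGCNAParams | None = None, prefix: str = "E"
) -> tuple[ModuleAssignment, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """End-to-end module detection on a normalised pseudobulk matrix.

    Returns the classified assignment, the module average profiles, the
    relative profiles, and the TOM restricted to the clustered features.
    """
    params = params or WGCNAParams()
    filtered = filter_by_cv(normalized, params.cv_min)
    scaled = scale_rows(filtered)
    adj = adjacency(scaled, params.beta)
    tom_m = tom(adj)
    assignment = detect_modules(tom_m, params)
    if assignment.module_members:
        assignment = classify_modules(assignment, normalized.loc[filtered.index], prefix)
        avg, rel = module_profiles(assignment, normalized.loc[filtered.index])
    else:
        avg = rel = pd.DataFrame(columns=normalized.columns)
    return assignment, avg, rel, tom_m
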