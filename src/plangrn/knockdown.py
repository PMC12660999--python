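"""Knockdown-evaluation statistics.

Per-cell gene-set scores against a random-gene baseline, chi-squared
cell-abundance residuals with post-hoc stars, DEG overlap percentages,
interaction-score validation of in-vivo DEGs against the inferred network,
a logistic detection-power model, and the all-intersections (upset)
partition of DEG sets.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, mannwhitneyu, norm

from .io import AnnotatedCountMatrix

STAR_P05 = 1.959963984540054  # two-sided normal quantile for p < 0.05
STAR_P01 = 2.5758293035489004  # p < 0.01


def gene_score(
    acm: AnnotatedCountMatrix,
    gene_set: list[str],
    subsample_frac: float = 0.05,
    seed: int = 0,
    normalise: str = "z",
) -> pd.Series:
    """Per-cell score: mean expression over the gene set minus mean over a
    random subsample of ceil(frac * G) genes, then z-normalised across
    cells (normalise="none" skips the final normalisation).

    Expression is library-size normalised (counts per cell total, scaled to
    the median total) before averaging.
    """
    rng = np.random.default_rng(seed)
    genes = list(acm.feature_ids)
    set_idx = [genes.index(g) for g in gene_set if g in genes]
    if not set_idx:
        raise ValueError("gene set has no overlap with the matrix features")
    k = int(np.ceil(subsample_frac * len(genes)))
    rand_idx = rng.choice(len(genes), size=k, replace=False)

    totals = np.asarray(acm.values.sum(axis=0)).ravel().astype(float)
    totals[totals == 0] = 1.0
    scale = np.median(totals) / totals

    set_mean = np.asarray(acm.values[set_idx].sum(axis=0)).ravel() * scale / len(set_idx)
    rand_mean = np.asarray(acm.values[rand_idx].sum(axis=0)).ravel() * scale / k
    score = set_mean - rand_mean
    if normalise == "z":
        sd = score.std(ddof=0)
        score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return pd.Series(score, index=acm.cell_ids, name="gene_score")


def abundance_chisq(cell_counts: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Omnibus Pearson chi-squared over a cluster x condition table plus
    adjusted standardized residuals.

    r_ij = (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)); approximately
    standard normal under independence.  Stars: * for |r| > 1.96 (p < .05),
    ** for |r| > 2.58 (p < .01).
    """
    obs = cell_counts.to_numpy(float)
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    N = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / N
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = float(np.nansum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    denom = np.sqrt(expected * (1 - row / N) * (1 - col / N))
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (obs - expected) / denom
    resid = np.nan_to_num(resid, nan=0.0)
    table = pd.DataFrame(resid, index=cell_counts.index, columns=cell_counts.columns)
    long = table.stack().rename("residual").reset_index()
    long.columns = ["cluster", "condition", "residual"]
    long["observed"] = obs.ravel()
    long["expected"] = expected.ravel()
    long["stars"] = np.select(
        [long["residual"].abs() > STAR_P01, long["residual"].abs() > STAR_P05],
        ["**", "*"],
        default="",
    )
    return stat, p, long


def deg_overlap(set_a: set[str], set_b: set[str], name_a: str = "a", name_b: str = "b") -> pd.DataFrame:
    """Exclusive/shared partition of two DEG sets with percentages of the
    union rounded to the nearest integer."""
    shared = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a
    union = len(set_a | set_b)
    rows = [
        (f"{name_a}_only", len(only_a)),
        (f"{name_b}_only", len(only_b)),
        ("shared", len(shared)),
    ]
    out = pd.DataFrame(rows, columns=["part", "n"])
    out["pct"] = [int(round(100 * n / union)) if union else 0 for n in out["n"]]
    return out


def score_vs_deg(
    network: pd.DataFrame, tf: str, deg_flags: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Interaction scores of tf -> gene edges grouped by DEG status, with a
    one-sided (greater) rank-sum p for DEG targets scoring higher."""
    edges = network[network["tf"] == tf][["target", "score"]].copy()
    edges["deg"] = [bool(deg_flags.get(t, False)) for t in edges["target"]]
    summary = edges.groupby("deg")["score"].describe()
    deg_scores = edges.loc[edges["deg"], "score"]
    rest = edges.loc[~edges["deg"], "score"]
    if deg_scores.empty or rest.empty:
        return summary, float("nan")
    _, p = mannwhitneyu(deg_scores, rest, alternative="greater")
    return summary, float(p)


def detection_logistic(
    deg_flag: pd.Series, interaction_score: pd.Series
) -> dict[str, float | bool]:
    """Logistic regression deg ~ score (logit link, IRLS).

    Returns slope, SE, Wald p and a ``separated`` flag raised when the
    classes are perfectly separated by the score (the MLE diverges)."""
    df = pd.DataFrame({"y": deg_flag.astype(int), "x": interaction_score}).dropna()
    y, x = df["y"].to_numpy(), df["x"].to_numpy()
    if y.min() == y.max():
        raise ValueError("need both DEG and non-DEG observations")
    separated = x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            slope, se = float(fit.params[1]), float(fit.bse[1])
            p = float(2 * norm.sf(abs(slope / se))) if se > 0 else float("nan")
        except Exception:  # noqa: BLE001 - divergence under separation
            separated, slope, se, p = True, float("inf"), float("nan"), float("nan")
    if separated:
        p = float("nan")
    return {"slope": slope, "se": se, "p": p, "separated": bool(separated)}


def upset_partition(deg_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive intersection counts over the power set of memberships.

    Each element is counted once, in the cell matching exactly the sets it
    belongs to, so per-set sums of exclusive parts recover set sizes.
    """
    names = sorted(deg_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*[deg_sets[n] for n in combo])
            outside = set.union(set(), *[deg_sets[n] for n in names if n not in combo])
            exclusive = inside - outside
            rows.append(("&".join(combo), combo, len(exclusive)))
    return pd.DataFrame(rows, columns=["intersection", "sets", "n"])
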