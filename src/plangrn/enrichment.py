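"""Motif, functional-category and OCR/gene-pair enrichment statistics.

All enrichment tests are upper-tail counting tests: hypergeometric for
motif hits in region sets (foreground regions vs a disjoint background),
one-sided Fisher for functional categories, and hypergeometric for
OCR/gene module pairs.  Multiple testing is controlled per unit with
Benjamini-Hochberg; motif significance uses q < 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GenomicIntervalSet

MOTIF_Q_THRESHOLD = 0.1


def _bh(p: np.ndarray) -> np.ndarray:
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    fg_ids: list[str],
    bg_ids: list[str],
    hit_table: pd.DataFrame,
    q_threshold: float = MOTIF_Q_THRESHOLD,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of motif hits in a region set.

    The background must exclude the foreground (it is constructed that way:
    regions of every other unit).  For each motif, with N = fg + bg regions,
    K regions carrying the motif and n = |fg|, p = P[X >= fg_hits].
    Motifs with zero hits anywhere are retained with p = 1.
    """
    fg = set(fg_ids)
    bg = set(bg_ids)
    if fg & bg:
        raise ValueError("foreground and background overlap")
    relevant = hit_table[hit_table["region_id"].isin(fg | bg)]
    motifs = sorted(hit_table["motif_id"].unique())
    hits_by_motif = {
        m: set(g["region_id"]) for m, g in relevant.groupby("motif_id")
    }
    N, n = len(fg) + len(bg), len(fg)
    rows = []
    for motif in motifs:
        carriers = hits_by_motif.get(motif, set())
        K = len(carriers)
        x = len(carriers & fg)
        p = 1.0 if K == 0 else float(hypergeom.sf(x - 1, N, K, n))
        fg_frac = x / n if n else 0.0
        bg_frac = (K - x) / len(bg) if bg else 0.0
        fold = fg_frac / bg_frac if bg_frac > 0 else np.inf if fg_frac > 0 else np.nan
        rows.append((motif, x, n, K - x, len(bg), fold, p))
    out = pd.DataFrame(
        rows, columns=["term", "fg_hits", "fg_total", "bg_hits", "bg_total", "fold", "p"]
    )
    out["q"] = _bh(out["p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out


def motif_enrichment_by_unit(
    unit_regions: dict[str, list[str]],
    all_regions: list[str],
    hit_table: pd.DataFrame,
    q_threshold: float = MOTIF_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-unit (module) motif enrichment with the unit's regions as
    foreground and every region of other units as background."""
    universe = set(all_regions)
    tables = []
    for unit, regions in sorted(unit_regions.items()):
        fg = [r for r in regions if r in universe]
        bg = sorted(universe - set(fg))
        tab = hypergeometric_enrichment(fg, bg, hit_table, q_threshold)
        tab.insert(0, "unit", unit)
        tables.append(tab)
    if not tables:
        return pd.DataFrame(
            columns=["unit", "term", "fg_hits", "fg_total", "bg_hits",
                     "bg_total", "fold", "p", "q", "significant"]
        )
    return pd.concat(tables, ignore_index=True)


def functional_enrichment(
    set_ids: list[str],
    universe: list[str],
    gene2term: pd.DataFrame,
    min_term_size: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotation terms in a gene set.

    Terms annotated to fewer than ``min_term_size`` genes in the universe
    are discarded.  ``gene2term`` has columns gene_id, term.
    """
    uni = set(universe)
    gs = set(set_ids) & uni
    ann = gene2term[gene2term["gene_id"].isin(uni)]
    rows = []
    for term, grp in ann.groupby("term"):
        term_genes = set(grp["gene_id"])
        if len(term_genes) < min_term_size:
            continue
        a = len(gs & term_genes)
        b = len(gs) - a
        c = len(term_genes) - a
        d = len(uni) - len(gs) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        fold = (
            (a / len(gs)) / (len(term_genes) / len(uni))
            if len(gs) and len(term_genes)
            else np.nan
        )
        rows.append((term, a, len(gs), c, len(uni) - len(gs), fold, float(p)))
    out = pd.DataFrame(
        rows, columns=["term", "fg_hits", "fg_total", "bg_hits", "bg_total", "fold", "p"]
    )
    out["q"] = _bh(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def nearest_tss(
    ocrs: GenomicIntervalSet, tss: GenomicIntervalSet
) -> "OCRGeneMap":
    """Assign each OCR its single closest TSS with a reference-signed distance.

    Distance is 0 when the TSS anchor lies inside the OCR; positive when
    the TSS is to the right of the OCR end, negative when it is to the left
    of the OCR start (reference orientation, strand-agnostic).  Ties go to
    the lower-coordinate TSS.  Distances are invariant under translating
    all coordinates.
    """
    rows = []
    tss_by_chrom = {
        chrom: grp.sort_values(["start", "id"], kind="mergesort")
        for chrom, grp in tss.df.groupby("chrom")
    }
    for _, ocr in ocrs.df.iterrows():
        cand = tss_by_chrom.get(ocr["chrom"])
        if cand is None or not len(cand):
            continue
        anchors = cand["start"].to_numpy()
        d = np.where(
            anchors < ocr["start"],
            anchors - ocr["start"],
            np.where(anchors >= ocr["end"], anchors - ocr["end"], 0),
        )
        absd = np.abs(d)
        best = int(np.flatnonzero(absd == absd.min())[0])  # lower coordinate wins
        rows.append((ocr["id"], cand["id"].iloc[best], int(d[best])))
    df = pd.DataFrame(rows, columns=["ocr_id", "gene_id", "distance"])
    return OCRGeneMap(df)


class OCRGeneMap:
    """ocr_id -> (gene_id, signed distance); exactly one gene per OCR."""

    def __init__(self, df: pd.DataFrame) -> None:
        if df["ocr_id"].duplicated().any():
            raise ValueError("an OCR maps to more than one gene")
        self.df = df.reset_index(drop=True)

    def gene_of(self) -> pd.Series:
        return self.df.set_index("ocr_id")["gene_id"]


def ocr_gene_pair_enrichment(
    gene_modules: pd.Series,  # gene -> module
    ocr_modules: pd.Series,  # ocr -> module
    ocr2gene: pd.Series,  # ocr -> gene
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of matched OCR/gene module pairs.

    The universe is the set of mapped (OCR, gene) pairs whose OCR and gene
    both carry a module label.  For a gene module G and OCR module O,
    x = #pairs with OCR in O and its gene in G; p = P[X >= x] under the
    hypergeometric null.  q values are BH-adjusted across all cells.
    """
    pairs = pd.DataFrame({"ocr": ocr2gene.index, "gene": ocr2gene.values})
    pairs["om"] = pairs["ocr"].map(ocr_modules)
    pairs["gm"] = pairs["gene"].map(gene_modules)
    pairs = pairs.dropna(subset=["om", "gm"])
    N = len(pairs)
    rows = []
    for gm, gm_grp in pairs.groupby("gm"):
        for om, om_grp in pairs.groupby("om"):
            n = len(om_grp)
            K = len(gm_grp)
            x = int(((pairs["om"] == om) & (pairs["gm"] == gm)).sum())
            p = 1.0 if n == 0 or K == 0 else float(hypergeom.sf(x - 1, N, K, n))
            rows.append((gm, om, x, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["gene_module", "ocr_module", "n_pairs", "gene_module_pairs",
                       "ocr_module_pairs", "total_pairs", "p"]
    )
    out["q"] = _bh(out["p"].to_numpy())
    return out


def motif_module_profile(enrichment_table: pd.DataFrame) -> pd.DataFrame:
    """Motif x unit matrix of foreground hit fractions (the enrichment
    profile correlated against TF connectivity)."""
    tab = enrichment_table.copy()
    tab["frac"] = tab["fg_hits"] / tab["fg_total"].where(tab["fg_total"] > 0, 1)
    return tab.pivot_table(index="term", columns="unit", values="frac", fill_value=0.0)


def connectivity_motif_agreement(
    connectivity: pd.DataFrame,  # TF x module
    motif_profiles: pd.DataFrame,  # motif x module (hit fractions)
    tf2motif: dict[str, str],
) -> pd.DataFrame:
    """Pearson r between each TF's per-module connectivity and its motif's
    per-module enrichment profile.  Constant profiles give NaN."""
    common = [m for m in connectivity.columns if m in motif_profiles.columns]
    rows = []
    for tf, motif in sorted(tf2motif.items()):
        if tf not in connectivity.index or motif not in motif_profiles.index:
            continue
        x = connectivity.loc[tf, common].to_numpy(float)
        y = motif_profiles.loc[motif, common].to_numpy(float)
        if np.isnan(x).any() or x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append((tf, motif, r))
    return pd.DataFrame(rows, columns=["tf", "motif", "r"])
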