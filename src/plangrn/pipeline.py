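"""End-to-end pipeline stages over an output directory.

Each stage reads the plain-text outputs of earlier stages, runs the
corresponding library operations, and writes TSV outputs with stable
ordering so repeated seeded runs are byte-identical.  The command-line
front end and the analysis drivers are thin wrappers around these
functions.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, grn, io, knockdown, module_graph, pseudobulk, simulate, wgcna

log = logging.getLogger(__name__)


def _truth_tables(truth: simulate.GroundTruth) -> dict[str, pd.DataFrame]:
    g2m = pd.DataFrame(
        sorted(truth.gene2module.items()), columns=["gene_id", "module"]
    )
    tfs = pd.DataFrame(
        [
            (tf, truth.tf_gene_of.get(tf, ""), truth.tf2motif[tf], truth.tf2module[tf] or "")
            for tf in sorted(truth.tf2motif)
        ],
        columns=["tf_id", "gene_id", "motif_id", "module"],
    )
    o2m = pd.DataFrame(
        sorted(truth.ocr2module.items()), columns=["ocr_id", "module"]
    )
    targets = pd.DataFrame(
        [
            (tf, g)
            for tf in sorted(truth.tf2targets)
            for g in truth.tf2targets[tf]
        ],
        columns=["tf_id", "gene_id"],
    )
    return {"gene_modules": g2m, "tfs": tfs, "ocr_modules": o2m, "tf_targets": targets}


def synthetic_gene2term(
    truth: simulate.GroundTruth, n_background_terms: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Functional annotation with one term per planted module plus random
    background terms over all genes."""
    rng = np.random.default_rng(seed)
    genes = list(truth.expected_mean.index)
    rows = [
        (g, f"term_{mod}")
        for mod, members in sorted(truth.module_members.items())
        for g in members
    ]
    # shared biology across modules of a supergroup: one term per pair of
    # modules whose planted programmes overlap (same driving cell types)
    mods = sorted(truth.module_members)
    types_of = {}
    for mod, members in truth.module_members.items():
        sub = truth.expected_mean.loc[list(members)]
        peak = sub.div(sub.max(axis=1), axis=0) > 0.5
        types_of[mod] = set(peak.columns[peak.mean(axis=0) > 0.5])
    for i, a in enumerate(mods):
        for b in mods[i + 1 :]:
            if types_of[a] & types_of[b]:
                for g in list(truth.module_members[a]) + list(truth.module_members[b]):
                    rows.append((g, f"term_shared_{a}_{b}"))
    for t in range(n_background_terms):
        size = int(rng.integers(5, 60))
        for g in rng.choice(genes, size=size, replace=False):
            rows.append((g, f"term_bg{t:02d}"))
    return pd.DataFrame(sorted(rows), columns=["gene_id", "term"])


def stage_simulate(out: Path, config: simulate.SyntheticConfig) -> None:
    out = Path(out)
    rna, truth = simulate.generate_expression(config)
    atac, ocrs, tss, motif_hits = simulate.generate_accessibility(config, truth)
    kd = simulate.generate_knockdown(config, truth)
    io.write_mtx_bundle(rna, out / "rna")
    io.write_mtx_bundle(atac, out / "atac")
    io.write_mtx_bundle(kd, out / "knockdown")
    io.write_bed(ocrs, out / "ocrs.bed")
    io.write_bed(tss, out / "tss.bed")
    io.write_tsv(motif_hits.sort_values(["region_id", "motif_id"]), out / "motif_hits.tsv", index=False)
    io.write_tsv(synthetic_gene2term(truth, seed=config.seed), out / "gene2term.tsv", index=False)
    for name, df in _truth_tables(truth).items():
        io.write_tsv(df, out / f"truth_{name}.tsv", index=False)
    io.write_tsv(truth.ocr2gene, out / "truth_ocr2gene.tsv", index=False)
    kd_spec = config.knockdown_spec
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "tf_id": kd_spec.tf_id,
                    "affected_cell_types": ",".join(kd_spec.affected_cell_types),
                    "target_suppression_factor": kd_spec.target_suppression_factor,
                    "abundance_reduction": kd_spec.abundance_reduction,
                    "n_replicates": kd_spec.n_replicates,
                }
            ]
        ),
        out / "truth_knockdown.tsv",
        index=False,
    )


def stage_pseudobulk(out: Path, keys: tuple[str, ...] = ("cluster",)) -> None:
    out = Path(out)
    for modality in ("rna", "atac"):
        acm = io.read_mtx_bundle(out / modality)
        wpb = pseudobulk.weighted_pseudobulk(acm, keys)
        pref = out / f"pseudobulk_{modality}"
        io.write_tsv(wpb.counts, pref.with_suffix(".counts.tsv"))
        io.write_tsv(wpb.w, pref.with_suffix(".weights.tsv"))
        io.write_tsv(wpb.size_factors.to_frame(), pref.with_suffix(".size_factors.tsv"))
        io.write_tsv(wpb.normalized_weighted, pref.with_suffix(".normalized.tsv"))
    kd = io.read_mtx_bundle(out / "knockdown")
    sm = pseudobulk.supermatrix(kd, ("cluster", "condition", "replicate"))
    io.write_tsv(sm, out / "supermatrix_knockdown.tsv")
    rna = io.read_mtx_bundle(out / "rna")
    sm_rna = pseudobulk.supermatrix(rna, ("cluster", "library"))
    io.write_tsv(sm_rna, out / "supermatrix_rna.tsv")


def _load_normalized(out: Path, modality: str) -> pd.DataFrame:
    return pd.read_csv(
        Path(out) / f"pseudobulk_{modality}.normalized.tsv", sep="\t", index_col=0
    )


def stage_modules(
    out: Path,
    mode: str = "expression",
    params: wgcna.WGCNAParams | None = None,
    overrides: dict | None = None,
) -> None:
    """Module detection: mode expression (soft power 8, min size 50) or
    ocr-all (power 7, min size 100) / ocr-da (power 8, min size 30);
    ``overrides`` patches individual fields of the mode preset."""
    out = Path(out)
    presets = {
        "expression": wgcna.WGCNAParams(beta=8, min_module_size=50, linkage_method="average"),
        "ocr-all": wgcna.WGCNAParams(beta=7, min_module_size=100, linkage_method="ward", cv_min=0.0),
        "ocr-da": wgcna.WGCNAParams(beta=8, min_module_size=30, linkage_method="ward", cv_min=0.0),
    }
    params = params or presets[mode]
    if overrides:
        params = dataclasses.replace(params, **overrides)
    modality = "rna" if mode == "expression" else "atac"
    prefix = "E" if mode == "expression" else "O"
    normalized = _load_normalized(out, modality)
    assignment, avg, rel, _tom = wgcna.expression_modules(normalized, params, prefix)
    tag = mode.replace("-", "_")
    io.write_tsv(assignment.table, out / f"modules_{tag}.assignment.tsv")
    io.write_tsv(avg, out / f"modules_{tag}.avg_profile.tsv")
    io.write_tsv(rel, out / f"modules_{tag}.rel_profile.tsv")
    io.write_tsv(
        wgcna.tau_table(normalized).to_frame(), out / f"modules_{tag}.tau.tsv"
    )
    if mode == "expression":
        tfs = pd.read_csv(out / "truth_tfs.tsv", sep="\t")
        tf_genes = [g for g in tfs["gene_id"] if g in normalized.index]
        conn = wgcna.tf_connectivity(normalized.loc[tf_genes], avg)
        conn.index = [
            tfs.set_index("gene_id")["tf_id"].get(g, g) for g in conn.index
        ]
        io.write_tsv(conn, out / "tf_connectivity.tsv")


def _module_members_from_table(table: pd.DataFrame) -> dict[str, list[str]]:
    assigned = table[table["module"] != "unassigned"]
    return {
        m: sorted(grp.index) for m, grp in assigned.groupby("module")
    }


def stage_enrich(out: Path, kind: str = "motif") -> None:
    out = Path(out)
    hits = pd.read_csv(out / "motif_hits.tsv", sep="\t")
    if kind == "motif":
        table = pd.read_csv(out / "modules_expression.assignment.tsv", sep="\t", index_col=0)
        members = _module_members_from_table(table)
        unit_regions = {
            m: [f"prom_{g}" for g in genes] for m, genes in members.items()
        }
        all_regions = [f"prom_{g}" for g in table.index]
        res = enrichment.motif_enrichment_by_unit(unit_regions, all_regions, hits)
        io.write_tsv(res, out / "enrich_motif_expression.tsv", index=False)
    elif kind == "motif-ocr":
        table = pd.read_csv(out / "modules_ocr_all.assignment.tsv", sep="\t", index_col=0)
        members = _module_members_from_table(table)
        all_regions = list(table.index)
        res = enrichment.motif_enrichment_by_unit(members, all_regions, hits)
        io.write_tsv(res, out / "enrich_motif_ocr.tsv", index=False)
    elif kind == "function":
        table = pd.read_csv(out / "modules_expression.assignment.tsv", sep="\t", index_col=0)
        gene2term = pd.read_csv(out / "gene2term.tsv", sep="\t")
        universe = list(table.index)
        frames = []
        for m, members in sorted(_module_members_from_table(table).items()):
            res = enrichment.functional_enrichment(members, universe, gene2term)
            res.insert(0, "unit", m)
            frames.append(res)
        io.write_tsv(pd.concat(frames, ignore_index=True), out / "enrich_function.tsv", index=False)
    elif kind == "pairs":
        gtab = pd.read_csv(out / "modules_expression.assignment.tsv", sep="\t", index_col=0)
        otab = pd.read_csv(out / "modules_ocr_all.assignment.tsv", sep="\t", index_col=0)
        o2g = pd.read_csv(out / "truth_ocr2gene.tsv", sep="\t")
        res = enrichment.ocr_gene_pair_enrichment(
            gtab.loc[gtab["module"] != "unassigned", "module"],
            otab.loc[otab["module"] != "unassigned", "module"],
            o2g.set_index("ocr_id")["gene_id"],
        )
        io.write_tsv(res, out / "enrich_pairs.tsv", index=False)
    else:
        raise ValueError(f"unknown enrichment kind '{kind}'")


def stage_graph(out: Path, seed: int = 0, layer_threshold: float = 0.5) -> None:
    out = Path(out)
    normalized = _load_normalized(out, "rna")
    table = pd.read_csv(out / "modules_expression.assignment.tsv", sep="\t", index_col=0)
    members = _module_members_from_table(table)
    assignment = table.loc[table["module"] != "unassigned", "module"]

    params = wgcna.WGCNAParams()
    filtered = wgcna.filter_by_cv(normalized, params.cv_min)
    scaled = wgcna.scale_rows(filtered)
    tom_m = wgcna.tom(wgcna.adjacency(scaled, params.beta))
    thr, gene_graph = module_graph.prune_tom_graph(tom_m)
    cross = module_graph.cross_connections(gene_graph, assignment)

    motif = pd.read_csv(out / "enrich_motif_expression.tsv", sep="\t")
    motif_prof = enrichment.motif_module_profile(motif[motif["significant"]])
    func = pd.read_csv(out / "enrich_function.tsv", sep="\t")
    func["frac"] = func["fg_hits"] / func["fg_total"].where(func["fg_total"] > 0, 1)
    func_prof = func.pivot_table(index="term", columns="unit", values="frac", fill_value=0.0)
    conn = pd.read_csv(out / "tf_connectivity.tsv", sep="\t", index_col=0)

    layers = [
        (cross > 0).astype(float),
        module_graph.correlation_layer(motif_prof.T, layer_threshold),
        module_graph.correlation_layer(func_prof.T, layer_threshold),
        module_graph.correlation_layer(conn.T, layer_threshold),
    ]
    consensus = module_graph.consensus_merge(layers, min_support=2)
    comms = module_graph.communities_label_propagation(consensus, seed=seed)

    edges = pd.DataFrame(
        [
            (u, v, d["weight"], ",".join(map(str, d["layers"])))
            for u, v, d in sorted(consensus.edges(data=True))
        ],
        columns=["node1", "node2", "support", "layers"],
    )
    io.write_tsv(edges, out / "module_graph_edges.tsv", index=False)
    io.write_tsv(comms.to_frame(), out / "module_graph_communities.tsv")

    for modality in ("rna", "atac"):
        mat = _load_normalized(out, modality)
        freq, Z = module_graph.ensemble_cooccurrence_tree(
            mat, n=200, seed=seed
        )
        io.write_tsv(freq, out / f"cooccurrence_{modality}.tsv")
        (out / f"cooccurrence_{modality}.nwk").write_text(
            module_graph.linkage_to_newick(Z, list(freq.index)) + "\n"
        )
    log.info("TOM graph threshold %.3f", thr)


def _grn_inputs(out: Path):
    acc = pd.read_csv(out / "pseudobulk_atac.normalized.tsv", sep="\t", index_col=0)
    expr = _load_normalized(out, "rna")
    hits = pd.read_csv(out / "motif_hits.tsv", sep="\t")
    o2g = pd.read_csv(out / "truth_ocr2gene.tsv", sep="\t")
    tfs = pd.read_csv(out / "truth_tfs.tsv", sep="\t")
    tf2motif = dict(zip(tfs["tf_id"], tfs["motif_id"]))
    tf_gene = dict(zip(tfs["tf_id"], tfs["gene_id"]))
    return acc, expr, hits, o2g, tf2motif, tf_gene


def build_fate_network(
    out: Path, fate: str, params: grn.BindingParams = grn.BindingParams()
) -> pd.DataFrame:
    """Interaction network for one cell type from the pseudobulk data on
    disk.  TF expression is looked up through the TF gene table."""
    out = Path(out)
    acc, expr, hits, o2g, tf2motif, tf_gene = _grn_inputs(out)
    binding = grn.weighted_binding(hits, acc[fate], o2g, tf2motif, params)
    # expression of a TF is the expression of its gene
    expr_fate = expr[fate].copy()
    for tf, gene in tf_gene.items():
        expr_fate[tf] = expr[fate].get(gene, 0.0)
    net = grn.interaction_scores(binding, expr_fate)
    net["fate"] = fate
    return net


def stage_grn(out: Path, fates: list[str] | None = None, origin: str = "neoblast") -> None:
    out = Path(out)
    expr = _load_normalized(out, "rna")
    fates = fates or [c for c in expr.columns if c != origin]
    nets = {}
    for fate in fates:
        net = build_fate_network(out, fate)
        nets[fate] = net
        io.write_tsv(
            net[net["score"] > 0.8].sort_values(["tf", "target"]),
            out / f"grn_network_{fate}.tsv",
            index=False,
        )
    metrics = {}
    for fate, net in nets.items():
        graph = grn.prune_network(net)
        metrics[fate] = grn.network_metrics(graph)["centrality"]
    cent = pd.DataFrame(metrics).fillna(0.0)
    io.write_tsv(cent, out / "grn_centrality.tsv")

    # influence for each stem-cell -> fate transition
    sm_rna = pd.read_csv(out / "supermatrix_rna.tsv", sep="\t", index_col=0)
    tf_table = pd.read_csv(out / "truth_tfs.tsv", sep="\t")
    tf_gene = dict(zip(tf_table["tf_id"], tf_table["gene_id"]))
    influence = {}
    for fate, net in nets.items():
        try:
            spec = differential.build_one_vs_neoblast(sm_rna, fate, origin)
            dge_res = differential.nb_wald_test(sm_rna, spec)
        except ValueError as exc:
            log.warning("influence for %s skipped: %s", fate, exc)
            continue
        infl = grn.influence_scores(net, dge_res, tf_gene=tf_gene)
        influence[fate] = infl["influence"]
    if influence:
        infl_matrix = pd.DataFrame(influence).fillna(0.0).sort_index()
        io.write_tsv(infl_matrix, out / "grn_influence.tsv")
        clusters = grn.coinfluence_clusters(infl_matrix)
        io.write_tsv(clusters, out / "grn_coinfluence_clusters.tsv", index=False)


def stage_dge(out: Path, clusters: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Knockdown-vs-control NB Wald tests per cluster on the supermatrix."""
    out = Path(out)
    sm_counts = pd.read_csv(out / "supermatrix_knockdown.tsv", sep="\t", index_col=0)
    meta_clusters = sorted({c.split(differential.GROUP_SEP)[0] for c in sm_counts.columns})
    clusters = clusters or meta_clusters
    results = {}
    for cluster in clusters:
        try:
            spec = differential.build_condition_contrast(sm_counts, cluster)
            res = differential.nb_wald_test(sm_counts, spec)
        except ValueError as exc:
            log.warning("skipping cluster %s: %s", cluster, exc)
            continue
        results[cluster] = res
        io.write_tsv(res, out / f"dge_knockdown_{cluster}.tsv")
    return results


def stage_report(out: Path, seed: int = 0) -> dict[str, object]:
    """Knockdown evaluation: abundance residuals, gene scores, DEG overlap."""
    out = Path(out)
    kd = io.read_mtx_bundle(out / "knockdown")
    counts = (
        kd.obs.groupby(["cluster", "condition"]).size().unstack(fill_value=0)
    )
    stat, p, resid = knockdown.abundance_chisq(counts)
    io.write_tsv(resid, out / "report_abundance_residuals.tsv", index=False)

    targets = pd.read_csv(out / "truth_tf_targets.tsv", sep="\t")
    kd_info = pd.read_csv(out / "truth_knockdown.tsv", sep="\t")
    kd_tf = kd_info["tf_id"].iloc[0] if len(kd_info) else None
    score = None
    if kd_tf is not None:
        gene_set = list(targets.loc[targets["tf_id"] == kd_tf, "gene_id"])
        score = knockdown.gene_score(kd, gene_set, seed=seed)
        io.write_tsv(score.to_frame(), out / "report_gene_scores.tsv")
    return {"chisq": stat, "p": p, "residuals": resid, "gene_score": score}
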