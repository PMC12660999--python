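# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Weighted pseudobulk

Counts are summed per group (cluster, optionally × condition ×
replicate). The expression constraint `w_ij = 1 − exp(−a_ij/b_ij)`
down-weights genes whose counts are scattered among a small fraction of a
large cluster relative to the fraction of expressing cells elsewhere.
Conventions at the boundary: `a = 0 → w = 0` (no signal in the group) and
`b = 0, a > 0 → w = 1` (the only continuous completion of the formula).
Filters: genes with fewer than 30 total counts are dropped; entries
supported by fewer than 3 expressing cells of the group are zeroed in the
weight matrix — an entry rule, not gene removal, because the rule's
purpose is to gate per-cluster expression information. Size factors are
DESeq-style median-of-ratios over genes positive in every column
(column-sum fallback, logged); the gene filter runs first, then factors
are estimated, then the normalised matrix is multiplied by `w` (in that
order).

## Module detection

Expression profiles keep rows with CV = sd/mean > 1.25 (population sd:
a one-hot profile over K groups then has CV = √(K−1)); the OCR variants
skip the CV filter, as their protocol does. Rows are z-scored, the
unsigned adjacency is `|r|^β` (β = 8 expression, 7 all-OCR, 8
differentially-accessible-OCR; a scale-free-fit scan across β = 1..20 is
available), and the TOM is

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_{u≠i,j} a_iu a_uj ,  TOM_ii = 1.

The tree on 1 − TOM (average linkage for expression, Ward for OCRs) is
cut by a simplified, deterministic branch decomposition in place of the
full hybrid dynamic-cut algorithm: a dendrogram node qualifies as a
module branch when it holds ≥ `min_module_size` leaves (50 / 100 / 30 per
variant) and its parent merges at a height exceeding the node's own top
merge by ≥ `min_branch_gap` (default 0.1) × total tree height; each leaf
is assigned to its smallest qualifying ancestor, residual fragments below
the size floor stay unassigned (the "grey" convention). The gap
criterion keeps cohesive branches whole (their internal merges form a
continuum) while refusing arbitrary slices of background noise (whose
merges also form a continuum near the root). A plain height sweep was
tried first and merged modules with overlapping member-type sets; the
branch decomposition separates them and is validated by planted-partition
recovery (ARI = 1 on the default conditions).

Classification: per module, the upper quartile (linear interpolation) of
member-gene expression per group; groups above mean + 1.5·sd (sample sd)
of that distribution are outliers; exactly one outlier → "s", otherwise
"m" — including zero outliers, since the single-peak label requires
positive evidence. Modules are renamed s/m + modality letter + index,
ordered by the position of their peak group in the fixed group ordering,
ties broken by decreasing size. τ = Σ(1 − x_i/max x)/(n−1). TF–module
connectivity is the Pearson correlation of the TF's pseudobulk profile
with the module average profile.

## Enrichment

Motif enrichment per module: foreground = the module's promoters (or
OCRs), background = the corresponding regions of all other modules
(disjoint by construction), upper-tail hypergeometric on region counts,
BH within module, significance at q < 0.1. No background subsampling:
it would only reduce power. Functional enrichment: one-sided Fisher,
terms with ≥ 5 annotated genes in the universe. OCR→gene: single nearest
TSS by |distance| with a reference-signed distance (0 on overlap,
negative when the TSS lies left of the OCR), ties to the lower
coordinate. OCR/gene module pairs: upper-tail hypergeometric over the
universe of labelled mapped pairs, BH across cells. The "upper-tail
geometric" wording of the protocol this follows is read as
hypergeometric — the sampling-without-replacement null is the one the
counting scheme implies.

## Module graph

Gene-level TOM graph pruned at the threshold maximising
C(t)·(1 − Gini(component sizes)) over components with ≥ 2 nodes (ties to
the larger threshold) — "many, evenly sized components" made explicit.
Cross-connections: neighbour counts per module divided by the source
module's size, summed, upper-triangle merged. Three correlation layers
(motif-enrichment profiles, functional profiles, TF-connectivity
profiles) keep edges at r ≥ 0.5 — a free parameter chosen so that
planted supergroup modules are connected; exposed in config. Consensus
keeps edges in ≥ 2 of the 4 layers, weight = support count; communities
by weighted asynchronous label propagation with a fixed seed. The
ensemble co-occurrence tree subsamples ⌈5% of features⌉ per iteration
(n = 1000 by default; the pipeline stage uses 200, which is converged to
< 0.05 in max norm on these data), computes Pearson-distance
average-linkage trees, cuts at heights 0.75 and 0.9, counts co-clustered
group pairs, and builds the consensus tree by average linkage on
1 − frequency.

## GRN inference

A transparent additive instantiation of expression + accessibility
network scoring. Binding: `B_tg = Σ acc_type(o)·exp(−|d(o,g)|/λ)` over
OCRs carrying the TF's motif within W of the gene's TSS; defaults
W = 100 kb, λ = 25 kb (config-exposed; on the synthetic 20 kb gene
spacing the kernel is effectively local). Interaction score: mean of
four rank components, each min–max scaled to [0,1] across the network —
TF expression (over TFs), target expression (over genes), binding (over
all pairs), TF activity = mean binding (over TFs). Pruning is strictly
score > 0.8; metrics include in/out-degree, relative outdegree
out/(in+out) (the literal in/(in+out) variant sits behind a flag, since
the protocol text names one and defines the other), and PageRank
centrality on edge scores (out-centrality on the reversed graph).
Influence mixes the TF's own upward expression change and its scored
targeting of significantly upregulated genes 50/50 after min–max scaling;
rankings are invariant to uniformly rescaling log2FCs. Co-influence:
Ward tree on 1 − Pearson of influence profiles cut at 0.7, top 5 TFs per
cluster by correlation to the cluster mean.

## Negative-binomial differential testing

Genes with zero counts in ≥ 2 samples are dropped. Size factors:
median-of-ratios. Dispersion: the parametric trend α(µ) = a0 + a1/µ is
fit by pooled weighted least squares of (v − m) on (m² − v/n, m) across
genes — the regressor m² − v/n is the unbiased estimate of µ², removing
the errors-in-variables attenuation of a0 — with variance weights
1/σ⁴ iterated three times; fallback to the median of per-gene moment
estimates below 10 usable genes. Per-gene moment estimates are mostly
noise at the 2–5 replicates pseudobulk designs offer, so the default
shrinkage weight on the trend is 1.0; weights < 1 re-admit per-gene
moments banded into [trend/8, 8·trend] so that genes whose sample
variance undershoots the mean cannot yield inflated statistics. The GLM
is an NB log-link fit (IRLS via statsmodels) with log size factors as
offset; Wald z on the condition coefficient, BH adjustment, DEG at
padj < 0.05 (a p < 0.05 option exists for the per-cell-type knockdown
analyses). Simplifications relative to the full DESeq2 machinery — no
Cox–Reid adjusted ML dispersion, no LFC shrinkage, no Cook's filtering,
no independent filtering — are deliberate; the validation surface is
simulation-calibrated error: on 3-vs-3 null data drawn from one NB
population, the type-I error at α = 0.05 is 0.053 ± binomial across
seeds (the oracle-dispersion floor is 0.050), and balanced planted
|log2FC| = 2 effects are recovered to within ±0.3. Under strongly
heterogeneous per-gene dispersion the trend-only default is mildly
anticonservative (~0.06), the known cost of trend-based dispersion.

## Knockdown evaluation

Gene score per cell: mean library-size-normalised expression over the
gene set minus the mean over a random ⌈5%·G⌉ gene subsample, then
z-normalised across cells (the normalisation is config-exposed; "none"
skips it). Abundance: omnibus Pearson chi-squared plus adjusted
standardized residuals (O−E)/√(E(1−row/N)(1−col/N)), starred at the
two-sided normal quantiles 1.96 (p < .05) and 2.58 (p < .01). Overlap
percentages round to the nearest integer of the union. The logistic
detection model (DEG ~ interaction score) flags perfect separation
instead of reporting a divergent slope as significant.

## Synthetic study conditions

Defaults emulate a whole-organism multiome experiment at desk scale: 10
cell types with skewed abundances (70–700 cells; ~3,000 scRNA cells
total), 2,000 genes, four single-type and six two-type modules of 60
genes at 8-fold elevation, 16 TFs (one driver per module plus 6
background TFs), 1,300 OCRs (110 per module, width 200 bp, within 5 kb
of member-gene TSSs on a 40 Mb linear pseudo-chromosome, one gene per
locus, TSS = interval start), NB dispersion 0.3 via gamma–Poisson,
log-normal per-cell library factors (σ = 0.35), background motif rate
0.02, and a two-replicate knockdown of the phagocyte/parenchyma driver
(target suppression to 0.3×, 50% abundance reduction, knockdown cell
numbers at half the atlas scale). Choices worth flagging:

* **Depletion outside member types.** Module genes are multiplied by
  fold^(−0.5) outside their member types — cell-type-specific genes are
  essentially off elsewhere in real data. Without this, two-type module
  genes sit below the CV > 1.25 filter at pseudobulk level; with a fold
  of 1 the genes remain exactly flat, preserving the null case.
* **Two-type multi modules.** The s/m outlier rule is mathematically
  indecisive for modules spanning ~30% of the groups (the threshold
  converges onto the member value), so multi-type modules span exactly
  two of the ten types; the two supergroups (phagocytes/basal-goblet/
  parenchyma and muscle/neurons/secretory) arise from overlapping pairs,
  which is also how the real catalogues express them across many narrow
  clusters.
* **Shared regulatory signal.** Modules sharing a member type also share
  signal: the driving TF's motif marks 40% of the overlapping module's
  promoters and OCRs, and each overlapping module pair shares a
  functional term. This is what makes the 2-of-4 consensus graph
  recover the supergroups, as the real data do through shared motifs,
  functions and TF connectivity.
* **TF profiles.** TF transcripts follow their module's mean profile
  with log-normal per-type jitter (σ = 0.4), so kME-style connectivity
  is high but not exactly 1.

What passing tests do **not** show about real data: the generator has no
doublets, ambient RNA, batch effects beyond round-robin library labels,
overlapping module membership of single genes, strand structure, or
dispersion heterogeneity across genes; cluster labels are exact rather
than inferred. Recovery metrics on this generator certify the
correctness and calibration of the implementations, not field
performance on noisy atlases.

## Determinism

Every stochastic step takes an explicit seed (generator, pseudoreplicate
splits, label propagation, ensemble subsampling, gene-score subsample);
writers order rows deterministically, so repeated seeded runs are
byte-identical — asserted in the test suite at the file level.
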