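"""Synthetic multimodal single-cell data with planted ground truth.

The generator emulates the structure of a whole-organism multiome study of
stem-cell differentiation: a gene x cell UMI matrix over ~10 cell types with
skewed abundances, planted single-type and multi-type co-expression modules,
TFs co-expressed with their modules, OCRs co-accessible in member types and
placed near member-gene TSSs carrying the driving TF's motif, and a
two-condition replicated knockdown design in which one TF's targets are
suppressed in two of the cell types and those clusters shrink in abundance.

Counts are negative binomial via a gamma-Poisson mixture; per-cell library
size varies log-normally so size-factor estimation downstream is
non-trivial.  Everything is driven by a single integer seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AnnotatedCountMatrix, BED_COLUMNS, GenomicIntervalSet

# The two planted "supergroups" of differentiated types sharing regulatory
# logic: an endodermal-like trio and a neuro-muscular-secretory trio.
DEFAULT_CELL_TYPES = (
    "neoblast",
    "epidermis_early",
    "epidermis_late",
    "phagocytes",
    "basal_goblet",
    "parenchyma",
    "muscle",
    "neurons",
    "secretory",
    "protonephridia",
)

# Skewed abundances: stem cells and neurons dominate, rare types are rare.
DEFAULT_CELLS_PER_TYPE = (700, 280, 320, 260, 140, 240, 330, 520, 90, 70)


@dataclass(frozen=True)
class ModuleSpec:
    module_id: str
    member_cell_types: tuple[str, ...]
    n_genes: int
    fold_elevation: float

    def __post_init__(self) -> None:
        if not self.member_cell_types:
            raise ValueError(f"module {self.module_id}: empty member set")
        if self.n_genes < 1:
            raise ValueError(f"module {self.module_id}: n_genes must be positive")
        if self.fold_elevation <= 0:
            raise ValueError(f"module {self.module_id}: fold_elevation must be > 0")


@dataclass(frozen=True)
class KnockdownSpec:
    tf_id: str
    affected_cell_types: tuple[str, ...]
    target_suppression_factor: float
    abundance_reduction: float
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.target_suppression_factor <= 1:
            raise ValueError("target_suppression_factor must be in (0, 1]")
        if not 0 <= self.abundance_reduction < 1:
            raise ValueError("abundance_reduction must be in [0, 1)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def default_module_specs() -> list[ModuleSpec]:
    """Four single-type and six multi-type modules.

    The overlapping two-type modules knit the differentiated types into two
    supergroups with shared regulatory logic: an endodermal trio
    (phagocytes / basal-goblet / parenchyma) and a neuro-muscular-secretory
    trio, mirroring the grouping structure the downstream graph analyses
    are meant to recover.
    """
    return [
        ModuleSpec("M01", ("epidermis_late",), 60, 8.0),
        ModuleSpec("M02", ("neurons",), 60, 8.0),
        ModuleSpec("M03", ("muscle",), 60, 8.0),
        ModuleSpec("M04", ("protonephridia",), 60, 8.0),
        ModuleSpec("M05", ("phagocytes", "parenchyma"), 60, 8.0),
        ModuleSpec("M06", ("phagocytes", "basal_goblet"), 60, 8.0),
        ModuleSpec("M07", ("basal_goblet", "parenchyma"), 60, 8.0),
        ModuleSpec("M08", ("muscle", "neurons"), 60, 8.0),
        ModuleSpec("M09", ("neurons", "secretory"), 60, 8.0),
        ModuleSpec("M10", ("epidermis_early", "epidermis_late"), 60, 8.0),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic multiome experiment."""

    n_cell_types: int = len(DEFAULT_CELL_TYPES)
    cell_type_names: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_type: tuple[int, ...] = DEFAULT_CELLS_PER_TYPE
    n_genes: int = 2000
    module_specs: tuple[ModuleSpec, ...] = field(
        default_factory=lambda: tuple(default_module_specs())
    )
    n_tfs: int = 16  # one driver per module plus unassigned background TFs
    n_ocrs: int = 1300
    ocrs_per_module: int = 110
    nb_dispersion: float = 0.3
    base_mean: float = 1.0
    # module genes are depleted outside their member types by
    # fold_elevation ** (-exponent), emulating cell-type-specific genes
    # that are essentially off elsewhere; a fold of 1 stays exactly flat
    module_depletion_exponent: float = 0.5
    libsize_sigma: float = 0.35
    tf_profile_sigma: float = 0.4  # log-normal jitter on TF per-type means
    knockdown_spec: KnockdownSpec = field(
        default_factory=lambda: KnockdownSpec(
            tf_id="TF05",
            affected_cell_types=("phagocytes", "parenchyma"),
            target_suppression_factor=0.3,
            abundance_reduction=0.5,
            n_replicates=2,
        )
    )
    genome_span: int = 40_000_000
    ocr_width: int = 200
    ocr_tss_window: int = 5_000
    ocr_fold_elevation: float = 8.0
    ocr_base_mean: float = 1.0
    background_motif_rate: float = 0.02
    # modules sharing a member cell type also share regulators: the driving
    # TF's motif appears in this fraction of the overlapping module's
    # promoters/OCRs, knitting supergroup modules together
    shared_motif_fraction: float = 0.4
    atac_cells_fraction: float = 0.4
    kd_cells_factor: float = 0.5  # knockdown experiment is a smaller run
    n_libraries: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least two cell types")
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length must equal n_cell_types")
        if len(self.cells_per_type) != self.n_cell_types:
            raise ValueError("cells_per_type length must equal n_cell_types")
        if any(n < 1 for n in self.cells_per_type):
            raise ValueError("all cell counts must be positive")
        for spec in self.module_specs:
            missing = set(spec.member_cell_types) - set(self.cell_type_names)
            if missing:
                raise ValueError(f"module {spec.module_id}: unknown cell types {missing}")
        demand = sum(s.n_genes for s in self.module_specs) + self.n_tfs
        if demand > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than module + TF gene demand ({demand})"
            )
        if self.n_tfs < len(self.module_specs):
            raise ValueError("need at least one TF per module")
        kd = self.knockdown_spec
        missing = set(kd.affected_cell_types) - set(self.cell_type_names)
        if missing:
            raise ValueError(f"knockdown affected_cell_types not in cell types: {missing}")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")


@dataclass
class GroundTruth:
    """Planted structure: who belongs where and what the expected means are."""

    gene2module: dict[str, str]
    tf2module: dict[str, str | None]
    tf2motif: dict[str, str]
    tf2targets: dict[str, tuple[str, ...]]
    ocr2module: dict[str, str]
    ocr2gene: pd.DataFrame  # ocr_id, gene_id, signed distance
    expected_mean: pd.DataFrame  # gene x cell type
    module_members: dict[str, tuple[str, ...]]
    cell_types: tuple[str, ...]
    tf_gene_of: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _build_expected_means(config: SyntheticConfig, rng: np.random.Generator) -> GroundTruth:
    genes = _gene_ids(config.n_genes)
    base = np.exp(rng.normal(np.log(config.base_mean), 1.0, size=config.n_genes))
    mean = np.tile(base[:, None], (1, config.n_cell_types))
    type_index = {t: j for j, t in enumerate(config.cell_type_names)}

    gene2module: dict[str, str] = {}
    module_members: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for spec in config.module_specs:
        members = genes[cursor : cursor + spec.n_genes]
        cursor += spec.n_genes
        module_members[spec.module_id] = tuple(members)
        for g in members:
            gene2module[g] = spec.module_id
        cols = [type_index[t] for t in spec.member_cell_types]
        non_cols = [j for j in range(config.n_cell_types) if j not in cols]
        idx = np.arange(cursor - spec.n_genes, cursor)
        mean[np.ix_(idx, cols)] *= spec.fold_elevation
        mean[np.ix_(idx, non_cols)] *= spec.fold_elevation ** (
            -config.module_depletion_exponent
        )

    # TF genes follow their module's mean profile with per-type jitter so the
    # pseudobulk connectivity is high but not exactly 1 by construction.
    tf2module: dict[str, str | None] = {}
    tf2motif: dict[str, str] = {}
    tf2targets: dict[str, tuple[str, ...]] = {}
    tf_gene_of: dict[str, str] = {}
    module_list = [s.module_id for s in config.module_specs]
    for k in range(config.n_tfs):
        tf_id = f"TF{k + 1:02d}"
        gene = genes[cursor]
        cursor += 1
        tf_gene_of[tf_id] = gene
        tf2motif[tf_id] = f"MOT_{tf_id}"
        if k < len(module_list):
            mod = module_list[k]
            tf2module[tf_id] = mod
            tf2targets[tf_id] = module_members[mod]
            spec = config.module_specs[k]
            cols = [type_index[t] for t in spec.member_cell_types]
            non_cols = [j for j in range(config.n_cell_types) if j not in cols]
            row = genes.index(gene)
            mean[row, cols] *= spec.fold_elevation
            mean[row, non_cols] *= spec.fold_elevation ** (
                -config.module_depletion_exponent
            )
            jitter = np.exp(
                rng.normal(0.0, config.tf_profile_sigma, size=config.n_cell_types)
            )
            mean[row, :] *= jitter
        else:
            tf2module[tf_id] = None
            tf2targets[tf_id] = ()

    expected = pd.DataFrame(mean, index=genes, columns=list(config.cell_type_names))
    truth = GroundTruth(
        gene2module=gene2module,
        tf2module=tf2module,
        tf2motif=tf2motif,
        tf2targets=tf2targets,
        ocr2module={},
        ocr2gene=pd.DataFrame(columns=["ocr_id", "gene_id", "distance"]),
        expected_mean=expected,
        module_members=module_members,
        cell_types=tuple(config.cell_type_names),
        tf_gene_of=tf_gene_of,
    )
    return truth


def _nb_counts(
    mean: np.ndarray, dispersion: float, libfac: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw: counts ~ Poisson(Gamma(1/d, d) * mean * libfac)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion, size=(mean.shape[0], libfac.size)) * (
        mean[:, None] * libfac[None, :]
    )
    return rng.poisson(lam)


def _draw_cells(
    config: SyntheticConfig,
    truth: GroundTruth,
    cells_per_type: dict[str, int],
    mean_override: pd.DataFrame | None,
    rng: np.random.Generator,
    cell_prefix: str,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    means = truth.expected_mean if mean_override is None else mean_override
    blocks, ann_rows = [], []
    counter = 0
    for ctype in config.cell_type_names:
        n = cells_per_type[ctype]
        libfac = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
        counts = _nb_counts(means[ctype].to_numpy(), config.nb_dispersion, libfac, rng)
        blocks.append(sp.csr_matrix(counts))
        for _ in range(n):
            ann_rows.append((f"{cell_prefix}{counter:06d}", ctype))
            counter += 1
    matrix = sp.hstack(blocks, format="csr")
    ann = pd.DataFrame(ann_rows, columns=["cell_id", "cluster"]).set_index("cell_id")
    return matrix, ann


_BROAD_MAP = {"epidermis_early": "epidermis", "epidermis_late": "epidermis"}


def generate_expression(
    config: SyntheticConfig,
) -> tuple[AnnotatedCountMatrix, GroundTruth]:
    """Generate the control scRNA count matrix, cell annotation and truth."""
    rng = np.random.default_rng(config.seed)
    truth = _build_expected_means(config, rng)
    cells = dict(zip(config.cell_type_names, config.cells_per_type))
    matrix, ann = _draw_cells(config, truth, cells, None, rng, "cell_")
    ann["broad_type"] = [_BROAD_MAP.get(c, c) for c in ann["cluster"]]
    ann["library"] = [f"lib{1 + i % config.n_libraries}" for i in range(len(ann))]
    ann["condition"] = "control"
    ann["replicate"] = "r1"
    acm = AnnotatedCountMatrix(
        values=matrix.astype(np.int64),
        feature_ids=pd.Index(truth.expected_mean.index),
        cell_ids=pd.Index(ann.index),
        obs=ann,
    )
    return acm, truth


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------

def generate_accessibility(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[AnnotatedCountMatrix, GenomicIntervalSet, GenomicIntervalSet, pd.DataFrame]:
    """OCR x cell counts, OCR/TSS BED intervals and the motif-hit table.

    Genes occupy a single linear pseudo-chromosome, one per locus, TSS at
    interval start on the + strand.  Module OCRs are placed within
    ``ocr_tss_window`` of a member gene's TSS and carry the driving TF's
    motif; background OCRs are flat across types.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = list(truth.expected_mean.index)
    n_genes = len(genes)
    spacing = config.genome_span // (n_genes + 1)
    needed = 2 * config.ocr_tss_window + config.ocr_width + 2000
    if spacing < needed:
        raise ValueError(
            f"genome_span={config.genome_span} too small: need >= "
            f"{needed * (n_genes + 1)} bp to place genes and OCRs without overlap"
        )
    gene_start = {g: (i + 1) * spacing for i, g in enumerate(genes)}
    tss_rows = [
        ("chr1", gene_start[g], gene_start[g] + 1, g, 0, "+") for g in genes
    ]
    tss = GenomicIntervalSet(pd.DataFrame(tss_rows, columns=BED_COLUMNS))

    module_of_tf = {m: t for t, m in truth.tf2module.items() if m is not None}
    module_list = list(truth.module_members)
    n_module_ocrs = config.ocrs_per_module * len(module_list)
    if n_module_ocrs > config.n_ocrs:
        raise ValueError("n_ocrs smaller than module OCR demand")

    ocr_rows, ocr2module, motif_hits = [], {}, []
    # discrete non-overlapping slots around each TSS
    step = config.ocr_width + 50
    n_slots = max(1, config.ocr_tss_window // step)
    used_slots: set[tuple[str, int]] = set()

    def place_near(gene: str) -> tuple[int, int] | None:
        for slot in rng.permutation(2 * n_slots):
            key = (gene, int(slot))
            if key in used_slots:
                continue
            used_slots.add(key)
            # slots alternate upstream / downstream of the TSS
            offset = (slot // 2 + 1) * step * (1 if slot % 2 == 0 else -1)
            start = gene_start[gene] + offset
            if start < 0:
                continue
            return start, start + config.ocr_width
        return None

    k = 0
    for mod in module_list:
        members = truth.module_members[mod]
        tf = module_of_tf.get(mod)
        for _ in range(config.ocrs_per_module):
            gene = members[int(rng.integers(len(members)))]
            placed = place_near(gene)
            if placed is None:
                raise ValueError("could not place module OCR; genome_span too small")
            ocr_id = f"ocr{k:05d}"
            k += 1
            ocr_rows.append(("chr1", placed[0], placed[1], ocr_id, 0, "."))
            ocr2module[ocr_id] = mod
            if tf is not None:
                motif_hits.append((ocr_id, truth.tf2motif[tf], 1))
    # background OCRs near random genes, flat accessibility
    while k < config.n_ocrs:
        gene = genes[int(rng.integers(n_genes))]
        placed = place_near(gene)
        if placed is None:
            continue
        ocr_id = f"ocr{k:05d}"
        k += 1
        ocr_rows.append(("chr1", placed[0], placed[1], ocr_id, 0, "."))
    ocrs = GenomicIntervalSet(pd.DataFrame(ocr_rows, columns=BED_COLUMNS))

    # planted motifs in member-gene promoters; background hits everywhere
    for mod in module_list:
        tf = module_of_tf.get(mod)
        if tf is None:
            continue
        for gene in truth.module_members[mod]:
            motif_hits.append((f"prom_{gene}", truth.tf2motif[tf], 1))

    # shared regulators across modules with overlapping member types: the
    # driving motif of one module also marks a fraction of the other's
    # promoters and OCRs
    members_of = {s.module_id: set(s.member_cell_types) for s in config.module_specs}
    if config.shared_motif_fraction > 0:
        for mod_a in module_list:
            tf_a = module_of_tf.get(mod_a)
            if tf_a is None:
                continue
            motif_a = truth.tf2motif[tf_a]
            for mod_b in module_list:
                if mod_b == mod_a or not (members_of[mod_a] & members_of[mod_b]):
                    continue
                genes_b = list(truth.module_members[mod_b])
                k_shared = int(round(config.shared_motif_fraction * len(genes_b)))
                for gene in rng.choice(genes_b, size=k_shared, replace=False):
                    motif_hits.append((f"prom_{gene}", motif_a, 1))
                ocrs_b = [o for o, m in ocr2module.items() if m == mod_b]
                k_ocr = int(round(config.shared_motif_fraction * len(ocrs_b)))
                for ocr_id in rng.choice(ocrs_b, size=k_ocr, replace=False):
                    motif_hits.append((ocr_id, motif_a, 1))
    all_regions = [r[3] for r in ocr_rows] + [f"prom_{g}" for g in genes]
    motifs = sorted(set(truth.tf2motif.values()))
    if config.background_motif_rate > 0:
        hit = rng.random((len(all_regions), len(motifs))) < config.background_motif_rate
        ii, jj = np.nonzero(hit)
        for i, j in zip(ii, jj):
            motif_hits.append((all_regions[i], motifs[j], 1))
    motif_table = (
        pd.DataFrame(motif_hits, columns=["region_id", "motif_id", "count"])
        .groupby(["region_id", "motif_id"], as_index=False)["count"]
        .max()
    )

    # accessibility counts over an independent ATAC cell population
    ocr_ids = [r[3] for r in ocr_rows]
    base = np.exp(rng.normal(np.log(config.ocr_base_mean), 0.5, size=len(ocr_ids)))
    acc_mean = np.tile(base[:, None], (1, config.n_cell_types))
    type_index = {t: j for j, t in enumerate(config.cell_type_names)}
    for i, ocr_id in enumerate(ocr_ids):
        mod = ocr2module.get(ocr_id)
        if mod is None:
            continue
        spec = next(s for s in config.module_specs if s.module_id == mod)
        cols = [type_index[t] for t in spec.member_cell_types]
        acc_mean[i, cols] *= config.ocr_fold_elevation
    acc_df = pd.DataFrame(acc_mean, index=ocr_ids, columns=list(config.cell_type_names))

    atac_cells = {
        t: max(3, int(round(config.atac_cells_fraction * n)))
        for t, n in zip(config.cell_type_names, config.cells_per_type)
    }
    matrix, ann = _draw_cells(config, truth, atac_cells, acc_df, rng, "atac_")
    ann["broad_type"] = [_BROAD_MAP.get(c, c) for c in ann["cluster"]]
    ann["library"] = "atac1"
    acm = AnnotatedCountMatrix(
        values=matrix.astype(np.int64),
        feature_ids=pd.Index(ocr_ids),
        cell_ids=pd.Index(ann.index),
        obs=ann,
    )

    truth.ocr2module = ocr2module
    from .enrichment import nearest_tss  # deferred: avoids import cycle at module load

    truth.ocr2gene = nearest_tss(ocrs, tss).df
    return acm, ocrs, tss, motif_table


# ---------------------------------------------------------------------------
# Knockdown
# ---------------------------------------------------------------------------

def generate_knockdown(
    config: SyntheticConfig, truth: GroundTruth
) -> AnnotatedCountMatrix:
    """Two-condition replicated design with the planted TF knocked down.

    The control condition is distributionally identical to
    :func:`generate_expression`; the knockdown condition multiplies target
    gene means by the suppression factor in affected types only, and shrinks
    affected-type cell numbers by (1 - abundance_reduction).  Replicates are
    drawn independently.
    """
    kd = config.knockdown_spec
    targets = set(truth.tf2targets.get(kd.tf_id, ()))
    if kd.tf_id not in truth.tf2module:
        raise ValueError(f"unknown knockdown TF {kd.tf_id}")
    rng = np.random.default_rng(config.seed + 2)

    kd_mean = truth.expected_mean.copy()
    target_rows = [g for g in kd_mean.index if g in targets]
    # suppress the TF's own transcript as well as its targets
    tf_gene = getattr(truth, "tf_gene_of", {}).get(kd.tf_id)
    if tf_gene is not None:
        target_rows.append(tf_gene)
    for ctype in kd.affected_cell_types:
        kd_mean.loc[target_rows, ctype] *= kd.target_suppression_factor

    mats, anns = [], []
    for rep in range(1, kd.n_replicates + 1):
        for condition in ("control", "knockdown"):
            cells = {
                t: max(3, int(round(n * config.kd_cells_factor)))
                for t, n in zip(config.cell_type_names, config.cells_per_type)
            }
            mean = truth.expected_mean
            if condition == "knockdown":
                mean = kd_mean
                for ctype in kd.affected_cell_types:
                    cells[ctype] = max(1, int(round(cells[ctype] * (1 - kd.abundance_reduction))))
            prefix = f"{condition[:4]}_r{rep}_"
            m, ann = _draw_cells(config, truth, cells, mean, rng, prefix)
            ann["condition"] = condition
            ann["replicate"] = f"r{rep}"
            ann["library"] = f"{condition[:4]}_r{rep}"
            mats.append(m)
            anns.append(ann)
    matrix = sp.hstack(mats, format="csr")
    ann = pd.concat(anns)
    ann["broad_type"] = [_BROAD_MAP.get(c, c) for c in ann["cluster"]]
    return AnnotatedCountMatrix(
        values=matrix.astype(np.int64),
        feature_ids=pd.Index(truth.expected_mean.index),
        cell_ids=pd.Index(ann.index),
        obs=ann,
    )
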