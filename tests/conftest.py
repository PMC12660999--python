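"""Shared fixtures: a small fast synthetic dataset for unit tests and the
full default-conditions dataset (built once per session) for the
planted-truth recovery checks."""

from __future__ import annotations

from pathlib import Path

import pytest

from plangrn import pipeline, simulate


def small_config(seed: int = 0) -> simulate.SyntheticConfig:
    """Scaled-down study: same cell types, fewer cells/genes/OCRs."""
    return simulate.SyntheticConfig(
        cells_per_type=(120, 50, 60, 50, 30, 45, 60, 90, 20, 18),
        n_genes=400,
        module_specs=(
            simulate.ModuleSpec("M01", ("epidermis_late",), 25, 8.0),
            simulate.ModuleSpec("M02", ("neurons",), 25, 8.0),
            simulate.ModuleSpec("M03", ("phagocytes", "parenchyma"), 25, 8.0),
            simulate.ModuleSpec("M04", ("muscle", "neurons"), 25, 8.0),
        ),
        n_tfs=6,
        n_ocrs=160,
        ocrs_per_module=30,
        genome_span=8_000_000,
        knockdown_spec=simulate.KnockdownSpec(
            tf_id="TF03",
            affected_cell_types=("phagocytes", "parenchyma"),
            target_suppression_factor=0.3,
            abundance_reduction=0.5,
            n_replicates=2,
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_expression(small_cfg):
    return simulate.generate_expression(small_cfg)


@pytest.fixture(scope="session")
def small_multiome(small_cfg, small_expression):
    acm, truth = small_expression
    atac, ocrs, tss, hits = simulate.generate_accessibility(small_cfg, truth)
    return acm, truth, atac, ocrs, tss, hits


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory) -> Path:
    """Full default-conditions pipeline run shared by recovery tests."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = simulate.SyntheticConfig(seed=0)
    pipeline.stage_simulate(out, cfg)
    pipeline.stage_pseudobulk(out)
    pipeline.stage_modules(out, "expression")
    pipeline.stage_modules(out, "ocr-all")
    for kind in ("motif", "motif-ocr", "function", "pairs"):
        pipeline.stage_enrich(out, kind)
    return out


@pytest.fixture(scope="session")
def default_truth():
    cfg = simulate.SyntheticConfig(seed=0)
    _, truth = simulate.generate_expression(cfg)
    simulate.generate_accessibility(cfg, truth)  # populates OCR ground truth
    return truth
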