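"""Readers and writers for the plain-text formats the pipeline touches.

Conventions used throughout the package:

* genomic intervals are BED-style, 0-based half-open;
* MatrixMarket files are 1-based only at the file boundary;
* all writers produce deterministic output (stable ordering) so repeated
  runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


@dataclass
class AnnotatedCountMatrix:
    """Sparse feature x cell count matrix with aligned cell metadata.

    ``values`` is CSR with non-negative integer entries; ``obs`` carries
    per-cell metadata (any subset of cluster, broad_type, library,
    condition, replicate) indexed by cell id.
    """

    values: sp.csr_matrix
    feature_ids: pd.Index
    cell_ids: pd.Index
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.feature_ids = pd.Index(self.feature_ids, name="feature")
        self.cell_ids = pd.Index(self.cell_ids, name="cell")
        if self.feature_ids.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.cell_ids.has_duplicates:
            raise ValueError("duplicate cell ids")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if self.obs.empty and len(self.obs) == 0:
            self.obs = pd.DataFrame(index=self.cell_ids)
        if len(self.obs) != len(self.cell_ids):
            raise ValueError("cell metadata rows do not align 1:1 with cells")
        self.obs = self.obs.set_axis(self.cell_ids, axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GenomicIntervalSet:
    """BED-style intervals: 0-based half-open, unique ids, strand in +/-/. ."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in BED_COLUMNS:
            if col not in df.columns:
                df[col] = 0 if col == "score" else "."
        df = df[BED_COLUMNS]
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "id"].tolist()[:3]
            raise ValueError(f"intervals with start >= end: {bad}")
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if df["id"].duplicated().any():
            raise ValueError("duplicate interval ids")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "GenomicIntervalSet":
        out = self.df.sort_values(
            ["chrom", "start", "end", "id"], kind="mergesort"
        ).reset_index(drop=True)
        return GenomicIntervalSet(out)


# ---------------------------------------------------------------------------
# MatrixMarket bundles (MTX + features.tsv + barcodes.tsv + metadata.tsv)
# ---------------------------------------------------------------------------

def _mtx_paths(path: Path) -> dict[str, Path]:
    path = Path(path)
    return {
        "mtx": path / "matrix.mtx",
        "features": path / "features.tsv",
        "barcodes": path / "barcodes.tsv",
        "metadata": path / "metadata.tsv",
    }


def _locate_bad_mtx_line(mtx_path: Path, n_rows: int, n_cols: int) -> str | None:
    """Scan a coordinate MTX file for an out-of-range 1-based index."""
    with open(mtx_path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("%"):
                continue
            if not header_seen:
                header_seen = True  # size line
                continue
            parts = line.split()
            if len(parts) < 2:
                continue
            i, j = int(parts[0]), int(parts[1])
            if not (1 <= i <= n_rows and 1 <= j <= n_cols):
                return f"line {lineno}: index ({i}, {j}) outside 1..{n_rows} x 1..{n_cols}"
    return None


def read_mtx_bundle(path: str | Path) -> AnnotatedCountMatrix:
    """Read a matrix.mtx + features.tsv + barcodes.tsv (+ metadata.tsv) bundle."""
    paths = _mtx_paths(Path(path))
    for key in ("mtx", "features", "barcodes"):
        if not paths[key].exists():
            raise FileNotFoundError(str(paths[key]))
    features = pd.read_csv(paths["features"], sep="\t", header=None)[0]
    barcodes = pd.read_csv(paths["barcodes"], sep="\t", header=None)[0]
    with open(paths["mtx"]) as fh:
        for line in fh:
            if not line.startswith("%"):
                n_rows, n_cols = int(line.split()[0]), int(line.split()[1])
                break
    if n_rows != len(features) or n_cols != len(barcodes):
        raise ValueError(
            f"dimension mismatch: {paths['mtx'].name} declares {n_rows} x {n_cols} "
            f"but {paths['features'].name} has {len(features)} rows and "
            f"{paths['barcodes'].name} has {len(barcodes)} rows"
        )
    try:
        mat = scipy.io.mmread(paths["mtx"])
    except Exception as exc:
        bad = _locate_bad_mtx_line(paths["mtx"], n_rows, n_cols)
        raise ValueError(
            f"invalid MatrixMarket file {paths['mtx'].name}"
            + (f" ({bad})" if bad else "")
        ) from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.tocoo().row.min() < 0:
        bad = _locate_bad_mtx_line(paths["mtx"], n_rows, n_cols)
        raise ValueError(f"invalid 1-based index in {paths['mtx'].name}: {bad}")
    obs = pd.DataFrame(index=pd.Index(barcodes))
    if paths["metadata"].exists():
        obs = pd.read_csv(paths["metadata"], sep="\t", index_col=0)
        if len(obs) != len(barcodes):
            raise ValueError(
                f"dimension mismatch: {paths['metadata'].name} has {len(obs)} rows "
                f"but {paths['barcodes'].name} has {len(barcodes)}"
            )
    return AnnotatedCountMatrix(
        values=mat.astype(np.int64), feature_ids=pd.Index(features),
        cell_ids=pd.Index(barcodes), obs=obs,
    )


def write_mtx_bundle(acm: AnnotatedCountMatrix, path: str | Path) -> None:
    """Write a bundle that round-trips bit-exactly through :func:`read_mtx_bundle`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = _mtx_paths(path)
    coo = acm.values.tocoo()
    order = np.lexsort((coo.row, coo.col))  # column-major, deterministic
    triplets = pd.DataFrame(
        {
            "i": coo.row[order] + 1,
            "j": coo.col[order] + 1,
            "x": coo.data[order].astype(np.int64),
        }
    )
    with open(paths["mtx"], "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{acm.shape[0]} {acm.shape[1]} {coo.nnz}\n")
        triplets.to_csv(fh, sep=" ", header=False, index=False, lineterminator="\n")
    acm.feature_ids.to_series().to_csv(paths["features"], sep="\t", header=False, index=False)
    acm.cell_ids.to_series().to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    if acm.obs.shape[1]:
        acm.obs.to_csv(paths["metadata"], sep="\t")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GenomicIntervalSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED_COLUMNS, usecols=range(6), dtype={"chrom": str, "id": str},
    )
    return GenomicIntervalSet(df)


def write_bed(intervals: GenomicIntervalSet, path: str | Path) -> None:
    intervals.sorted().df.to_csv(path, sep="\t", header=False, index=False)


def make_promoters(tss: GenomicIntervalSet, flank: int = 200) -> GenomicIntervalSet:
    """Symmetric promoter windows [anchor - flank, anchor + flank) clipped at 0.

    ``tss`` rows are 1-bp anchors.  The flank is symmetric around the anchor,
    so strand only matters for where the anchor was placed upstream of this
    call (the synthetic generator anchors at interval start on + strand).
    """
    df = tss.df.copy()
    anchor = df["start"]
    df["start"] = (anchor - flank).clip(lower=0)
    df["end"] = anchor + flank
    return GenomicIntervalSet(df)


def read_gtf_tss(path: str | Path) -> GenomicIntervalSet:
    """Extract gene_id and TSS anchors from a GTF (gene features only).

    Minimal on purpose: only gene_id and coordinates are used downstream.
    The TSS anchor is the start for + strand and end - 1 for - strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in parts[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            start, end, strand = int(parts[3]) - 1, int(parts[4]), parts[6]
            anchor = start if strand != "-" else end - 1
            rows.append((parts[0], anchor, anchor + 1, gene_id, 0, strand))
    return GenomicIntervalSet(pd.DataFrame(rows, columns=BED_COLUMNS))


# ---------------------------------------------------------------------------
# Small helpers shared by the CLI and the analysis drivers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def config_hash(config: dict) -> str:
    buf = _stdio.StringIO()
    pd.Series(
        {k: repr(v) for k, v in sorted(config.items())}, dtype=object
    ).to_csv(buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]
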