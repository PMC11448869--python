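"""Readers and writers for the standard on-disk formats the pipeline touches.

On disk the count matrix follows the 10x convention: Matrix Market triplet
with genes as rows and cells as columns, plus one-column (or 10x
three-column) ``barcodes.tsv`` / ``features.tsv`` sidecars.  In memory the
orientation is always cells×genes, so the reader transposes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import CellMatrix, ClonotypeTable, FormatError


def _read_sidecar(path) -> np.ndarray:
    """First column of a TSV sidecar (1-column or 10x 3-column)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_mtx_triplet(matrix_path, barcodes_path, features_path) -> CellMatrix:
    """Read a 10x-style MTX triplet into a cells×genes :class:`CellMatrix`.

    The on-disk matrix is genes×cells (10x default) and is transposed on
    load; the sidecar lengths must match the corresponding matrix
    dimensions.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # noqa: BLE001 - normalize to format error
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
    mat = sp.csr_matrix(mat)
    barcodes = _read_sidecar(barcodes_path)
    features = _read_sidecar(features_path)
    n_genes, n_cells = mat.shape
    if len(features) != n_genes or len(barcodes) != n_cells:
        raise FormatError(
            f"matrix is {n_genes} genes x {n_cells} cells but sidecars have "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    uniq, counts = np.unique(barcodes.astype(str), return_counts=True)
    if (counts > 1).any():
        raise FormatError(
            f"duplicate barcodes: {uniq[counts > 1][:5].tolist()}"
        )
    return CellMatrix(counts=mat.T.tocsr(), cell_ids=barcodes, gene_ids=features)


def write_mtx_triplet(cm: CellMatrix, out_dir) -> dict[str, Path]:
    """Write ``cm`` as matrix.mtx + barcodes.tsv + features.tsv (10x layout).

    Returns the three paths.  The matrix is stored genes×cells so that
    :func:`read_mtx_triplet` round-trips exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
    }
    scipy.io.mmwrite(
        os.fspath(paths["matrix"]), cm.counts.T.tocoo().astype(int), field="integer"
    )
    paths["barcodes"].write_text("".join(f"{b}\n" for b in cm.cell_ids))
    paths["features"].write_text("".join(f"{g}\n" for g in cm.gene_ids))
    return paths


def read_clonotype_csv(path) -> ClonotypeTable:
    """Read a per-cell clonotype CSV (barcode, clone_id[, cdr3_nt, cdr3_aa]).

    A barcode mapped to two distinct clone_ids is a conflict error; exact
    duplicate rows are collapsed.  Cells absent from the file are treated
    as clonotype-unassigned downstream.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"barcode", "clone_id"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"clonotype CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    keep = ["clone_id"] + [c for c in ("cdr3_nt", "cdr3_aa") if c in df.columns]
    df = df.set_index("barcode")[keep]
    return ClonotypeTable(assignments=df)


def write_clonotype_csv(table: ClonotypeTable, path) -> Path:
    path = Path(path)
    df = table.assignments.reset_index().rename(columns={"index": "barcode"})
    if df.columns[0] != "barcode":
        df = df.rename(columns={df.columns[0]: "barcode"})
    df.to_csv(path, index=False)
    return path


def read_cell_meta_csv(path, cell_ids=None) -> pd.DataFrame:
    """Per-cell metadata CSV keyed by barcode (first column)."""
    df = pd.read_csv(path, dtype=str).set_index("barcode")
    if cell_ids is not None:
        df = df.reindex(cell_ids)
    return df


def read_gene_list(path) -> list[str]:
    """Plain-text gene set: one symbol per line, blanks and '#' skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.append(sym)
    return genes
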