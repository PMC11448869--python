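"""Core data carriers: the cell×gene matrix, the clonotype table, run config.

``CellMatrix`` is the universal carrier between pipeline stages: a sparse
nonnegative-integer UMI count matrix (cells as rows), per-cell metadata,
and optional derived layers (log-normalized, imputed) that share its shape.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("clonofate")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of its documented range."""


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


@dataclass
class CellMatrix:
    """Sparse cell×gene counts with per-cell metadata and optional layers.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, cells as rows.  Any array or scipy
        sparse matrix is accepted and stored as CSR.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    cell_meta
        Table indexed by cell_id; typical columns are ``sample``,
        ``timepoint``, ``phenotype`` and ``clone_id``, any of which may be
        absent.
    layer_log, layer_imputed
        Optional real-valued matrices sharing the counts shape.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame | None = None
    layer_log: np.ndarray | None = None
    layer_imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                dups = uniq[counts > 1][:5].tolist()
                raise FormatError(f"duplicate {name} ids: {dups}")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("counts contain negative entries")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("counts contain non-integral entries")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            unknown = self.cell_meta.index.difference(pd.Index(self.cell_ids))
            if len(unknown):
                raise FormatError(
                    f"cell_meta rows key unknown cells: {list(unknown[:5])}"
                )
            self.cell_meta = self.cell_meta.reindex(pd.Index(self.cell_ids, name="cell_id"))
        for layer_name in ("layer_log", "layer_imputed"):
            layer = getattr(self, layer_name)
            if layer is not None:
                layer = np.asarray(layer, dtype=float)
                if layer.shape != self.counts.shape:
                    raise FormatError(
                        f"{layer_name} shape {layer.shape} != counts {self.counts.shape}"
                    )
                setattr(self, layer_name, layer)

    # -- basic views ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, genes) -> np.ndarray:
        """Column indices for the requested gene symbols (KeyError on miss)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(self, cell_mask=None, gene_mask=None) -> "CellMatrix":
        """Row/column subset propagated through metadata and layers."""
        cm = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        gm = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        if cm.dtype == bool:
            cm = np.flatnonzero(cm)
        if gm.dtype == bool:
            gm = np.flatnonzero(gm)
        return CellMatrix(
            counts=self.counts[cm][:, gm],
            cell_ids=self.cell_ids[cm],
            gene_ids=self.gene_ids[gm],
            cell_meta=self.cell_meta.iloc[cm],
            layer_log=None if self.layer_log is None else self.layer_log[np.ix_(cm, gm)],
            layer_imputed=None
            if self.layer_imputed is None
            else self.layer_imputed[np.ix_(cm, gm)],
        )

    def dense_counts(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)


@dataclass
class ClonotypeTable:
    """Map from cell barcode to clonotype, with clone sizes and CDR3s.

    Cells absent from the table are clonotype-unassigned.  Clone sizes
    ``n_c`` are derived, never stored, so they cannot drift out of sync
    with the assignment.
    """

    assignments: pd.DataFrame  # index barcode; columns clone_id[, cdr3_nt, cdr3_aa]

    def __post_init__(self) -> None:
        df = self.assignments
        if "clone_id" not in df.columns:
            raise FormatError("clonotype table needs a clone_id column")
        if df.index.has_duplicates:
            dup_index = df.index[df.index.duplicated(keep=False)]
            conflicting = (
                df.loc[dup_index].groupby(level=0)["clone_id"].nunique()
            )
            bad = conflicting[conflicting > 1].index.tolist()
            if bad:
                raise FormatError(
                    f"barcodes mapped to multiple clone_ids: {bad[:5]}"
                )
            self.assignments = df[~df.index.duplicated()]

    @property
    def clone_sizes(self) -> pd.Series:
        """n_c: number of member cells per clone."""
        return self.assignments["clone_id"].value_counts().sort_index()

    @property
    def n_clones(self) -> int:
        return self.assignments["clone_id"].nunique()

    def members(self, clone_id) -> np.ndarray:
        return self.assignments.index[
            self.assignments["clone_id"] == clone_id
        ].to_numpy()

    def clones(self, min_cells: int = 1) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (clone_id, member barcodes) for clones with ≥ min_cells cells."""
        for clone_id, group in self.assignments.groupby("clone_id", sort=True):
            if len(group) >= min_cells:
                yield clone_id, group.index.to_numpy()

    def clone_of(self, cell_ids) -> pd.Series:
        """Clone id per requested cell; NaN for unassigned cells."""
        return self.assignments["clone_id"].reindex(cell_ids)


# ----------------------------------------------------------------------
# Run configuration: flat key=value text document with a schema version.
# Unknown keys are errors so a typo in a threshold cannot pass silently.

_CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """End-to-end run parameters, serializable to flat key=value text."""

    seed: int = 0
    mito_max: float = 0.20
    min_molecules: int = 500
    min_cells_per_gene: int = 10
    dialect: str = "median_log2_p0.1"
    k: int = 30
    ka: int = 10
    t: int = 4
    n_pcs: int = 20
    clonotype_k: int = 10
    min_clone_cells: int = 5
    n_perm: int = 500
    out_dir: str = "clonofate_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_max <= 1.0:
            raise ConfigError(f"mito_max out of [0,1]: {self.mito_max}")
        for name in ("min_molecules", "min_cells_per_gene", "min_clone_cells"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.dialect not in ("median_log2_p0.1", "cp10k_log2_p1"):
            raise ConfigError(f"unknown normalization dialect: {self.dialect}")
        if not (1 <= self.ka <= self.k):
            raise ConfigError(f"need 1 <= ka <= k, got ka={self.ka}, k={self.k}")
        if self.t < 0 or self.n_pcs < 1 or self.n_perm < 1:
            raise ConfigError("t >= 0, n_pcs >= 1 and n_perm >= 1 required")

    def to_text(self) -> str:
        lines = [f"schema_version={_CONFIG_SCHEMA_VERSION}"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "schema_version":
                if int(value) != _CONFIG_SCHEMA_VERSION:
                    raise ConfigError(f"unsupported schema version {value}")
                continue
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown config key {key!r}")
            target = known[key]
            if target in ("int", int):
                kwargs[key] = int(value)
            elif target in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())


class stage_timer:
    """Context manager emitting a structured log line per pipeline stage."""

    def __init__(self, stage: str, seed: int | None = None):
        self.stage = stage
        self.seed = seed

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        elapsed = time.perf_counter() - self._t0
        logger.info(
            "stage=%s seed=%s elapsed=%.3fs", self.stage, self.seed, elapsed
        )
        return False
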