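"""Quality control, normalization dialects, HVG selection and DE testing.

Two normalization dialects are supported:

``median_log2_p0.1``
    library-size normalize, multiply by the median total molecule count
    across cells, log2 with pseudocount 0.1 (mouse T-cell dialect);
``cp10k_log2_p1``
    scale to 10,000 counts per cell, log2 with pseudocount 1 (human
    peripheral-blood dialect).

Differential expression is a per-gene two-sided Wilcoxon rank-sum test
with Benjamini–Hochberg correction.  This is a documented stand-in for a
hurdle-model test with a detected-genes covariate; the pass thresholds
(strict FDR cutoff and strict |log2FC| cutoff) are applied exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CellMatrix, ConfigError, logger


@dataclass
class QCThresholds:
    """Cell and gene quality-control cutoffs (all inequalities strict).

    mito_max : maximum tolerated mitochondrial fraction (cells with a
        strictly greater fraction are removed; default 0.20).
    min_molecules : cells with strictly fewer total molecules are removed
        (default 500).
    min_cells_per_gene : genes expressed in no more than this many cells
        are removed (default 10; a stricter 1000 fits large blood cohorts).
    min_genes_per_cell : optional library-complexity filter; None disables.
    """

    mito_max: float = 0.20
    min_molecules: int = 500
    min_cells_per_gene: int = 10
    min_genes_per_cell: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_max <= 1.0:
            raise ConfigError(f"mito_max out of [0,1]: {self.mito_max}")
        if self.min_molecules < 0 or self.min_cells_per_gene < 0:
            raise ConfigError("count minima must be >= 0")


_DIALECTS = {
    "median_log2_p0.1": dict(scale="median", pseudocount=0.1),
    "cp10k_log2_p1": dict(scale=10_000.0, pseudocount=1.0),
}


@dataclass
class NormalizationDialect:
    tag: str = "median_log2_p0.1"
    scale: float | str = field(init=False)
    pseudocount: float = field(init=False)
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.tag not in _DIALECTS:
            raise ConfigError(
                f"unknown dialect {self.tag!r}; choose from {sorted(_DIALECTS)}"
            )
        spec = _DIALECTS[self.tag]
        self.scale = spec["scale"]
        self.pseudocount = spec["pseudocount"]


def qc_filter(
    cm: CellMatrix,
    thresholds: QCThresholds | None = None,
    mito_gene_prefix: str = "mt-",
    mito_genes: list[str] | None = None,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Apply cell filters, then the gene filter; return matrix and report.

    Cells with mitochondrial fraction > ``mito_max`` or total molecules
    < ``min_molecules`` (or, if enabled, detected genes
    < ``min_genes_per_cell``) are removed first; afterwards genes expressed
    in ≤ ``min_cells_per_gene`` of the surviving cells are removed.  The
    report lists removals per rule in application order.
    """
    thresholds = thresholds or QCThresholds()
    counts = cm.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if mito_genes is not None:
        mito_mask = np.isin(cm.gene_ids, list(mito_genes))
    else:
        mito_mask = np.array(
            [str(g).lower().startswith(mito_gene_prefix.lower()) for g in cm.gene_ids]
        )
    mito_totals = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 1.0)

    fail_mito = mito_frac > thresholds.mito_max
    fail_mol = totals < thresholds.min_molecules
    rules = [
        ("mito_fraction", fail_mito),
        ("min_molecules", fail_mol),
    ]
    if thresholds.min_genes_per_cell is not None:
        n_genes_per_cell = counts.getnnz(axis=1)
        rules.append(
            ("min_genes_per_cell", n_genes_per_cell < thresholds.min_genes_per_cell)
        )
    removed_so_far = np.zeros(cm.n_cells, dtype=bool)
    report_rows = []
    for name, fail in rules:
        newly = fail & ~removed_so_far
        report_rows.append(("cell", name, int(newly.sum())))
        removed_so_far |= fail
    keep_cells = ~removed_so_far
    if not keep_cells.any():
        raise ValueError("empty after QC: every cell failed a cell filter")

    surviving = counts[keep_cells]
    cells_per_gene = surviving.getnnz(axis=0)
    keep_genes = cells_per_gene > thresholds.min_cells_per_gene
    report_rows.append(("gene", "min_cells_per_gene", int((~keep_genes).sum())))
    report = pd.DataFrame(report_rows, columns=["level", "rule", "n_removed"])
    logger.info("qc_filter removed %d cells, %d genes",
                int(removed_so_far.sum()), int((~keep_genes).sum()))
    return cm.subset(keep_cells, keep_genes), report


def normalize(cm: CellMatrix, dialect: NormalizationDialect | str = "median_log2_p0.1") -> CellMatrix:
    """Equalize per-cell totals to the dialect's target, then log-transform.

    The result is stored in ``layer_log``; raw counts are untouched.
    """
    if isinstance(dialect, str):
        dialect = NormalizationDialect(dialect)
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = cm.cell_ids[totals == 0][:5].tolist()
        raise ValueError(f"zero-total cells present (QC them first): {bad}")
    target = float(np.median(totals)) if dialect.scale == "median" else float(dialect.scale)
    scaled = cm.counts.multiply((target / totals)[:, None]).toarray()
    layer = np.log(scaled + dialect.pseudocount) / np.log(dialect.log_base)
    return CellMatrix(
        counts=cm.counts,
        cell_ids=cm.cell_ids,
        gene_ids=cm.gene_ids,
        cell_meta=cm.cell_meta,
        layer_log=layer,
        layer_imputed=cm.layer_imputed,
    )


def _dispersion_zscores(log_layer: np.ndarray, n_bins: int) -> np.ndarray:
    """Normalized dispersion: var/mean of log values, z-scored within
    equal-count mean-expression bins."""
    mean = log_layer.mean(axis=0)
    var = log_layer.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(np.abs(mean) > 1e-12, var / np.abs(mean), 0.0)
    order = np.argsort(mean, kind="stable")
    n_genes = log_layer.shape[1]
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    z = np.zeros(n_genes)
    for b in range(n_bins):
        members = bins == b
        if not members.any():
            continue
        d = disp[members]
        sd = d.std()
        z[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    return z


def select_hvg(
    cm: CellMatrix,
    n: int = 1000,
    sample_ids=None,
    n_bins: int = 20,
) -> list[str]:
    """Top-``n`` highly variable genes by mean-binned normalized dispersion.

    With ``sample_ids`` given, dispersion ranks are computed within each
    sample and combined by summed rank (smaller total rank = more
    variable), so no single deep sample dominates.
    """
    if cm.layer_log is None:
        raise ValueError("normalize() before select_hvg()")
    if n >= cm.n_genes:
        if n > cm.n_genes:
            logger.warning("requested %d HVGs from %d genes; returning all", n, cm.n_genes)
        return list(cm.gene_ids)
    if sample_ids is None:
        z = _dispersion_zscores(cm.layer_log, n_bins)
        order = np.argsort(-z, kind="stable")
    else:
        sample_ids = np.asarray(sample_ids)
        total_rank = np.zeros(cm.n_genes)
        for sample in np.unique(sample_ids):
            z = _dispersion_zscores(cm.layer_log[sample_ids == sample], n_bins)
            ranks = np.empty(cm.n_genes)
            ranks[np.argsort(-z, kind="stable")] = np.arange(cm.n_genes)
            total_rank += ranks
        order = np.argsort(total_rank, kind="stable")
    return list(cm.gene_ids[order[:n]])


def differential_expression(
    cm: CellMatrix,
    groups,
    min_lfc: float = 0.5,
    max_fdr: float = 0.01,
    one_vs_rest: bool = True,
) -> pd.DataFrame:
    """Per-gene rank-sum DE with BH correction and strict pass thresholds.

    ``pass`` requires FDR strictly below ``max_fdr`` AND |log2FC| strictly
    above ``min_lfc``.  log2FC is the difference of group means on the log
    layer.  Two presets cover common usage: ``max_fdr=1e-10`` (stringent)
    and ``max_fdr=0.01`` (figure-legend preset).  In one-vs-rest mode each
    group is tested against all remaining cells.
    """
    if cm.layer_log is None:
        raise ValueError("normalize() before differential_expression()")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 cells")

    if one_vs_rest:
        contrasts = [(lab, groups == lab, groups != lab) for lab in labels]
    else:
        if len(labels) != 2:
            raise ValueError("pairwise mode needs exactly two groups")
        contrasts = [(labels[0], groups == labels[0], groups == labels[1])]

    frames = []
    X = cm.layer_log
    for lab, in_mask, out_mask in contrasts:
        a, b = X[in_mask], X[out_mask]
        lfc = a.mean(axis=0) - b.mean(axis=0)
        # vectorized over genes via the normal approximation used by ranksums
        pvals = np.array(
            [stats.ranksums(a[:, j], b[:, j]).pvalue for j in range(X.shape[1])]
        )
        fdr = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": cm.gene_ids,
                    "group": lab,
                    "log2fc": lfc,
                    "p": pvals,
                    "fdr": fdr,
                    "pass": (fdr < max_fdr) & (np.abs(lfc) > min_lfc),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
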