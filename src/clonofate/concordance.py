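"""Replicate and cross-sample concordance metrics.

Centroid correlation compares cluster average expression profiles across
two datasets: centroids are computed on a shared gene set, each gene is
z-scored across the centroids *within* each dataset (removing per-dataset
location/scale effects), and Pearson r is reported for every
cross-dataset cluster pair.  Cluster matching between replicates is
automated by maximum-weight bipartite matching on that correlation
matrix.  The overlap coefficient |A∩B|/min(|A|,|B|) compares recovered
DEG sets, and the adjusted Rand index compares clusterings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .core import CellMatrix


def _centroids(cm: CellMatrix, labels, genes) -> pd.DataFrame:
    labels = np.asarray(labels)
    cols = cm.gene_index(list(genes))
    if cm.layer_log is not None:
        X = cm.layer_log[:, cols]
    else:
        X = np.asarray(cm.counts[:, cols].todense(), dtype=float)
    rows = {}
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() == 0:  # pragma: no cover - unique() precludes
            raise ValueError(f"cluster {lab!r} has no cells")
        rows[lab] = X[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(genes))


def centroid_correlation(
    cmA: CellMatrix, labelsA, cmB: CellMatrix, labelsB, genes
) -> pd.DataFrame:
    """Cross-dataset Pearson correlation of z-scored cluster centroids.

    Each dataset needs >= 2 clusters (z-scoring across a single centroid
    is undefined).  Genes with zero variance across either dataset's
    centroids are dropped with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("shared gene set is empty")
    cents = []
    for cm, labels, tag in ((cmA, labelsA, "A"), (cmB, labelsB, "B")):
        cent = _centroids(cm, labels, genes)
        if cent.shape[0] < 2:
            raise ValueError(f"dataset {tag} has fewer than 2 clusters")
        cents.append(cent)
    centA, centB = cents
    sdA, sdB = centA.std(axis=0, ddof=0), centB.std(axis=0, ddof=0)
    keep = (sdA > 0) & (sdB > 0)
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"dropping zero-variance genes across centroids: {dropped}")
    if not keep.any():
        raise ValueError("no gene varies across centroids in both datasets")
    zA = (centA.loc[:, keep] - centA.loc[:, keep].mean()) / sdA[keep]
    zB = (centB.loc[:, keep] - centB.loc[:, keep].mean()) / sdB[keep]
    out = np.empty((zA.shape[0], zB.shape[0]))
    for i, (_, a) in enumerate(zA.iterrows()):
        for j, (_, b) in enumerate(zB.iterrows()):
            out[i, j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(out, index=zA.index, columns=zB.index)


def match_clusters(corr: pd.DataFrame) -> list[tuple]:
    """Maximum-weight bipartite matching of clusters on the correlation
    matrix; returns (row_cluster, col_cluster, r) triples."""
    ri, ci = linear_sum_assignment(-corr.to_numpy())
    return [
        (corr.index[i], corr.columns[j], float(corr.iat[i, j]))
        for i, j in zip(ri, ci)
    ]


def overlap_coefficient(setA, setB) -> float:
    """|A ∩ B| / min(|A|, |B|) for two nonempty sets."""
    A, B = set(setA), set(setB)
    if not A or not B:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(A & B) / min(len(A), len(B))


def adjusted_rand_index(labelsA, labelsB) -> float:
    """Permutation-model adjusted Rand index between two labelings."""
    labelsA, labelsB = np.asarray(labelsA), np.asarray(labelsB)
    if labelsA.shape != labelsB.shape:
        raise ValueError(
            f"label length mismatch: {labelsA.shape} vs {labelsB.shape}"
        )
    return float(adjusted_rand_score(labelsA, labelsB))
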