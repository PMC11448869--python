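"""Marker-panel PC-score classifier for purging CD8 T cells.

The procedure, per sample: cp10k + log2(x+1) normalize the nine-gene
lineage marker panel (Cd8b, Cd8a, Ccl5, Nkg7, Gzmm / Cd4, Cd40lg,
Tnfrsf4, Itgb1), z-score each gene, take the first principal-component
score as a composite lineage score, derive proxy labels from mutually
exclusive raw Cd4 vs Cd8a/b counts, pick the score threshold that
maximizes the Matthews correlation coefficient (MCC) on the proxy cells,
and extend the classification to every cell.  The PC sign is fixed so
CD4-proxy cells score higher than CD8-proxy cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import CellMatrix, ConfigError

DEFAULT_CD8 = ("Cd8b", "Cd8a", "Ccl5", "Nkg7", "Gzmm")
DEFAULT_CD4 = ("Cd4", "Cd40lg", "Tnfrsf4", "Itgb1")


@dataclass
class MarkerPanel:
    """Lineage marker panel with the CD4-side / CD8-side proxy subsets."""

    genes: tuple[str, ...] = DEFAULT_CD8 + DEFAULT_CD4
    cd8_side: tuple[str, ...] = DEFAULT_CD8
    cd4_side: tuple[str, ...] = DEFAULT_CD4
    # proxy labels key on the canonical lineage genes only
    proxy_cd4_gene: str = "Cd4"
    proxy_cd8_genes: tuple[str, ...] = ("Cd8a", "Cd8b")

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError("empty marker panel")
        if set(self.cd4_side) & set(self.cd8_side):
            raise ConfigError("cd4_side and cd8_side must be disjoint")


def proxy_label(cm: CellMatrix, panel: MarkerPanel | None = None) -> pd.Series:
    """Mutually-exclusive-expression proxy labels from raw counts.

    CD4 proxy: Cd4 count > 0 and both Cd8a and Cd8b zero.  CD8 proxy:
    Cd8a or Cd8b > 0 and Cd4 zero.  Everything else (co-expressing or
    all-zero) is 'unlabeled'.
    """
    panel = panel or MarkerPanel()
    genes = [panel.proxy_cd4_gene, *panel.proxy_cd8_genes]
    try:
        cols = cm.gene_index(genes)
    except KeyError as exc:
        raise ValueError(f"proxy genes missing from matrix: {exc}") from exc
    raw = np.asarray(cm.counts[:, cols].todense())
    cd4 = raw[:, 0] > 0
    cd8 = raw[:, 1:].sum(axis=1) > 0
    labels = np.full(cm.n_cells, "unlabeled", dtype=object)
    labels[cd4 & ~cd8] = "CD4"
    labels[cd8 & ~cd4] = "CD8"
    return pd.Series(labels, index=pd.Index(cm.cell_ids, name="cell_id"),
                     name="proxy")


def _panel_zscores(cm: CellMatrix, panel: MarkerPanel) -> np.ndarray:
    """cp10k → log2(x+1) → per-gene z-score, restricted to panel genes."""
    cols = cm.gene_index(list(panel.genes))
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; QC before scoring")
    sub = np.asarray(cm.counts[:, cols].todense(), dtype=float)
    sub = sub * (10_000.0 / totals)[:, None]
    sub = np.log2(sub + 1.0)
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0  # flat gene contributes nothing after centering
    return (sub - sub.mean(axis=0)) / sd


def marker_pc_score(
    cm: CellMatrix,
    panel: MarkerPanel | None = None,
    sample_ids=None,
    proxy: pd.Series | None = None,
) -> tuple[pd.Series, dict]:
    """First-PC composite lineage score per cell, computed per sample.

    Orientation is fixed within each sample so that the mean score of
    CD4-proxy cells exceeds that of CD8-proxy cells.  Samples with fewer
    than 3 proxy-labeled cells are flagged unfit (scores returned anyway).
    Returns (scores, info) where info carries per-sample loadings and
    fitness flags.
    """
    panel = panel or MarkerPanel()
    proxy = proxy if proxy is not None else proxy_label(cm, panel)
    if sample_ids is None:
        sample_ids = np.repeat("sample0", cm.n_cells)
    sample_ids = np.asarray(sample_ids)
    scores = np.empty(cm.n_cells)
    info: dict = {"samples": {}}
    for sample in np.unique(sample_ids):
        mask = sample_ids == sample
        Z = _panel_zscores(cm.subset(mask), panel)
        # first right singular vector = first PC loadings (Z already centered)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        loadings = vt[0]
        s = Z @ loadings
        prox = proxy[mask]
        n_proxy = int((prox != "unlabeled").sum())
        cd4_mean = s[(prox == "CD4").to_numpy()].mean() if (prox == "CD4").any() else np.nan
        cd8_mean = s[(prox == "CD8").to_numpy()].mean() if (prox == "CD8").any() else np.nan
        if np.isfinite(cd4_mean) and np.isfinite(cd8_mean) and cd4_mean < cd8_mean:
            loadings, s = -loadings, -s
        scores[mask] = s
        info["samples"][str(sample)] = {
            "loadings": dict(zip(panel.genes, loadings.round(6).tolist())),
            "n_proxy": n_proxy,
            "fit": n_proxy >= 3,
        }
    return (
        pd.Series(scores, index=pd.Index(cm.cell_ids, name="cell_id"), name="pc_score"),
        info,
    )


def _confusion_sweep(scores: np.ndarray, is_cd4: np.ndarray):
    """Vectorized TP/FP/TN/FN for the rule `score > threshold → CD4` at
    every candidate threshold (midpoints of consecutive distinct sorted
    scores, plus ±inf)."""
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = is_cd4[order].astype(int)
    distinct = np.unique(s_sorted)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.r_[-np.inf, mids, np.inf]
    n_pos = y_sorted.sum()
    n_neg = len(y_sorted) - n_pos
    # cells with score <= thr are predicted CD8
    below = np.searchsorted(s_sorted, thresholds, side="right")
    cum_pos = np.r_[0, np.cumsum(y_sorted)]
    fn = cum_pos[below]            # CD4 cells predicted CD8
    tn = below - fn                # CD8 cells predicted CD8
    tp = n_pos - fn
    fp = n_neg - tn
    return thresholds, tp, fp, tn, fn


def _mcc(tp, fp, tn, fn) -> np.ndarray:
    tp, fp, tn, fn = (np.asarray(x, dtype=float) for x in (tp, fp, tn, fn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = (tp * tn - fp * fn) / denom
    return np.where(denom > 0, mcc, 0.0)


@dataclass
class ThresholdModel:
    """Fitted MCC-optimal threshold on the oriented PC score."""

    threshold: float
    mcc: float
    balanced_accuracy: float
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "mcc": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
            "confusion": self.confusion,
        }


def fit_mcc_threshold(scores, proxy_labels) -> ThresholdModel:
    """Threshold maximizing MCC on proxy-labeled cells.

    Candidates are midpoints between consecutive distinct scores plus
    ±inf.  Ties on MCC break toward the larger balanced accuracy, then
    the smaller threshold — a fixed, deterministic rule.
    """
    scores = np.asarray(scores, dtype=float)
    proxy_labels = np.asarray(proxy_labels)
    labeled = proxy_labels != "unlabeled"
    scores, proxy_labels = scores[labeled], proxy_labels[labeled]
    classes = set(proxy_labels)
    if not {"CD4", "CD8"} <= classes:
        raise ValueError(f"both proxy classes required, got {sorted(classes)}")
    is_cd4 = proxy_labels == "CD4"
    thresholds, tp, fp, tn, fn = _confusion_sweep(scores, is_cd4)
    mcc = _mcc(tp, fp, tn, fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
    bal_acc = (sens + spec) / 2.0
    # lexicographic argmax: MCC, then balanced accuracy, then -threshold
    best = max(
        range(len(thresholds)),
        key=lambda i: (mcc[i], bal_acc[i], -thresholds[i]),
    )
    return ThresholdModel(
        threshold=float(thresholds[best]),
        mcc=float(mcc[best]),
        balanced_accuracy=float(bal_acc[best]),
        confusion={
            "tp": int(tp[best]), "fp": int(fp[best]),
            "tn": int(tn[best]), "fn": int(fn[best]),
        },
    )


def classify(scores, model: ThresholdModel) -> np.ndarray:
    """Extend the fitted criterion to all cells: score > threshold → CD4."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > model.threshold, "CD4", "CD8").astype(object)


class CD4CD8Classifier(BaseEstimator, ClassifierMixin):
    """End-to-end marker-panel classifier (sklearn estimator facade).

    ``fit(cm)`` derives proxy labels, computes oriented per-sample PC
    scores and the MCC-optimal threshold; ``predict(cm)`` classifies every
    cell.  Fitted attributes: ``scores_``, ``proxy_``, ``model_``,
    ``pc_info_``, ``labels_``.
    """

    def __init__(self, panel: MarkerPanel | None = None, sample_key: str | None = None):
        self.panel = panel
        self.sample_key = sample_key

    def _sample_ids(self, cm: CellMatrix):
        if self.sample_key is None:
            return None
        return cm.cell_meta[self.sample_key].to_numpy()

    def fit(self, cm: CellMatrix, y=None):
        panel = self.panel or MarkerPanel()
        self.proxy_ = proxy_label(cm, panel)
        self.scores_, self.pc_info_ = marker_pc_score(
            cm, panel, sample_ids=self._sample_ids(cm), proxy=self.proxy_
        )
        self.model_ = fit_mcc_threshold(self.scores_, self.proxy_)
        self.labels_ = pd.Series(
            classify(self.scores_, self.model_),
            index=self.scores_.index, name="lineage",
        )
        return self

    def predict(self, cm: CellMatrix) -> np.ndarray:
        panel = self.panel or MarkerPanel()
        scores, _ = marker_pc_score(
            cm, panel, sample_ids=self._sample_ids(cm)
        )
        return classify(scores, self.model_)
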