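"""Gene-signature scoring, percentile binning, and score-based partitions.

A signature score is the average z-scored (across cells) imputed
expression over the signature's genes.  Downstream conventions implemented
here: percentile binning into low/mid/high (default: below the 60th
percentile = low, top 5% = high), a naive/effector partition by the top
fraction of an effector score, and a per-sample signature comparison that
averages scores within sample×subset (dropping subsets with ≤ 10 cells in
a sample) and tests sample means between groups with a two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CellMatrix, ConfigError, logger


@dataclass
class GeneSignature:
    """Named gene set; duplicate symbols are collapsed, order irrelevant."""

    name: str
    genes: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ConfigError(f"signature {self.name!r} is empty")


@dataclass
class SignatureScores:
    """Per-cell scores (z-units) for one signature, optionally binned."""

    name: str
    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str] = field(default_factory=list)
    bins: pd.Series | None = None


def _zscore(X: np.ndarray, ddof: int = 0) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    return (X - mu) / sd


def score_signature(
    cm: CellMatrix, sig: GeneSignature, layer: str = "layer_imputed", ddof: int = 0
) -> SignatureScores:
    """Average z-scored imputed expression over the signature genes.

    Genes absent from the matrix are reported (error if none remain);
    zero-variance genes are dropped with a warning since their z-score is
    undefined.  z-scoring uses the population (n) denominator by default.
    """
    X = getattr(cm, layer)
    if X is None:
        raise ValueError(f"{layer} missing; impute/normalize first")
    present = [g for g in sig.genes if g in set(cm.gene_ids)]
    missing = [g for g in sig.genes if g not in set(cm.gene_ids)]
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} present; missing: {missing}"
        )
    cols = cm.gene_index(present)
    sub = X[:, cols]
    sd = sub.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        dropped = [g for g, s in zip(present, sd) if s == 0]
        warnings.warn(
            f"signature {sig.name!r}: dropping zero-variance genes {dropped}"
        )
        keep = sd > 0
        if not keep.any():
            raise ValueError(f"all genes of signature {sig.name!r} have zero variance")
        sub, present = sub[:, keep], [g for g, k in zip(present, keep) if k]
    scores = _zscore(sub, ddof=ddof).mean(axis=1)
    return SignatureScores(
        name=sig.name,
        scores=pd.Series(scores, index=pd.Index(cm.cell_ids, name="cell_id"),
                         name=sig.name),
        genes_used=present,
        genes_missing=missing,
    )


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Empirical percentile rank: 100 * (#cells strictly below) / n.

    On distinct scores the rank-r cell (1-based) gets 100*(r-1)/n, so a
    cut "below the P-th percentile" captures exactly P% of the cells
    whenever P*n/100 is integral; tied cells share a rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    below = np.searchsorted(values[order], values, side="left")
    return 100.0 * below / len(values)


def bin_by_percentiles(
    scores: pd.Series, low_pct: float = 60.0, high_pct: float = 95.0
) -> tuple[pd.Series, dict[str, float]]:
    """Partition cells into low / mid / high score bins.

    low = strictly below the ``low_pct`` nearest-rank percentile;
    high = at or above the ``high_pct`` percentile (the "top 5%" with the
    default 95); mid = remainder.  Returns labels and the achieved bin
    fractions.
    """
    if low_pct >= high_pct:
        raise ConfigError(f"low_pct={low_pct} must be < high_pct={high_pct}")
    values = np.asarray(scores, dtype=float)
    if len(values) < 20:
        warnings.warn("fewer than 20 cells: percentile bins will be coarse")
    prank = _percentile_ranks(values)
    labels = np.where(
        prank < low_pct, "low", np.where(prank >= high_pct, "high", "mid")
    )
    fractions = {b: float((labels == b).mean()) for b in ("low", "mid", "high")}
    if len(np.unique(labels)) == 1:
        warnings.warn("degenerate bins: all cells fall in one bin (tied scores?)")
    return (
        pd.Series(labels, index=scores.index, name="bin"),
        fractions,
    )


def partition_naive_effector(
    naive_scores: pd.Series,
    effector_scores: pd.Series,
    effector_top_frac: float = 0.10,
) -> tuple[pd.Series, float]:
    """Split cells into naive vs effector by the effector-score top tail.

    Cells in the top ``effector_top_frac`` of the effector score are
    labeled effector (a conservative cut — only scores deviating clearly
    from background qualify); the rest naive.  Returns labels and the
    threshold used.
    """
    if not 0.0 < effector_top_frac < 1.0:
        raise ConfigError("effector_top_frac must be in (0, 1)")
    if not naive_scores.index.equals(effector_scores.index):
        raise ValueError("score vectors must cover the same cells")
    values = effector_scores.to_numpy(dtype=float)
    prank = _percentile_ranks(values)
    is_effector = prank >= 100.0 * (1 - effector_top_frac)
    threshold = float(values[is_effector].min()) if is_effector.any() else float("inf")
    labels = np.where(is_effector, "effector", "naive")
    logger.info(
        "partition_naive_effector: threshold=%.4f, effector fraction=%.3f",
        threshold, float((labels == "effector").mean()),
    )
    return pd.Series(labels, index=naive_scores.index, name="partition"), float(threshold)


def samplewise_signature_test(
    scores: pd.Series,
    sample_ids,
    subset_labels,
    group_labels,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-subset comparison of sample-mean scores between two groups.

    Scores are averaged within each sample × subset; sample×subset cells
    counts must strictly exceed ``min_cells`` to qualify.  Per subset, the
    qualifying sample means of the two groups are compared with a
    two-sided Wilcoxon rank-sum test.  Subsets where a group has no
    qualifying sample are flagged untestable (p = NaN).
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "sample": np.asarray(sample_ids),
            "subset": np.asarray(subset_labels),
            "group": np.asarray(group_labels),
        }
    )
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    per_sample = (
        df.groupby(["subset", "sample", "group"], sort=True)["score"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    qualifying = per_sample[per_sample["n"] > min_cells]
    rows = []
    for subset, block in qualifying.groupby("subset"):
        a = block.loc[block["group"] == groups[0], "mean"].to_numpy()
        b = block.loc[block["group"] == groups[1], "mean"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append((subset, len(a), len(b), np.nan, False))
            continue
        p = stats.ranksums(a, b).pvalue
        rows.append((subset, len(a), len(b), p, True))
    return pd.DataFrame(
        rows,
        columns=["subset", f"n_samples_{groups[0]}", f"n_samples_{groups[1]}",
                 "p", "testable"],
    ).set_index("subset")
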