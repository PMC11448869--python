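"""Clonotype fate-bias statistics.

A clonotype — the progeny of one naive T cell, identified by shared CDR3
sequences — occupies a region of the phenotypic manifold.  Its
*neighborhood weight vector* ``w_c`` is the mean of the diffusion-operator
rows ``A_i`` of its member cells: ``w_c = (1/n_c) * sum_{i in c} A_i``.
Since each ``A_i`` is a unit-normalized local neighborhood, ``w_c`` is a
probability vector over cells describing the phenotypic region the clone
occupies, and clones can be compared through it even when their member
cells never coincide.

Fate bias is then quantified three ways: (1) clustering the ``w_c``
vectors (cosine distance, k=10 by default) into clonotype groups;
(2) a ternary corroboration rule on each clone's (TH1, TFH, pTCM) member
fractions (>40% major fate and <20% of the opposing fate); and (3)
counting clonotypes in each of the seven nonempty fate combinations and
comparing to a clone-size-preserving permutation null (labels shuffled
over cells with the clone partition fixed; 500 permutations by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClonotypeTable, ConfigError, logger
from .diffusion import DiffusionOperator, GraphClusterer

PHENOTYPES = ("TH1", "TFH", "pTCM")
#: canonical order of the 7 nonempty fate combinations: singletons,
#: pairs, then the full triple, each in PHENOTYPES order.
COMBINATIONS = tuple(
    frozenset(combo)
    for r in (1, 2, 3)
    for combo in itertools.combinations(PHENOTYPES, r)
)


def combination_label(combo: frozenset) -> str:
    return "+".join(p for p in PHENOTYPES if p in combo)


@dataclass
class BiasThresholds:
    """Ternary corroboration thresholds for fate-biased clonotypes.

    A TH1-biased clone has a TH1 member fraction strictly above
    ``major_min`` (default 0.40) and a TFH fraction strictly below
    ``minor_max`` (default 0.20); TFH-biased is symmetric.  Only clones
    with at least ``min_clone_cells`` members (default 5) qualify.
    """

    major_min: float = 0.40
    minor_max: float = 0.20
    min_clone_cells: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_max < self.major_min <= 1.0:
            raise ConfigError("need 0 <= minor_max < major_min <= 1")
        if self.min_clone_cells < 1:
            raise ConfigError("min_clone_cells must be >= 1")


@dataclass
class NeighborhoodWeights:
    """Clone × cell matrix W whose rows are the w_c vectors (rows sum to 1)."""

    W: np.ndarray
    clone_ids: list[str]
    cell_ids: np.ndarray
    graph_params: dict = field(default_factory=dict)

    def row(self, clone_id) -> np.ndarray:
        return self.W[self.clone_ids.index(clone_id)]


def neighborhood_weights(
    graph: DiffusionOperator,
    clones: ClonotypeTable,
    cell_ids,
    min_clone_cells: int = 1,
) -> NeighborhoodWeights:
    """w_c = mean of the operator rows A_i over the clone's member cells.

    ``cell_ids`` gives the barcode of each graph node, in node order.
    A clone member missing from the graph is an error naming the clone —
    silently dropping cells would bias w_c.
    """
    cell_ids = np.asarray(cell_ids, dtype=object)
    pos = {b: i for i, b in enumerate(cell_ids)}
    P = graph.P_
    rows, ids = [], []
    for clone_id, members in clones.clones(min_cells=min_clone_cells):
        try:
            idx = np.array([pos[b] for b in members], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"clone {clone_id!r} has member {exc.args[0]!r} absent from the graph"
            ) from exc
        w = np.asarray(P[idx].mean(axis=0)).ravel()
        rows.append(w)
        ids.append(clone_id)
    if not rows:
        raise ValueError("no clones satisfy the size cutoff")
    return NeighborhoodWeights(
        W=np.stack(rows),
        clone_ids=ids,
        cell_ids=cell_ids,
        graph_params={"k": graph.k, "ka": graph.ka, "t": graph.t},
    )


class NeighborhoodClusterer(GraphClusterer):
    """Cosine-distance Phenograph-style clustering of w_c vectors (k=10)."""

    def __init__(self, k: int = 10, resolution: float = 1.0, random_state: int = 0):
        super().__init__(k=k, metric="cosine", resolution=resolution,
                         random_state=random_state)


def cluster_clonotype_neighborhoods(
    weights: NeighborhoodWeights, k: int = 10, seed: int = 0,
    resolution: float = 1.0,
) -> pd.Series:
    """Cluster clonotypes by the cosine similarity of their w_c vectors."""
    n = weights.W.shape[0]
    if n < k + 1:
        raise ValueError(
            f"only {n} qualifying clones for k={k}; use a smaller k"
        )
    labels = NeighborhoodClusterer(k=k, resolution=resolution, random_state=seed).fit_predict(
        weights.W
    )
    return pd.Series(labels, index=pd.Index(weights.clone_ids, name="clone_id"),
                     name="group")


def _phenotype_per_clone(
    clones: ClonotypeTable, phenotype_labels: pd.Series, min_clone_cells: int
):
    """Yield (clone_id, member phenotypes) over qualifying clones, keeping
    only members with a phenotype in PHENOTYPES.  The size cutoff applies
    to the count of in-fate members (cells outside the three fates are
    excluded upstream of all bias statistics)."""
    for clone_id, members in clones.clones(min_cells=1):
        phen = phenotype_labels.reindex(members).dropna()
        phen = phen[phen.isin(PHENOTYPES)]
        if len(phen) >= min_clone_cells:
            yield clone_id, phen.to_numpy(dtype=object)


def phenotype_proportions(
    clones: ClonotypeTable,
    phenotype_labels: pd.Series,
    min_clone_cells: int = 5,
) -> pd.DataFrame:
    """Per-clone (TH1, TFH, pTCM) member-fraction vectors (rows sum to 1).

    Only clones with at least ``min_clone_cells`` members among the three
    fates qualify (ternary-plot convention: "expanded clonotypes, >= 5
    cells" by default; pass 6 for the strict Methods reading).
    """
    bad = set(phenotype_labels.dropna().unique()) - set(PHENOTYPES)
    if bad:
        logger.info("phenotype_proportions: ignoring non-fate labels %s", sorted(bad))
    rows = {}
    for clone_id, phen in _phenotype_per_clone(clones, phenotype_labels, min_clone_cells):
        rows[clone_id] = [float((phen == p).mean()) for p in PHENOTYPES]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(PHENOTYPES)
    ).rename_axis("clone_id")


def rule_pass(props: pd.DataFrame, thresholds: BiasThresholds) -> pd.DataFrame:
    """Per-clone pass/fail of the two ternary bias rules (strict inequalities)."""
    return pd.DataFrame(
        {
            "TH1_rule": (props["TH1"] > thresholds.major_min)
            & (props["TFH"] < thresholds.minor_max),
            "TFH_rule": (props["TFH"] > thresholds.major_min)
            & (props["TH1"] < thresholds.minor_max),
        },
        index=props.index,
    )


def annotate_bias(
    group_labels: pd.Series,
    proportions: pd.DataFrame,
    thresholds: BiasThresholds | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label each clonotype group TH1_biased / TFH_biased / mixed.

    The group archetype is decided by its median clone: TH1_biased when
    the group's median TH1 fraction exceeds ``major_min`` and its median
    TFH fraction is below ``minor_max`` (TFH_biased symmetric; otherwise
    mixed).  Also returns the per-clone rule flags.
    """
    thresholds = thresholds or BiasThresholds()
    common = group_labels.index.intersection(proportions.index)
    if len(common) == 0:
        raise ValueError("no clones shared between group labels and proportions")
    group_labels = group_labels.loc[common]
    props = proportions.loc[common]
    flags = rule_pass(props, thresholds)
    annotations = {}
    for group, members in props.groupby(group_labels):
        if len(members) == 0:
            raise ValueError(f"group {group!r} is empty")
        med = members.median(axis=0)
        if med["TH1"] > thresholds.major_min and med["TFH"] < thresholds.minor_max:
            annotations[group] = "TH1_biased"
        elif med["TFH"] > thresholds.major_min and med["TH1"] < thresholds.minor_max:
            annotations[group] = "TFH_biased"
        else:
            annotations[group] = "mixed"
    return pd.Series(annotations, name="archetype").rename_axis("group"), flags


def combination_counts(
    clones: ClonotypeTable,
    phenotype_labels: pd.Series,
    min_clone_cells: int = 5,
) -> pd.Series:
    """Count qualifying clonotypes per nonempty fate combination.

    A clone is "represented" in a fate if one or more member cells carry
    it, so each clone lands in exactly one of the 7 nonempty subsets of
    {TH1, TFH, pTCM}; the counts therefore sum to the number of
    qualifying clones.
    """
    counts = {c: 0 for c in COMBINATIONS}
    for _, phen in _phenotype_per_clone(clones, phenotype_labels, min_clone_cells):
        combo = frozenset(np.unique(phen).tolist())
        counts[combo] += 1
    return pd.Series(
        {combination_label(c): counts[c] for c in COMBINATIONS}, name="n_clonotypes"
    )


def _counts_from_arrays(
    clone_slices: list[np.ndarray], labels: np.ndarray, min_clone_cells: int
) -> np.ndarray:
    """Combination counts over integer fate codes (0,1,2); -1 = non-fate."""
    out = np.zeros(len(COMBINATIONS), dtype=int)
    for idx in clone_slices:
        codes = labels[idx]
        codes = codes[codes >= 0]
        if len(codes) < min_clone_cells:
            continue
        mask = 0
        for c in codes:
            mask |= 1 << c
        out[_MASK_TO_SLOT[mask]] += 1
    return out


def _counts_sorted(
    codes_sorted: np.ndarray, starts: np.ndarray, min_clone_cells: int
) -> np.ndarray:
    """Vectorized combination counts for clone-contiguous fate codes.

    ``codes_sorted`` holds fate codes (0/1/2, -1 = non-fate) for cells
    sorted so each clone occupies one contiguous block beginning at the
    ``starts`` offsets."""
    in_fate = codes_sorted >= 0
    n_fate = np.add.reduceat(in_fate.astype(np.int64), starts)
    mask = np.zeros(len(starts), dtype=np.int64)
    for code in range(len(PHENOTYPES)):
        present = np.add.reduceat(
            (codes_sorted == code).astype(np.int64), starts
        ) > 0
        mask |= present.astype(np.int64) << code
    qualifying = n_fate >= min_clone_cells
    counts = np.bincount(mask[qualifying & (mask > 0)], minlength=8)
    return counts[_SLOT_ORDER]


# bitmask (bit p set ⇔ fate p present) → canonical combination slot
_MASK_TO_SLOT = {}
for slot, combo in enumerate(COMBINATIONS):
    m = 0
    for p_idx, p in enumerate(PHENOTYPES):
        if p in combo:
            m |= 1 << p_idx
    _MASK_TO_SLOT[m] = slot
# inverse: _SLOT_ORDER[i] = bitmask whose canonical slot is i (slot 0 of the
# bincount output, mask 0, is never emitted)
_SLOT_ORDER = np.array(
    [m for m, _ in sorted(_MASK_TO_SLOT.items(), key=lambda kv: kv[1])], dtype=int
)


@dataclass
class PermutationNull:
    """Observed vs clone-size-preserving-null combination counts.

    ``perm_counts`` is (n_perm × 7); ``expected`` its column means;
    ``deviation`` = observed − expected; ``p`` the +1-corrected two-sided
    empirical p-value per combination.
    """

    labels: list[str]
    observed: np.ndarray
    perm_counts: np.ndarray
    expected: np.ndarray
    sd: np.ndarray
    deviation: np.ndarray
    p: np.ndarray
    p_randomized: np.ndarray
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        lo, hi = np.percentile(self.perm_counts, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "observed": self.observed,
                "expected": self.expected,
                "sd": self.sd,
                "deviation": self.deviation,
                "perm_q2.5": lo,
                "perm_q97.5": hi,
                "p": self.p,
                "p_randomized": self.p_randomized,
            },
            index=pd.Index(self.labels, name="combination"),
        )


def permutation_test(
    clones: ClonotypeTable,
    phenotype_labels: pd.Series,
    n_perm: int = 500,
    seed: int = 0,
    min_clone_cells: int = 5,
) -> PermutationNull:
    """Clone-size-preserving permutation null for combination counts.

    Each permutation shuffles the multiset of phenotype labels over all
    clonotype-assigned cells without replacement, keeping the clone
    partition fixed — equivalent to drawing random clonotypes with the
    observed size distribution — then recounts fate combinations.  The
    empirical two-sided p per combination is
    ``(1 + #{|perm − exp| >= |obs − exp|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    assigned = clones.assignments.index
    labels = phenotype_labels.reindex(assigned)
    code_map = {p: i for i, p in enumerate(PHENOTYPES)}
    codes = np.array(
        [code_map.get(lab, -1) for lab in labels.to_numpy()], dtype=int
    )
    clone_ids = clones.assignments["clone_id"].to_numpy()
    order = np.argsort(clone_ids, kind="stable")
    sorted_clones = clone_ids[order]
    starts = np.flatnonzero(np.r_[True, sorted_clones[1:] != sorted_clones[:-1]])

    codes_sorted = codes[order]
    observed = _counts_sorted(codes_sorted, starts, min_clone_cells)
    perm_counts = np.empty((n_perm, len(COMBINATIONS)), dtype=int)
    work = codes_sorted.copy()
    for r in range(n_perm):
        rng.shuffle(work)
        perm_counts[r] = _counts_sorted(work, starts, min_clone_cells)
    expected = perm_counts.mean(axis=0)
    sd = perm_counts.std(axis=0)
    deviation = observed - expected
    abs_perm = np.abs(perm_counts - expected)
    abs_obs = np.abs(deviation)
    greater = (abs_perm > abs_obs[None, :]).sum(axis=0)
    ties = (abs_perm == abs_obs[None, :]).sum(axis=0)
    # conservative p: ties (and the observation itself) count as exceedances
    p = (1.0 + greater + ties) / (n_perm + 1.0)
    # tie-randomized p: exactly Uniform under the null despite the discrete
    # statistic (the observation is placed uniformly within its tie block)
    u = rng.random(len(COMBINATIONS))
    p_randomized = (greater + u * (ties + 1.0)) / (n_perm + 1.0)
    return PermutationNull(
        labels=[combination_label(c) for c in COMBINATIONS],
        observed=observed,
        perm_counts=perm_counts,
        expected=expected,
        sd=sd,
        deviation=deviation,
        p=p,
        p_randomized=p_randomized,
        n_perm=n_perm,
        seed=seed,
    )


def exhaustive_null(
    clone_sizes: list[int], phenotype_multiset: list[str], min_clone_cells: int = 1
) -> np.ndarray:
    """Exact expected combination counts by enumerating every distinct
    assignment of the label multiset to cells (feasible for <= ~8 cells).

    Serves as the independent oracle for :func:`permutation_test`.
    """
    code_map = {p: i for i, p in enumerate(PHENOTYPES)}
    labels = [code_map.get(p, -1) for p in phenotype_multiset]
    n = len(labels)
    if sum(clone_sizes) != n:
        raise ValueError("clone sizes must sum to the number of labels")
    slices = []
    start = 0
    for s in clone_sizes:
        slices.append(np.arange(start, start + s))
        start += s
    totals = np.zeros(len(COMBINATIONS), dtype=float)
    count = 0
    seen_orderings = set()
    for perm in itertools.permutations(labels, n):
        if perm in seen_orderings:
            continue
        seen_orderings.add(perm)
        totals += _counts_from_arrays(slices, np.array(perm), min_clone_cells)
        count += 1
    return totals / count
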