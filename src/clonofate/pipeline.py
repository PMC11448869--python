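"""End-to-end synthetic clonal fate-bias run, shared by the CLI and tests.

``run_synthetic_cohort`` wires the stages together on generated data:
simulate expression + planted clonotypes → QC → normalize → PCA →
adaptive diffusion operator → clonotype neighborhood weights → cosine
clustering of w_c → ternary corroboration → combination counts and the
clone-size-preserving permutation null.  All randomness flows from a
single seed, so two runs with the same seed produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .clonotype import (
    BiasThresholds,
    annotate_bias,
    cluster_clonotype_neighborhoods,
    combination_counts,
    neighborhood_weights,
    permutation_test,
    phenotype_proportions,
)
from .core import ClonotypeTable, CellMatrix, RunConfig, stage_timer
from .diffusion import DiffusionOperator, pca_reduce
from .preprocess import QCThresholds, normalize, qc_filter


@dataclass
class CohortResult:
    cells: CellMatrix
    clones: ClonotypeTable
    clone_truth: pd.DataFrame
    operator: DiffusionOperator
    groups: pd.Series
    archetypes: pd.Series
    proportions: pd.DataFrame
    rule_flags: pd.DataFrame
    combos: pd.Series
    null: "object"

    def group_of_archetype(self, archetype: str):
        """Groups annotated with the given archetype label."""
        return self.archetypes.index[self.archetypes == archetype].tolist()


def run_synthetic_cohort(
    seed: int = 0,
    n_per_fate: int = 900,
    n_naive: int = 300,
    clone_sizes=(5, 20),
    n_clones_per_archetype: int = 30,
    config: RunConfig | None = None,
) -> CohortResult:
    """Simulate a cohort with planted fate-bias archetypes and analyze it.

    ``clone_sizes`` is an inclusive (low, high) range; sizes are drawn
    uniformly so every clone passes the >=5-cell cutoff by construction.
    """
    config = config or RunConfig(seed=seed)
    rng = np.random.default_rng(seed)
    lo, hi = clone_sizes
    archetypes = simulate.default_archetypes(n_clones=n_clones_per_archetype)
    for spec in archetypes:
        spec.sizes = rng.integers(lo, hi + 1, size=spec.n_clones).tolist()

    with stage_timer("simulate", seed):
        cells, clones, truth = simulate.simulate_cohort(
            n_per_fate=n_per_fate,
            n_naive=n_naive,
            archetypes=archetypes,
            seed=int(rng.integers(2**31 - 1)),
        )
    with stage_timer("preprocess", seed):
        # generous QC so the planted cells all survive (they are clean by
        # construction); the filters still run for pipeline fidelity
        cells, _ = qc_filter(
            cells, QCThresholds(min_molecules=0, min_cells_per_gene=0)
        )
        cells = normalize(cells, config.dialect)
    with stage_timer("graph", seed):
        scores, _ = pca_reduce(cells, n_pcs=min(config.n_pcs, 20))
        op = DiffusionOperator(k=config.k, ka=config.ka, t=config.t).fit(scores)
    with stage_timer("clonotype_bias", seed):
        weights = neighborhood_weights(op, clones, cells.cell_ids)
        groups = cluster_clonotype_neighborhoods(
            weights, k=config.clonotype_k, seed=seed
        )
        phen = cells.cell_meta["state"]
        props = phenotype_proportions(
            clones, phen, min_clone_cells=config.min_clone_cells
        )
        arch, flags = annotate_bias(groups, props, BiasThresholds(
            min_clone_cells=config.min_clone_cells
        ))
        combos = combination_counts(
            clones, phen, min_clone_cells=config.min_clone_cells
        )
        null = permutation_test(
            clones, phen, n_perm=config.n_perm, seed=seed,
            min_clone_cells=config.min_clone_cells,
        )
    return CohortResult(
        cells=cells, clones=clones, clone_truth=truth, operator=op,
        groups=groups, archetypes=arch, proportions=props, rule_flags=flags,
        combos=combos, null=null,
    )


def write_cohort_outputs(result: CohortResult, out_dir) -> list[Path]:
    """Write the analysis tables as CSV; returns the paths (stable order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clone_table = pd.concat(
        [
            result.groups,
            result.groups.map(result.archetypes).rename("archetype"),
            result.proportions,
            result.rule_flags,
            result.clone_truth["archetype"].rename("true_archetype"),
        ],
        axis=1,
    ).sort_index()
    paths = []
    for name, frame in (
        ("clonotype_groups.csv", clone_table),
        ("combination_counts.csv", result.null.to_frame()),
        ("phenotype_proportions.csv", result.proportions.sort_index()),
    ):
        path = out / name
        frame.to_csv(path, float_format="%.10g")
        paths.append(path)
    return paths
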