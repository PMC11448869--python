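"""Synthetic expression + clonotype generators for pipeline fixtures.

The generators emulate the statistical structure of droplet scRNA-seq of
antigen-specific CD4 T cells with paired TCR clonotypes: negative-binomial
UMI counts over discrete cell states (naive, ISG+ naive, TH1, TFH, pTCM,
and a CD8 contaminant), per-cell library-size variation, Bernoulli
dropout, an optional smooth 1-D differentiation trajectory, and
clonotypes whose member phenotypes follow archetype-specific probability
vectors over the three effector fates with a long-tailed clone-size
distribution.

Everything is driven by ``numpy.random.Generator``; a fixed seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellMatrix, ClonotypeTable, ConfigError

DEFAULT_STATES = ("naive", "naive_ISG", "TH1", "TFH", "pTCM", "CD8")
FATES = ("TH1", "TFH", "pTCM")


@dataclass
class StateProgram:
    """Mean-expression program of one discrete cell state.

    ``means`` is the per-gene NB mean mu_gs (length = panel size);
    ``markers`` lists genes whose mean in this state strictly exceeds
    their mean in every other state (validated by
    :func:`validate_programs`).
    """

    name: str
    means: np.ndarray
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if not np.isfinite(self.means).all() or (self.means < 0).any():
            raise ConfigError(f"state {self.name}: means must be finite and >= 0")


def validate_programs(programs: dict[str, StateProgram], gene_ids) -> None:
    """Check the marker invariant: each marker's mean in its own state is
    strictly greater than its mean in every other state."""
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for name, prog in programs.items():
        for marker in prog.markers:
            j = gene_pos[marker]
            own = prog.means[j]
            for other, oprog in programs.items():
                if other != name and oprog.means[j] >= own:
                    raise ConfigError(
                        f"marker {marker} of {name} not dominant over {other}"
                    )


@dataclass
class SimConfig:
    """Knobs of the expression simulator.

    n_cells : cells per state.
    theta : NB dispersion (var = m + m^2/theta); ``inf`` gives Poisson.
    lib_sigma : sd of the log-normal per-cell library factor (log scale).
    dropout : extra Bernoulli zero-inflation rate in [0, 1).
    trajectory : if set, a (state_a, state_b) pair — cells get a latent
        pseudotime tau in [0,1] and means interpolated between the two
        anchor programs instead of discrete states.
    mito_frac : average fraction of counts placed on injected "mt-" genes
        (0 disables injection) — used to exercise QC filters.
    seed : RNG seed; fixed seed ⇒ bit-identical output.
    """

    n_cells: dict[str, int] = field(
        default_factory=lambda: {s: 200 for s in DEFAULT_STATES}
    )
    theta: float = 2.0
    lib_sigma: float = 0.25
    dropout: float = 0.1
    trajectory: tuple[str, str] | None = None
    mito_frac: float = 0.0
    n_mito_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if not 0.0 <= self.mito_frac < 1.0:
            raise ConfigError("mito_frac must be in [0, 1)")
        if any(n < 0 for n in self.n_cells.values()):
            raise ConfigError("negative cell counts")


@dataclass
class ArchetypeSpec:
    """A clonal fate-bias archetype.

    ``p`` is the phenotype probability vector over (TH1, TFH, pTCM); the
    defaults mirror the three canonical patterns: TH1-biased (0.7, 0.1,
    0.2), TFH-biased (0.1, 0.7, 0.2), mixed (0.4, 0.35, 0.25).  Clone
    sizes come from a zero-truncated geometric with parameter ``rho``
    (long tail) unless an explicit ``sizes`` list is given.
    """

    name: str
    p: tuple[float, float, float]
    n_clones: int = 30
    rho: float = 0.25
    sizes: list[int] | None = None
    min_size: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"archetype {self.name}: p must be a 3-simplex vector")
        if not 0 < self.rho < 1:
            raise ConfigError("rho must be in (0, 1)")
        if self.sizes is not None and len(self.sizes) != self.n_clones:
            raise ConfigError("sizes list length must equal n_clones")

    def draw_sizes(self, rng: np.random.Generator) -> np.ndarray:
        if self.sizes is not None:
            return np.asarray(self.sizes, dtype=int)
        sizes = rng.geometric(self.rho, size=self.n_clones)
        return np.maximum(sizes, self.min_size)


def default_archetypes(n_clones: int = 30, **kw) -> list[ArchetypeSpec]:
    return [
        ArchetypeSpec("TH1_biased", (0.7, 0.1, 0.2), n_clones=n_clones, **kw),
        ArchetypeSpec("TFH_biased", (0.1, 0.7, 0.2), n_clones=n_clones, **kw),
        ArchetypeSpec("mixed", (0.4, 0.35, 0.25), n_clones=n_clones, **kw),
    ]


def default_programs(
    n_genes: int = 200,
    n_markers: int = 20,
    base_mean: float = 0.5,
    marker_mean: float = 5.0,
    states=DEFAULT_STATES,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, StateProgram], list[str]]:
    """Build well-separated state programs over a synthetic gene panel.

    Each state receives a disjoint block of ``n_markers`` marker genes
    with mean ``marker_mean``; all other genes share a log-normal baseline
    around ``base_mean`` common to every state (so markers are the only
    systematic state differences).
    """
    rng = rng or np.random.default_rng(0)
    states = tuple(states)
    if n_markers * len(states) > n_genes:
        raise ConfigError("gene panel too small for the requested marker blocks")
    gene_ids = [f"g{j:04d}" for j in range(n_genes)]
    baseline = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    programs: dict[str, StateProgram] = {}
    for s_idx, state in enumerate(states):
        means = baseline.copy()
        block = slice(s_idx * n_markers, (s_idx + 1) * n_markers)
        means[block] = marker_mean
        programs[state] = StateProgram(
            name=state, means=means, markers=gene_ids[block]
        )
    validate_programs(programs, gene_ids)
    return programs, gene_ids


def _nb_counts(mean: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean, dispersion theta) via Gamma–Poisson; theta=inf → Poisson."""
    if np.isinf(theta):
        return rng.poisson(mean)
    shape = rng.gamma(theta, mean / theta)
    return rng.poisson(shape)


def simulate_expression(
    programs: dict[str, StateProgram],
    gene_ids,
    config: SimConfig,
    clones_demanding: dict[str, int] | None = None,
) -> CellMatrix:
    """Draw a count matrix from the state programs.

    Counts are NB(l_i * mu_gs, theta) with a log-normal per-cell library
    factor l_i, followed by Bernoulli dropout.  The true state label (and,
    for trajectory mode, the latent pseudotime tau) is recorded in
    ``cell_meta``; a ``lib_factor`` column records l_i.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = list(gene_ids)
    if clones_demanding:
        for state, demand in clones_demanding.items():
            if demand > 0 and config.n_cells.get(state, 0) == 0:
                raise ConfigError(
                    f"clones demand state {state!r} but zero cells requested"
                )

    if config.trajectory is not None:
        a, b = config.trajectory
        n_total = sum(config.n_cells.values())
        tau = np.sort(rng.uniform(0.0, 1.0, size=n_total))
        mean_matrix = (
            (1 - tau)[:, None] * programs[a].means[None, :]
            + tau[:, None] * programs[b].means[None, :]
        )
        states_per_cell = np.where(tau < 0.5, a, b).astype(object)
        meta_extra = {"tau": tau}
    else:
        states_per_cell = np.concatenate(
            [np.repeat(s, n) for s, n in config.n_cells.items() if n > 0]
        )
        n_total = len(states_per_cell)
        mean_matrix = np.stack([programs[s].means for s in states_per_cell])
        meta_extra = {}

    if config.mito_frac > 0:
        # mito genes carry mito_frac/(1-mito_frac) of the non-mito mean mass
        mito_total = mean_matrix.sum(axis=1) * config.mito_frac / (1 - config.mito_frac)
        mito_means = np.repeat(
            mito_total[:, None] / config.n_mito_genes, config.n_mito_genes, axis=1
        )
        mean_matrix = np.hstack([mean_matrix, mito_means])
        gene_ids = gene_ids + [f"mt-{j}" for j in range(config.n_mito_genes)]

    lib = rng.lognormal(0.0, config.lib_sigma, size=n_total)
    counts = _nb_counts(lib[:, None] * mean_matrix, config.theta, rng)
    if config.dropout > 0:
        keep = rng.random(counts.shape) >= config.dropout
        counts = counts * keep
    cell_ids = np.array([f"cell{j:05d}" for j in range(n_total)], dtype=object)
    meta = pd.DataFrame(
        {"state": states_per_cell, "lib_factor": lib, **meta_extra},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=np.array(gene_ids, dtype=object),
        cell_meta=meta,
    )


def simulate_clonotypes(
    archetypes: list[ArchetypeSpec],
    state_labels,
    cell_ids=None,
    seed: int = 0,
) -> tuple[ClonotypeTable, pd.DataFrame]:
    """Plant clonotypes over cells according to fate-bias archetypes.

    For each clone, the size is drawn from the archetype's distribution
    and each member's phenotype i.i.d. from its probability vector; the
    member is then matched to a random not-yet-assigned cell of that
    phenotype (phenotype-first assignment keeps clones dispersed across
    the manifold within a state).  Demanding more cells of a phenotype
    than exist raises rather than truncating silently.

    Returns the clonotype table and a per-clone truth table
    (clone_id, archetype, size).
    """
    rng = np.random.default_rng(seed)
    state_labels = np.asarray(state_labels, dtype=object)
    if cell_ids is None:
        cell_ids = np.array([f"cell{j:05d}" for j in range(len(state_labels))], dtype=object)
    cell_ids = np.asarray(cell_ids, dtype=object)

    pools = {
        fate: list(rng.permutation(np.flatnonzero(state_labels == fate)))
        for fate in FATES
    }
    rows, truth = [], []
    clone_counter = 0
    for spec in archetypes:
        sizes = spec.draw_sizes(rng)
        for size in sizes:
            clone_id = f"clone{clone_counter:04d}"
            clone_counter += 1
            fates = rng.choice(len(FATES), size=size, p=np.asarray(spec.p))
            for f_idx in fates:
                fate = FATES[f_idx]
                if not pools[fate]:
                    raise ConfigError(
                        f"exhausted cells of phenotype {fate!r} while placing "
                        f"{clone_id} (archetype {spec.name}); simulate more cells"
                    )
                cell_idx = pools[fate].pop()
                rows.append((cell_ids[cell_idx], clone_id))
            truth.append((clone_id, spec.name, int(size)))
    assignments = pd.DataFrame(rows, columns=["barcode", "clone_id"]).set_index("barcode")
    truth_df = pd.DataFrame(truth, columns=["clone_id", "archetype", "size"]).set_index(
        "clone_id"
    )
    return ClonotypeTable(assignments=assignments), truth_df


# ----------------------------------------------------------------------
# CD4/CD8 mixture for the marker-panel classifier

CD8_MARKERS = ("Cd8b", "Cd8a", "Ccl5", "Nkg7", "Gzmm")
CD4_MARKERS = ("Cd4", "Cd40lg", "Tnfrsf4", "Itgb1")


@dataclass
class CD4CD8Config:
    """Two-population T-cell mixture over the nine-gene marker panel.

    Marker genes of the cell's own lineage have mean ``on_mean``; the
    other lineage's markers leak at ``off_mean`` (cross-contamination /
    ambient counts); ``n_background`` extra genes are lineage-neutral.
    """

    n_cells: int = 1000
    cd4_fraction: float = 0.5
    on_mean: float = 4.0
    off_mean: float = 0.05
    background_mean: float = 1.0
    n_background: int = 50
    theta: float = 2.0
    lib_sigma: float = 0.25
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cd4_fraction <= 1.0:
            raise ConfigError("cd4_fraction must be in [0, 1]")
        if self.theta <= 0 or not 0 <= self.dropout < 1:
            raise ConfigError("invalid theta or dropout")


def simulate_cd4cd8(config: CD4CD8Config | None = None) -> CellMatrix:
    """Generate the CD4-like / CD8-like mixture with the nine-gene panel.

    The true population label is recorded in ``cell_meta['population']``.
    """
    config = config or CD4CD8Config()
    rng = np.random.default_rng(config.seed)
    n_cd4 = int(round(config.n_cells * config.cd4_fraction))
    labels = np.array(
        ["CD4"] * n_cd4 + ["CD8"] * (config.n_cells - n_cd4), dtype=object
    )
    gene_ids = list(CD8_MARKERS + CD4_MARKERS) + [
        f"bg{j:03d}" for j in range(config.n_background)
    ]
    means = np.empty((config.n_cells, len(gene_ids)))
    cd8_cols = np.arange(len(CD8_MARKERS))
    cd4_cols = np.arange(len(CD8_MARKERS), len(CD8_MARKERS) + len(CD4_MARKERS))
    bg_cols = np.arange(len(CD8_MARKERS) + len(CD4_MARKERS), len(gene_ids))
    is_cd4 = labels == "CD4"
    means[np.ix_(is_cd4, cd4_cols)] = config.on_mean
    means[np.ix_(is_cd4, cd8_cols)] = config.off_mean
    means[np.ix_(~is_cd4, cd8_cols)] = config.on_mean
    means[np.ix_(~is_cd4, cd4_cols)] = config.off_mean
    means[:, bg_cols] = config.background_mean
    lib = rng.lognormal(0.0, config.lib_sigma, size=config.n_cells)
    counts = _nb_counts(lib[:, None] * means, config.theta, rng)
    if config.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout)
    order = rng.permutation(config.n_cells)
    counts, labels = counts[order], labels[order]
    cell_ids = np.array([f"cell{j:05d}" for j in range(config.n_cells)], dtype=object)
    meta = pd.DataFrame(
        {"population": labels}, index=pd.Index(cell_ids, name="cell_id")
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=np.array(gene_ids, dtype=object),
        cell_meta=meta,
    )


# ----------------------------------------------------------------------
# convenience cohort builders used by tests and the acceptance pipeline


def simulate_cohort(
    n_per_fate: int = 900,
    n_naive: int = 300,
    archetypes: list[ArchetypeSpec] | None = None,
    n_genes: int = 200,
    seed: int = 0,
    **sim_kw,
) -> tuple[CellMatrix, ClonotypeTable, pd.DataFrame]:
    """Expression + planted clonotypes in one call (the t1/t2 condition).

    ~3*n_per_fate effector cells plus naive background; default archetypes
    30 clones each.  Returns (cells, clonotypes, clone truth table).
    """
    rng = np.random.default_rng(seed)
    programs, gene_ids = default_programs(
        n_genes=n_genes, states=("naive", "TH1", "TFH", "pTCM"), rng=rng
    )
    config = SimConfig(
        n_cells={"naive": n_naive, "TH1": n_per_fate, "TFH": n_per_fate, "pTCM": n_per_fate},
        seed=int(rng.integers(2**31 - 1)),
        **sim_kw,
    )
    cells = simulate_expression(programs, gene_ids, config)
    archetypes = archetypes if archetypes is not None else default_archetypes()
    clones, truth = simulate_clonotypes(
        archetypes,
        cells.cell_meta["state"].to_numpy(),
        cell_ids=cells.cell_ids,
        seed=int(rng.integers(2**31 - 1)),
    )
    return cells, clones, truth


def simulate_trajectory(
    n_cells: int = 1000,
    n_genes: int = 200,
    theta: float = 2.0,
    dropout: float = 0.2,
    lib_sigma: float = 0.25,
    seed: int = 0,
) -> CellMatrix:
    """Smooth 1-D differentiation trajectory over a latent pseudotime.

    Each gene follows its own smooth mean curve along tau in [0, 1]:
    a sigmoidal switch (on- or off-going, random midpoint and steepness)
    or a transient bell-shaped pulse, on top of a log-normal baseline —
    the canonical behaviors of genes along a differentiation continuum.
    Counts are NB with dispersion ``theta``, a log-normal library factor,
    and Bernoulli dropout.  ``tau`` is recorded in ``cell_meta``.
    """
    rng = np.random.default_rng(seed)
    tau = np.sort(rng.uniform(0.0, 1.0, size=n_cells))
    baseline = 0.5 * rng.lognormal(0.0, 0.5, size=n_genes)
    amplitude = 3.0 * rng.lognormal(0.0, 0.4, size=n_genes)
    center = rng.uniform(0.1, 0.9, size=n_genes)
    steepness = rng.uniform(5.0, 15.0, size=n_genes)
    kind = rng.integers(0, 3, size=n_genes)  # 0 up, 1 down, 2 pulse
    curve = np.empty((n_cells, n_genes))
    for j in range(n_genes):
        z = steepness[j] * (tau - center[j])
        if kind[j] == 0:
            shape = 1.0 / (1.0 + np.exp(-z))
        elif kind[j] == 1:
            shape = 1.0 / (1.0 + np.exp(z))
        else:
            shape = np.exp(-(z**2) / 2.0)
        curve[:, j] = baseline[j] + amplitude[j] * shape
    lib = rng.lognormal(0.0, lib_sigma, size=n_cells)
    counts = _nb_counts(lib[:, None] * curve, theta, rng)
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)
    cell_ids = np.array([f"cell{j:05d}" for j in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {"tau": tau, "lib_factor": lib},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=np.array([f"g{j:04d}" for j in range(n_genes)], dtype=object),
        cell_meta=meta,
    )
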