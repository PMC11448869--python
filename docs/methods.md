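# Methods

This note documents the models and procedures `clonofate` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedure left genuine
freedom.

## Diffusion operator

Cells are embedded by PCA of the log-normalized expression matrix (genes
centered; deterministic sign convention: each component's
largest-magnitude loading is positive). On the top `n_pcs` scores
(default 20) a kNN graph is built with `k` neighbors per cell (default
30, self excluded). The adaptive bandwidth of cell *i* is the Euclidean
distance to its `ka`-th neighbor (default 10), giving the anisotropic
kernel

    K_ij = exp(−(d_ij / σ_i)²)   for j among i's k nearest neighbors.

`K` is symmetrized as `(K + Kᵀ)/2`, a self-affinity of 1 is placed on the
diagonal, and rows are normalized to the row-stochastic operator
`P = D⁻¹K`. Duplicate points would give `σ_i = 0`; the bandwidth then
falls back to the smallest positive neighbor distance with a warning, and
fully degenerate input (all points identical) is an error.

**Imputation** is `P^t·X` with `t` applications of the sparse operator
(default t=4; `t=0` is the identity). Because `P` is row-stochastic,
constant genes are exact fixed points, the map is linear, and as `t → ∞`
every gene converges to its stationary-weighted mean (`π ∝` row sums of
`K`). These invariants, plus equality with a dense brute-force
construction for n ≤ 50, are asserted in the test suite.

**Diffusion maps** come from the symmetric conjugate
`S = D^{1/2} P D^{−1/2}` (numerically stable, real spectrum). The trivial
λ=1 pair is dropped; eigenvectors are mapped back (`ψ = D^{−1/2} v`),
normalized under the stationary inner product, and sign-fixed. On a
disconnected graph a per-component map is computed with a warning.
**Diffusion distances** are Euclidean distances in multiscale coordinates
`ψ_l · λ_l/(1−λ_l)` — the all-times aggregate rather than a fixed-power
weighting, chosen because it needs no extra time parameter; group
distances are centroid distances by default (mean pairwise available).

**Parameter stability.** Imputed values should be insensitive to
reasonable `ka` and `t`. On the smooth synthetic trajectory (below) the
average per-gene Pearson correlation between imputed matrices across
ka ∈ {5, 10, 20} (t=4) and t ∈ {3, 4, 11} (ka=10) stays ≈ 0.95 for every
pair of settings; the most divergent pair is t=3 vs t=11, as expected
since it compares the least with the most smoothing.

## Community detection

Cell clustering follows the Phenograph recipe: kNN lists (k=30 by
default, deliberately small enough to capture small discrete populations
at the cost of over-splitting continuous regions), a shared-neighbor
graph weighted by the Jaccard overlap of (self-inclusive) neighbor lists,
and seeded modularity optimization (Leiden, RB-configuration at
resolution 1.0). Given a seed the partition is deterministic.

## Clonotype fate-bias statistics

For clone *c* with *n_c* member cells, the neighborhood weight vector is

    w_c = (1/n_c) Σ_{i∈c} A_i,

where `A_i` is row *i* of `P` — each member's unit-normalized local
diffusion neighborhood. `w_c` is itself a probability vector over cells
and represents the clone's occupied region of the phenotypic manifold;
two clones can be compared through it even when their members never
coincide. Clones are clustered on `w_c` under cosine distance (k=10,
same SNN/Leiden machinery), and each group is annotated by its median
clone: TH1-biased if the group's median T_H1 member fraction strictly
exceeds 0.40 while its median T_FH fraction is strictly below 0.20
(TFH-biased symmetric; otherwise mixed). The group-median rule is an
automated stand-in for annotation by inspection; the per-clone rule flags
are also returned so the corroboration can be examined clone by clone.

The expansion cutoff defaults to clones with ≥5 cells (configurable; a
strict >5 reading is available). Cells whose phenotype is outside
{T_H1, T_FH, pT_CM} are excluded before proportions and combination
counts.

**Combination counting and the permutation null.** Each qualifying clone
is assigned to the subset of fates in which it has at least one member
cell — one of 7 nonempty combinations, so counts partition the clones.
The null model shuffles the multiset of phenotype labels across all
clonotype-assigned cells without replacement, keeping the clone partition
fixed (equivalent to redrawing clonotypes with the observed size
distribution), and recounts; 500 permutations by default. Reported per
combination: observed, expected (permutation mean), permutation SD and
2.5/97.5% band, the deviation obs − exp, and two empirical two-sided
p-values:

- `p` — the conservative `(1 + #{|perm−exp| ≥ |obs−exp|}) / (n_perm+1)`,
  which counts ties as exceedances and can never be zero;
- `p_randomized` — the tie-randomized version (the observation is placed
  uniformly within its tie block, seeded). On a discrete statistic the
  conservative p rejects well below nominal level (measured ≈ 0.02 at
  nominal 0.05 on null cohorts, because combination counts are small
  integers with heavy tie mass); the randomized p is exactly uniform
  under the null and is the one to use when calibrated error rates
  matter. Both are deterministic given the seed.

An exhaustive-enumeration oracle (all distinct assignments of the label
multiset, feasible to ~8 cells) validates the Monte-Carlo expectations in
the tests.

**Limits of archetype recovery.** With archetype probability vectors
(0.7, 0.1, 0.2) / (0.1, 0.7, 0.2) / (0.4, 0.35, 0.25), the mixed
archetype is *not* separable from the two biased ones at realistic clone
sizes: a Bayes-optimal classifier on the true per-clone fate draws
reaches only ARI ≈ 0.65 at clone sizes 5–20, and in the ideal large-clone
limit the cosine between a mixed and a biased `w_c` is still ≈ 0.85, so
the mixed clones form a bridge between the two biased groups rather than
a separate community. The TH1-biased vs TFH-biased dichotomy, by
contrast, is recovered essentially perfectly, and the ternary
corroboration of the TH1-biased group (median T_H1 > 40%, median
T_FH < 20%) holds with wide margin. Interpretations of the "mixed" label
on real data should keep this identifiability limit in mind.

## Preprocessing

QC removes cells with mitochondrial fraction > 0.20 or total molecules
< 500 (both strict, applied in that order; an optional min-genes-per-cell
complexity filter is off by default because no canonical cutoff exists),
then genes expressed in ≤ 10 cells (a 1,000-cell variant suits large
blood cohorts). Two normalization dialects are implemented exactly:
median-scaled log2 with pseudocount 0.1, and counts-per-10k log2 with
pseudocount 1. HVG selection ranks genes by variance/mean of log values,
z-scored within 20 equal-count mean-expression bins; with multiple
samples, per-sample rankings are combined by summed rank. Differential
expression is a per-gene two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg correction — a deliberate, documented stand-in for a
hurdle-model test with a detected-genes covariate, which is out of scope;
the pass thresholds are exact and strict (FDR below 1e-10 or 0.01
depending on preset, |log2FC| > 0.5 computed as the difference of group
means on the log layer).

## Signatures and partitions

A signature score is the mean over signature genes of the per-gene
z-score (population denominator; n−1 available) of imputed expression;
absent genes are reported, zero-variance genes dropped with a warning.
Percentile binning uses empirical percentile ranks
(100 · #{strictly below}/n): low = rank < 60, high = rank ≥ 95, so on
distinct scores the bins hit the requested fractions exactly and the
binning is invariant to monotone transforms. The naive/effector partition
takes the top 10% of the effector score as effector — the conservative
"deviates clearly from background" reading. The sample-wise comparison
averages scores within sample × subset, keeps sample×subset pairs with
strictly more than 10 cells, and compares sample means between two groups
with a two-sided Wilcoxon rank-sum test per subset; subsets where a group
has no qualifying sample are flagged untestable rather than silently
dropped.

## CD4/CD8 classifier

Per sample: cp10k → log2(x+1) → per-gene z-score restricted to the
nine-gene panel; the composite score is the first principal-component
score, sign-fixed so CD4-proxy cells average higher than CD8-proxy cells.
Proxy labels use raw counts: CD4 proxy = Cd4 > 0 with Cd8a = Cd8b = 0;
CD8 proxy = Cd8a or Cd8b > 0 with Cd4 = 0 ("expression" is count > 0,
the simplest reading of mutual exclusivity). The threshold sweep
evaluates MCC at every midpoint between consecutive distinct scores plus
±∞ (so the sweep is exhaustive by construction — no better threshold
exists for the rule `score > θ → CD4`), breaking MCC ties toward higher
balanced accuracy, then the smaller threshold, for determinism. MCC is
evaluated on proxy cells only; the fitted criterion is then extended to
all cells. Samples with fewer than 3 proxy cells are flagged unfit.

## Concordance

Cluster centroids are computed per dataset on a shared gene set, each
gene z-scored *across that dataset's centroids* (removing per-dataset
location/scale), and Pearson r taken for every cross-dataset cluster
pair; replicate clusters are matched automatically by maximum-weight
bipartite assignment on the correlation matrix. The overlap coefficient
is |A∩B|/min(|A|,|B|); the adjusted Rand index uses the standard
permutation-model correction.

## Synthetic data

`simulate_expression` draws counts `NB(ℓ_i · μ_gs, θ)` — Gamma–Poisson
with dispersion θ (default 2, a typical droplet-data value; θ=∞ gives
Poisson) — with a log-normal library factor (σ=0.25) and Bernoulli
dropout (default 0.1). States get disjoint marker blocks (default 20
genes at mean 5 against a log-normal baseline around 0.5), validated so
every marker is strictly dominant in its own state. `simulate_clonotypes`
draws clone sizes (zero-truncated geometric, ρ=0.25, or explicit lists),
draws each member's fate i.i.d. from the archetype's probability vector,
and matches members to random unassigned cells of that fate —
phenotype-first assignment keeps clones dispersed within a state, which
keeps `w_c` nondegenerate. Exhausting a fate's cells is an explicit
error. `simulate_trajectory` gives each gene a smooth mean curve along a
latent pseudotime (sigmoidal on/off switches with random midpoints and
steepness 5–15, or transient Gaussian pulses, amplitude ≈ 3 over
baseline ≈ 0.5) — the canonical behaviors of genes along a
differentiation continuum; a trajectory in which most genes were flat
would measure noise smoothing rather than operator stability.
`simulate_cd4cd8` mixes two populations over the nine-gene panel
(own-lineage markers at mean 4, cross-lineage leak at 0.05, 50
lineage-neutral background genes at mean 1).

What the generators do *not* emulate: transcriptome-wide gene–gene
correlation beyond state/trajectory structure, batch effects, doublets,
ambient RNA profiles, or V(D)J sequence structure (clone ids are opaque).
Passing tests therefore demonstrate correctness of the statistics and
their implementation under the stated generative assumptions, not
robustness to those artifacts.

## Problem sizes and determinism

The bundled end-to-end runs use ~3,000-cell cohorts with 90 planted
clonotypes, 1,000-cell mixtures for the classifier, and 1,000 × 200
trajectories for imputation stability — sizes at which every statistic is
well within its asymptotic regime while a full run completes in seconds.
All stochastic stages take explicit seeds (numpy `default_rng`,
leidenalg partition seeds); a fixed seed reproduces every output
bit-for-bit, and the CLI prints SHA-256 checksums of its outputs so runs
can be compared at a glance.
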