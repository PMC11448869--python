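"""Neighborhood weights, bias annotation, combination counts, permutation null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonofate.clonotype import (
    BiasThresholds,
    annotate_bias,
    cluster_clonotype_neighborhoods,
    combination_counts,
    exhaustive_null,
    neighborhood_weights,
    permutation_test,
    phenotype_proportions,
    rule_pass,
)
from clonofate.core import ClonotypeTable, ConfigError
from clonofate.diffusion import DiffusionOperator, pca_reduce
from clonofate.preprocess import QCThresholds, normalize, qc_filter

from conftest import make_clonotypes


@pytest.fixture(scope="module")
def cohort_graph(small_cohort):
    cells, clones, truth = small_cohort
    cells, _ = qc_filter(cells, QCThresholds(min_molecules=0, min_cells_per_gene=0))
    cells = normalize(cells)
    X, _ = pca_reduce(cells, n_pcs=20)
    op = DiffusionOperator(k=30, ka=10, t=4).fit(X)
    return cells, clones, truth, op


class TestNeighborhoodWeights:
    def test_singleton_clone_equals_operator_row(self, cohort_graph):
        cells, clones, _, op = cohort_graph
        barcode = clones.assignments.index[0]
        singleton = make_clonotypes({"solo": [barcode]})
        w = neighborhood_weights(op, singleton, cells.cell_ids)
        node = list(cells.cell_ids).index(barcode)
        assert np.allclose(w.W[0], op.P_[node].toarray().ravel())

    def test_rows_sum_to_one(self, cohort_graph):
        cells, clones, _, op = cohort_graph
        w = neighborhood_weights(op, clones, cells.cell_ids)
        assert np.abs(w.W.sum(axis=1) - 1.0).max() < 1e-10
        assert (w.W >= 0).all()

    def test_mean_of_member_rows(self, cohort_graph):
        cells, clones, _, op = cohort_graph
        clone_id = clones.clone_sizes.index[0]
        members = clones.members(clone_id)
        w = neighborhood_weights(op, clones, cells.cell_ids)
        pos = [list(cells.cell_ids).index(b) for b in members]
        expected = np.asarray(op.P_[pos].mean(axis=0)).ravel()
        assert np.allclose(w.row(clone_id), expected)

    def test_permutation_equivariance_under_cell_reorder(self, rng):
        X = rng.normal(size=(30, 3))
        ids = np.array([f"b{i}" for i in range(30)], dtype=object)
        clones = make_clonotypes({"c1": ["b0", "b5", "b9"], "c2": ["b3", "b4"]})
        op = DiffusionOperator(k=5, ka=2).fit(X)
        w = neighborhood_weights(op, clones, ids)
        perm = rng.permutation(30)
        op2 = DiffusionOperator(k=5, ka=2).fit(X[perm])
        w2 = neighborhood_weights(op2, clones, ids[perm])
        inv = np.argsort(perm)
        assert np.allclose(w.W, w2.W[:, inv], atol=1e-10)

    def test_member_absent_from_graph_names_clone(self, cohort_graph):
        cells, _, _, op = cohort_graph
        clones = make_clonotypes({"ghost": ["nonexistent-barcode"]})
        with pytest.raises(ValueError, match="ghost"):
            neighborhood_weights(op, clones, cells.cell_ids)


class TestClonotypeClustering:
    def test_planted_bias_dichotomy_recovered(self, cohort_graph):
        """TH1- and TFH-biased clones form distinct clonotype groups.

        The mixed archetype sits between the two biased archetypes in
        cosine space (ideal-limit cosine ~0.85 to each) and is not
        separable at realistic clone sizes, so recovery is asserted on
        the biased dichotomy, which is the planted signal that survives
        clone-level sampling noise.
        """
        cells, clones, truth, op = cohort_graph
        w = neighborhood_weights(op, clones, cells.cell_ids, min_clone_cells=5)
        groups = cluster_clonotype_neighborhoods(w, k=10, seed=0)
        joined = truth.join(groups, how="inner")
        biased = joined[joined["archetype"] != "mixed"]
        ari = adjusted_rand_score(biased["archetype"], biased["group"])
        assert ari >= 0.8

    def test_duplicating_rows_preserves_partition(self, cohort_graph):
        cells, clones, _, op = cohort_graph
        w = neighborhood_weights(op, clones, cells.cell_ids, min_clone_cells=5)
        groups = cluster_clonotype_neighborhoods(w, k=10, seed=0)
        w.W = np.vstack([w.W, w.W])
        w.clone_ids = w.clone_ids + [f"{c}_dup" for c in w.clone_ids]
        doubled = cluster_clonotype_neighborhoods(w, k=10, seed=0)
        half = len(groups)
        ari = adjusted_rand_score(
            doubled.iloc[:half], doubled.iloc[half:]
        )
        assert ari == 1.0

    def test_cosine_scale_invariance(self, cohort_graph, rng):
        cells, clones, _, op = cohort_graph
        w = neighborhood_weights(op, clones, cells.cell_ids, min_clone_cells=5)
        base = cluster_clonotype_neighborhoods(w, k=10, seed=1)
        w.W = w.W * 37.5
        scaled = cluster_clonotype_neighborhoods(w, k=10, seed=1)
        assert adjusted_rand_score(base, scaled) == 1.0

    def test_too_few_clones_error(self, cohort_graph):
        cells, clones, _, op = cohort_graph
        w = neighborhood_weights(op, clones, cells.cell_ids, min_clone_cells=5)
        w.W, w.clone_ids = w.W[:5], w.clone_ids[:5]
        with pytest.raises(ValueError, match="smaller k"):
            cluster_clonotype_neighborhoods(w, k=10, seed=0)


class TestProportionsAndBias:
    def test_proportions_example(self):
        clones = make_clonotypes({"c1": [f"b{i}" for i in range(5)]})
        phen = pd.Series(
            ["TH1", "TH1", "TFH", "pTCM", "pTCM"],
            index=[f"b{i}" for i in range(5)],
        )
        props = phenotype_proportions(clones, phen, min_clone_cells=5)
        assert np.allclose(props.loc["c1"], [0.4, 0.2, 0.4])

    def test_pure_clone_and_size_cutoff(self):
        clones = make_clonotypes(
            {"big": [f"b{i}" for i in range(5)], "small": [f"s{i}" for i in range(4)]}
        )
        phen = pd.Series(
            ["TH1"] * 9, index=[f"b{i}" for i in range(5)] + [f"s{i}" for i in range(4)]
        )
        props = phenotype_proportions(clones, phen, min_clone_cells=5)
        assert list(props.index) == ["big"]
        assert np.allclose(props.loc["big"], [1.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "vec,th1_ok",
        [
            ((0.5, 0.1, 0.4), True),    # satisfies >40% TH1, <20% TFH
            ((1 / 3, 1 / 3, 1 / 3), False),
            ((0.40, 0.10, 0.50), False),  # boundary: strict >
            ((0.45, 0.20, 0.35), False),  # boundary: strict <
        ],
    )
    def test_ternary_rule_boundaries(self, vec, th1_ok):
        props = pd.DataFrame([vec], columns=["TH1", "TFH", "pTCM"], index=["c"])
        flags = rule_pass(props, BiasThresholds())
        assert bool(flags.loc["c", "TH1_rule"]) is th1_ok

    def test_group_annotation_by_median_clone(self):
        props = pd.DataFrame(
            {
                "TH1": [0.7, 0.6, 0.1, 0.05, 0.35, 0.3],
                "TFH": [0.1, 0.15, 0.7, 0.8, 0.35, 0.3],
                "pTCM": [0.2, 0.25, 0.2, 0.15, 0.3, 0.4],
            },
            index=[f"c{i}" for i in range(6)],
        )
        groups = pd.Series([0, 0, 1, 1, 2, 2], index=props.index)
        arch, flags = annotate_bias(groups, props)
        assert arch.to_dict() == {0: "TH1_biased", 1: "TFH_biased", 2: "mixed"}
        assert flags.loc["c0", "TH1_rule"] and not flags.loc["c4", "TH1_rule"]

    def test_thresholds_validated(self):
        with pytest.raises(ConfigError):
            BiasThresholds(major_min=0.2, minor_max=0.4)


class TestCombinationCounts:
    def test_hand_enumerated_toy(self):
        clones = make_clonotypes(
            {
                "c1": ["a1", "a2", "a3", "a4", "a5"],
                "c2": ["b1", "b2", "b3", "b4", "b5"],
                "c3": ["c1_", "c2_", "c3_", "c4_", "c5_"],
                "c4": ["d1", "d2", "d3", "d4", "d5"],
            }
        )
        phen = pd.Series(
            ["TH1"] * 5                                  # c1: {TH1}
            + ["TH1"] * 5                                # c2: {TH1}
            + ["TH1", "TFH", "TH1", "TFH", "TH1"]        # c3: {TH1,TFH}
            + ["TH1", "TFH", "pTCM", "TH1", "TFH"],      # c4: all three
            index=list(clones.assignments.index),
        )
        counts = combination_counts(clones, phen, min_clone_cells=5)
        assert counts.tolist() == [2, 0, 0, 1, 0, 0, 1]

    def test_membership_rule_single_cell_suffices(self):
        clones = make_clonotypes({"c": ["x1", "x2", "x3", "x4", "x5"]})
        phen = pd.Series(
            ["TH1", "TH1", "TH1", "TH1", "pTCM"], index=clones.assignments.index
        )
        counts = combination_counts(clones, phen, min_clone_cells=5)
        assert counts["TH1+pTCM"] == 1

    def test_counts_partition_qualifying_clones(self, small_cohort):
        cells, clones, _ = small_cohort
        phen = cells.cell_meta["state"]
        counts = combination_counts(clones, phen, min_clone_cells=5)
        n_qualifying = sum(
            1
            for _, members in clones.clones()
            if phen.reindex(members).isin(["TH1", "TFH", "pTCM"]).sum() >= 5
        )
        assert counts.sum() == n_qualifying


class TestPermutationNull:
    def _tiny(self):
        clones = make_clonotypes({"c1": ["b0", "b1"], "c2": ["b2"], "c3": ["b3"]})
        phen = pd.Series(["TH1", "TH1", "TFH", "pTCM"],
                         index=["b0", "b1", "b2", "b3"])
        return clones, phen

    def test_exhaustive_oracle_matches_monte_carlo(self):
        """Expected counts from enumerating all 12 distinct assignments of
        the label multiset equal the Monte-Carlo means within 3 SE."""
        clones, phen = self._tiny()
        exact = exhaustive_null([2, 1, 1], ["TH1", "TH1", "TFH", "pTCM"],
                                min_clone_cells=1)
        null = permutation_test(clones, phen, n_perm=5000, seed=0,
                                min_clone_cells=1)
        se = null.perm_counts.std(axis=0, ddof=1) / np.sqrt(null.n_perm)
        assert (np.abs(null.expected - exact) <= 3 * np.maximum(se, 1e-12)).all()

    @pytest.mark.parametrize("trial", range(4))
    def test_oracle_equivalence_on_small_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        sizes = rng.integers(1, 4, size=rng.integers(2, 4)).tolist()
        n = int(sum(sizes))
        if n > 8:
            sizes[-1] -= n - 8
            n = 8
        labels = rng.choice(["TH1", "TFH", "pTCM"], size=n).tolist()
        cells = [f"b{i}" for i in range(n)]
        mapping, start = {}, 0
        for j, s in enumerate(sizes):
            mapping[f"c{j}"] = cells[start : start + s]
            start += s
        clones = make_clonotypes(mapping)
        phen = pd.Series(labels, index=cells)
        exact = exhaustive_null(sizes, labels, min_clone_cells=1)
        null = permutation_test(clones, phen, n_perm=4000,
                                seed=int(rng.integers(2**31 - 1)),
                                min_clone_cells=1)
        se = null.perm_counts.std(axis=0, ddof=1) / np.sqrt(null.n_perm)
        assert (np.abs(null.expected - exact) <= 3 * np.maximum(se, 1e-9)).all()

    def test_identical_labels_degenerate_null(self):
        clones = make_clonotypes({"c1": ["b0", "b1"], "c2": ["b2", "b3"]})
        phen = pd.Series(["TH1"] * 4, index=["b0", "b1", "b2", "b3"])
        null = permutation_test(clones, phen, n_perm=50, seed=0,
                                min_clone_cells=1)
        assert (null.perm_counts == null.observed[None, :]).all()
        assert (null.p == 1.0).all()

    def test_seed_determinism_bit_identical(self):
        clones, phen = self._tiny()
        a = permutation_test(clones, phen, n_perm=100, seed=7, min_clone_cells=1)
        b = permutation_test(clones, phen, n_perm=100, seed=7, min_clone_cells=1)
        assert np.array_equal(a.perm_counts, b.perm_counts)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.p_randomized, b.p_randomized)

    def test_counts_sum_to_qualifying_clones_each_permutation(self, small_cohort):
        cells, clones, _ = small_cohort
        phen = cells.cell_meta["state"]
        null = permutation_test(clones, phen, n_perm=50, seed=1,
                                min_clone_cells=5)
        # fate-label multiset is fixed, clone partition fixed → the number
        # of qualifying clones is identical across permutations
        sums = null.perm_counts.sum(axis=1)
        assert (sums == sums[0]).all()

    def test_invalid_n_perm(self):
        clones, phen = self._tiny()
        with pytest.raises(ConfigError):
            permutation_test(clones, phen, n_perm=0)

    def test_planted_enrichment_detected(self):
        """Cohorts with an excess of TFH+pTCM-restricted clones show
        obs − exp > 2 permutation SD for that combination in >=90% of
        simulations."""
        rng = np.random.default_rng(2024)
        detected = 0
        n_sims = 20
        for _ in range(n_sims):
            mapping, labels, idx = {}, [], 0
            for j in range(60):
                size = int(rng.integers(5, 11))
                if j < 18:   # enriched archetype: TFH/pTCM only
                    phens = rng.choice(["TFH", "pTCM"], size=size, p=[0.6, 0.4])
                    # ensure both fates present so the clone lands in TFH+pTCM
                    phens[0], phens[1] = "TFH", "pTCM"
                else:
                    phens = rng.choice(["TH1", "TFH", "pTCM"], size=size,
                                       p=[0.4, 0.35, 0.25])
                cells = [f"b{idx + i}" for i in range(size)]
                idx += size
                mapping[f"c{j}"] = cells
                labels.extend(phens.tolist())
            clones = make_clonotypes(mapping)
            phen = pd.Series(labels, index=[f"b{i}" for i in range(idx)])
            null = permutation_test(clones, phen, n_perm=100,
                                    seed=int(rng.integers(2**31 - 1)),
                                    min_clone_cells=5)
            slot = null.labels.index("TFH+pTCM")
            if null.deviation[slot] > 2 * null.sd[slot]:
                detected += 1
        assert detected >= 0.9 * n_sims
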