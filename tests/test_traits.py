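"""PGLS machinery, AICc arithmetic, model enumeration and averaging."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from altishift.errors import AltishiftError, RankDeficiencyError
from altishift.phylo import consensus_with_lengths, grafen_lengths, phylo_covariance
from altishift.simulate import SimulationConfig, generate_traits_and_tree
from altishift.traits import (HYPOTHESIS_GROUPS, PglsFit, aicc, design_matrix,
                              enumerate_models, fit_trait_models, model_average,
                              pgls_fit, standardize_traits)


def star_tree(n, length=1.0):
    names = [f"t{i}" for i in range(n)]
    newick = "(" + ",".join(f"{x}:{length}" for x in names) + ");"
    return dendropy.Tree.get(data=newick, schema="newick"), names


def balanced_pair_tree():
    # two sisters diverging at depth 0.6 of a height-1 tree
    t = dendropy.Tree.get(data="((a:0.4,b:0.4):0.6,(c:0.4,d:0.4):0.6);", schema="newick")
    return t


class TestPhyloCovariance:
    def test_star_tree_is_identity(self):
        tree, names = star_tree(5)
        C = phylo_covariance(tree, names)
        assert np.allclose(C, np.eye(5))

    def test_sister_pair_shared_depth(self):
        C = phylo_covariance(balanced_pair_tree(), ["a", "b", "c", "d"])
        assert C[0, 1] == pytest.approx(0.6)
        assert C[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(C), 1.0)

    def test_ultrametric_constant_diagonal(self):
        cfg = SimulationConfig(seed=5, n_species=12)
        truth = generate_traits_and_tree(cfg)
        C = phylo_covariance(truth.tree, list(truth.traits.index))
        assert np.allclose(np.diag(C), np.diag(C)[0], rtol=1e-6)
        assert np.all(np.linalg.eigvalsh(C) > -1e-8)

    def test_missing_tip_raises(self):
        tree, names = star_tree(4)
        with pytest.raises(AltishiftError, match="missing"):
            phylo_covariance(tree, names + ["nope"])

    def test_negative_branch_length_raises(self):
        t = dendropy.Tree.get(data="(a:1,(b:-0.5,c:1):1);", schema="newick")
        with pytest.raises(AltishiftError, match="negative"):
            phylo_covariance(t, ["a", "b", "c"])


class TestPgls:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        n = 20
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = 1.0 + 2.0 * X["x"] + rng.normal(size=n)
        fit = pgls_fit(y, X, np.eye(n))
        beta_ols = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-8)

    def test_slope_recovery_on_simulated_tree(self):
        """Mean slope estimate over seeded Brownian simulations is near the truth."""
        cfg = SimulationConfig(seed=8, n_species=40)
        truth = generate_traits_and_tree(cfg)
        species = list(truth.traits.index)
        C = phylo_covariance(truth.tree, species)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(species)))
        z = standardize_traits(truth.traits)["longevity"].to_numpy()
        X = pd.DataFrame({"intercept": 1.0, "longevity": z})
        rng = np.random.default_rng(9)
        ests = []
        for _ in range(200):
            y = 5.0 - 1.3 * z + L @ rng.standard_normal(len(species))
            ests.append(pgls_fit(y, X, C).params["longevity"])
        assert np.mean(ests) == pytest.approx(-1.3, abs=0.15)

    def test_duplicating_species_as_tiny_splits_changes_little(self):
        """Pseudo-replicated tips (near-zero splits) barely move the estimates."""
        rng = np.random.default_rng(3)
        tree, names = star_tree(8)
        x = rng.normal(size=8)
        y = 0.5 + 1.5 * x + rng.normal(0, 0.5, 8)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        base = pgls_fit(y, X, phylo_covariance(tree, names))

        eps = 1e-6
        newick = "(" + ",".join(
            f"({n}a:{eps},{n}b:{eps}):{1.0 - eps}" for n in names) + ");"
        tree2 = dendropy.Tree.get(data=newick, schema="newick")
        names2 = [f"{n}{s}" for n in names for s in ("a", "b")]
        C2 = phylo_covariance(tree2, names2)
        X2 = pd.DataFrame({"intercept": 1.0, "x": np.repeat(x, 2)})
        dup = pgls_fit(np.repeat(y, 2), X2, C2)
        assert np.allclose(dup.params.to_numpy(), base.params.to_numpy(), atol=1e-3)

    def test_rank_deficient_design_names_factor(self):
        tree, names = star_tree(6)
        X = pd.DataFrame({"intercept": 1.0, "all_same": 1.0}, index=range(6))
        with pytest.raises(RankDeficiencyError):
            pgls_fit(np.arange(6.0), X, np.eye(6))


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-47.0, 3, 10) == pytest.approx(94 + 6 + 24 / 6)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-5)

    def test_k_below_two_rejected(self):
        with pytest.raises(AltishiftError):
            aicc(-10.0, 1, 100)

    def test_small_n_undefined(self):
        with pytest.raises(AltishiftError):
            aicc(-10.0, 5, 6)


class TestEnumeration:
    def test_sixteen_models_including_null_and_full(self):
        models = enumerate_models()
        assert len(models) == 16
        assert frozenset() in models
        assert frozenset(HYPOTHESIS_GROUPS) in models

    def test_two_groups_give_four(self):
        sub = {k: HYPOTHESIS_GROUPS[k] for k in ("fastness_slowness", "population_dynamics")}
        assert len(enumerate_models(sub)) == 4

    def test_subsets_unique_and_exhaustive(self):
        models = enumerate_models()
        assert len(set(models)) == 16
        sizes = sorted(len(m) for m in models)
        assert sizes == [0, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3, 4]


def make_fit(names, betas, ses, loglik, n=30):
    return PglsFit(params=pd.Series(betas, index=names),
                   bse=pd.Series(ses, index=names),
                   loglik=loglik, k=len(names) + 1, sigma2_ml=1.0, n=n)


class TestModelAverage:
    def test_single_model_window_identity(self):
        fits = {frozenset(): make_fit(["intercept"], [3.0], [0.5], -10.0),
                frozenset({"a"}): make_fit(["intercept", "x"], [1.0, 2.0], [0.5, 0.5], -30.0)}
        table, avg = model_average(fits, window=4.0)
        assert avg.loc["intercept", "estimate"] == pytest.approx(3.0)
        assert "x" not in avg.index

    def test_equal_aicc_symmetric_average(self):
        fits = {frozenset({"a"}): make_fit(["intercept", "x"], [0.0, 2.0], [1.0, 1.0], -10.0),
                frozenset({"b"}): make_fit(["intercept", "x"], [0.0, 4.0], [1.0, 1.0], -10.0)}
        _, avg = model_average(fits, window=4.0)
        assert avg.loc["x", "estimate"] == pytest.approx(3.0)

    def test_tiny_window_reduces_to_best_model(self):
        fits = {frozenset({"a"}): make_fit(["intercept", "x"], [1.0, 2.0], [0.5, 0.5], -10.0),
                frozenset({"b"}): make_fit(["intercept", "z"], [9.0, 9.0], [0.5, 0.5], -11.0)}
        _, avg = model_average(fits, window=0.1)
        assert avg.loc["x", "estimate"] == pytest.approx(2.0)
        assert "z" not in avg.index

    def test_weights_sum_to_one_and_best_delta_zero(self):
        rng = np.random.default_rng(1)
        fits = {frozenset({f"m{i}"}): make_fit(["intercept"], [0.0], [1.0],
                                               float(-rng.uniform(10, 40))) for i in range(16)}
        table, _ = model_average(fits)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_full_averaging_shrinks_toward_zero(self):
        fits = {frozenset({"a"}): make_fit(["intercept", "x"], [0.0, 2.0], [1.0, 1.0], -10.0),
                frozenset(): make_fit(["intercept"], [0.0], [1.0], -10.0)}
        table, cond = model_average(fits, method="conditional")
        _, full = model_average(fits, method="full")
        # conditional averaging leaves the coefficient untouched; full
        # averaging shrinks it by the weight of the model lacking the term
        w_a = table.set_index(table["model"].map(bool))["weight"][True]
        assert cond.loc["x", "estimate"] == pytest.approx(2.0)
        assert full.loc["x", "estimate"] == pytest.approx(2.0 * w_a)
        assert full.loc["x", "estimate"] < cond.loc["x", "estimate"]


class TestFullTraitStage:
    def test_ranking_invariant_to_branch_scale(self):
        cfg = SimulationConfig(seed=21, n_species=25)
        truth = generate_traits_and_tree(cfg)
        shifts = pd.DataFrame({"species": list(truth.traits.index),
                               "mean_shift": truth.shift.to_numpy()})
        set1 = fit_trait_models(shifts, truth.traits, truth.tree)
        for e in truth.tree.preorder_edge_iter():
            if e.length:
                e.length *= 7.3
        set2 = fit_trait_models(shifts, truth.traits, truth.tree)
        order1 = [m for m in set1.table["model"]]
        order2 = [m for m in set2.table["model"]]
        assert order1 == order2
        assert np.allclose(set1.table["delta_aicc"], set2.table["delta_aicc"], atol=1e-6)

    def test_excluded_species_is_dropped(self):
        cfg = SimulationConfig(seed=22, n_species=20)
        truth = generate_traits_and_tree(cfg)
        shifts = pd.DataFrame({"species": list(truth.traits.index),
                               "mean_shift": truth.shift.to_numpy()})
        sp0 = shifts["species"].iloc[0]
        out = fit_trait_models(shifts, truth.traits, truth.tree, excluded_species=(sp0,))
        assert all(fit.n == 19 for fit in out.fits.values())

    def test_standardized_continuous_traits(self):
        cfg = SimulationConfig(seed=23, n_species=30)
        tr = standardize_traits(generate_traits_and_tree(cfg).traits)
        for col in ("clutch_size", "longevity", "sti", "population_trend"):
            assert tr[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert tr[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestConsensus:
    def test_identical_trees_keep_topology(self):
        cfg = SimulationConfig(seed=31, n_species=10)
        base = generate_traits_and_tree(cfg).tree
        trees = [base.clone(depth=1) for _ in range(20)]
        cons = consensus_with_lengths(trees)
        assert len(cons.leaf_nodes()) == 10
        ref_bipartitions = set(b.split_bitmask for b in base.encode_bipartitions())
        cons.migrate_taxon_namespace(base.taxon_namespace)
        cons_bip = set(b.split_bitmask for b in cons.encode_bipartitions())
        assert cons_bip == ref_bipartitions

    def test_resulting_covariance_psd_and_ultrametric(self):
        cfg = SimulationConfig(seed=32, n_species=8)
        trees = [generate_traits_and_tree(SimulationConfig(seed=32, n_species=8)).tree
                 for _ in range(5)]
        cons = consensus_with_lengths(trees)
        names = [lf.taxon.label for lf in cons.leaf_node_iter()]
        C = phylo_covariance(cons, names)
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)
        assert np.allclose(np.diag(C), np.diag(C)[0])

    def test_conflicting_tip_sets_rejected(self):
        t1, _ = star_tree(4)
        t2 = dendropy.Tree.get(data="(x:1,y:1,z:1);", schema="newick",
                               taxon_namespace=t1.taxon_namespace)
        with pytest.raises(AltishiftError, match="tip sets"):
            consensus_with_lengths([t1, t2])

    def test_grafen_heights_proportional_to_clade_size(self):
        t = dendropy.Tree.get(data="((a,b),(c,(d,e)));", schema="newick")
        g = grafen_lengths(t)
        depths = {}
        for leaf in g.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        assert np.allclose(list(depths.values()), 1.0)
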