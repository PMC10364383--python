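"""Soft-threshold screening, TOM, module detection, eigengenes, module-trait."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import pyroscore as ps
from conftest import toy_expression
from oracles import eigengene_oracle, tom_oracle


def blocks_cohort(seed=3):
    spec = ps.SyntheticSpec(n_genes=220, n_case=30, n_control=30, n_batches=1,
                            de_fraction=0.02, pyro_up_size=2, pyro_down_size=2,
                            celltype_profiles={}, ifng_size=2,
                            module_blocks=[(30, 0.8), (30, 0.8)], seed=seed)
    return ps.make_cohort(spec)


class TestSoftThreshold:
    def test_planted_modular_structure_passes_deterministically(self):
        expr, _ = blocks_cohort()
        st1 = ps.pick_soft_threshold(expr)
        st2 = ps.pick_soft_threshold(expr)
        assert st1.passed
        assert st1.chosen == st2.chosen
        assert 1 <= st1.chosen <= 30
        assert st1.table["r2_signed"].between(-1, 1).all()

    def test_low_power_not_chosen_on_equicorrelated_block(self):
        # one homogeneous block: connectivity nearly uniform at beta = 1
        rng = np.random.default_rng(5)
        latent = rng.normal(size=40)
        vals = 0.9 * latent[None, :] + rng.normal(0, 0.45, (60, 40))
        expr = toy_expression(vals)
        st = ps.pick_soft_threshold(expr)
        row = st.table.loc[1]
        assert row["r2_signed"] <= 0.8 or st.chosen != 1

    def test_too_few_samples_rejected(self):
        expr = toy_expression(np.random.default_rng(0).normal(size=(20, 8)))
        with pytest.raises(ValueError, match=">= 10 samples"):
            ps.pick_soft_threshold(expr)


class TestTom:
    def test_triangle_direct_formula(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        omega = ps.tom_similarity(A)
        assert abs(omega[0, 1] - 0.5) < 1e-12  # (0.25 + 0.5) / (1 + 1 - 0.5)

    def test_perfect_overlap_pair(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        omega = ps.tom_similarity(A)
        assert abs(omega[0, 1] - 1.0) < 1e-12

    def test_random_matrices_match_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            M = rng.uniform(0, 1, (6, 6))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 0.0)
            omega = ps.tom_similarity(A)
            assert np.abs(omega - tom_oracle(A)).max() < 1e-12
            assert np.allclose(omega, omega.T)
            assert omega.min() >= 0 and omega.max() <= 1 + 1e-12

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ps.tom_similarity(np.array([[0, 0.2], [0.5, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            ps.tom_similarity(np.array([[0.5, 0.2], [0.2, 0.5]]))


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, truth = blocks_cohort()
        st = ps.pick_soft_threshold(expr)
        A = ps.adjacency_matrix(expr, st.chosen)
        tom = ps.tom_similarity(A)
        mods = ps.detect_modules(1 - tom, expr.genes, min_size=12)
        assert len(mods.module_names) == 2
        planted = truth.module_labels[truth.module_labels != ""]
        ari = adjusted_rand_score(planted, mods.labels[planted.index])
        assert ari == 1.0

    def test_undersized_block_goes_grey(self):
        spec = ps.SyntheticSpec(n_genes=200, n_case=30, n_control=30,
                                n_batches=1, de_fraction=0.02, pyro_up_size=2,
                                pyro_down_size=2, celltype_profiles={},
                                ifng_size=2, module_blocks=[(8, 0.8)], seed=8)
        expr, truth = ps.make_cohort(spec)
        A = ps.adjacency_matrix(expr, 6)
        mods = ps.detect_modules(1 - ps.tom_similarity(A), expr.genes,
                                 min_size=12)
        block = truth.block_genes(0)
        assert (mods.labels[block] == "grey").all()

    def test_labels_invariant_to_gene_order(self):
        expr, _ = blocks_cohort()
        A = ps.adjacency_matrix(expr, 6)
        tom = ps.tom_similarity(A)
        mods = ps.detect_modules(1 - tom, expr.genes, min_size=12)
        perm = np.random.default_rng(2).permutation(len(expr.genes))
        mods_p = ps.detect_modules((1 - tom)[np.ix_(perm, perm)],
                                   [expr.genes[i] for i in perm], min_size=12)
        assert (mods_p.labels.sort_index() == mods.labels.sort_index()).all()


class TestEigengenes:
    def test_perfectly_correlated_module(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=20)
        vals = np.vstack([2 * base + 1, -3 * base + 5, 0.5 * base])
        expr = toy_expression(vals, groups=["case"] * 10 + ["control"] * 10)
        mods = ps.ModuleSet(labels=pd.Series(["turquoise"] * 3,
                                             index=expr.values.index))
        eig = ps.module_eigengenes(expr, mods)["turquoise"]
        assert abs(abs(np.corrcoef(eig, base)[0, 1]) - 1.0) < 1e-10
        assert abs(np.linalg.norm(eig) - 1.0) < 1e-12

    def test_sign_antisymmetry_and_mean_alignment(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(7, 1, (5, 16)) + rng.normal(size=16)[None, :]
        expr = toy_expression(vals, groups=["case"] * 8 + ["control"] * 8)
        mods = ps.ModuleSet(labels=pd.Series(["blue"] * 5,
                                             index=expr.values.index))
        eig = ps.module_eigengenes(expr, mods)["blue"]
        flipped = ps.ExpressionMatrix(values=-expr.values,
                                      metadata=expr.metadata.copy())
        eig_f = ps.module_eigengenes(flipped, mods)["blue"]
        assert np.allclose(eig_f, -eig, atol=1e-10)
        assert np.corrcoef(eig, expr.values.mean(axis=0))[0, 1] >= 0

    def test_five_gene_toy_matches_svd_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(5, 12))
        expr = toy_expression(vals, groups=["case"] * 6 + ["control"] * 6)
        mods = ps.ModuleSet(labels=pd.Series(["red"] * 5,
                                             index=expr.values.index))
        eig = ps.module_eigengenes(expr, mods)["red"].to_numpy()
        Z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1,
                                                                 keepdims=True)
        ref = eigengene_oracle(Z)
        assert min(np.abs(eig - ref).max(), np.abs(eig + ref).max()) < 1e-10

    def test_constant_module_rejected(self):
        expr = toy_expression(np.ones((4, 10)))
        mods = ps.ModuleSet(labels=pd.Series(["brown"] * 4,
                                             index=expr.values.index))
        with pytest.raises(ValueError, match="constant"):
            ps.module_eigengenes(expr, mods)


class TestModuleTrait:
    def test_eigengene_trait_self_correlation(self):
        expr, _ = blocks_cohort()
        A = ps.adjacency_matrix(expr, 6)
        mods = ps.detect_modules(1 - ps.tom_similarity(A), expr.genes, 12)
        eig = ps.module_eigengenes(expr, mods)
        m = eig.columns[0]
        traits = pd.DataFrame({"self": eig[m], "flat": np.ones(len(eig))},
                              index=eig.index)
        table, selected = ps.module_trait(eig, traits)
        row = table[(table["module"] == m) & (table["trait"] == "self")]
        assert abs(row["r"].iloc[0] - 1.0) < 1e-12
        assert "flat" not in set(table["trait"])  # constant trait dropped
        assert selected == m

    def test_driver_block_selected_against_computed_traits(self):
        spec = ps.SyntheticSpec(n_genes=800, n_case=30, n_control=30,
                                n_batches=1, de_fraction=0.08,
                                module_blocks=[(30, 0.8), (30, 0.8), (30, 0.8)],
                                driver_block=0, seed=2024)
        expr, truth = ps.make_cohort(spec)
        pes = ps.directional_score(expr, truth.pyro_up, truth.pyro_down).score
        gs = ps.make_genesets(spec, truth)
        tgd = ps.score_cell_types(expr, gs.subset(["Tgd"]))["Tgd"]
        ifng = ps.directional_score(expr, truth.ifng_genes).score
        traits = pd.DataFrame({"PES": pes, "tgd_score": tgd,
                               "ifng_response": ifng})
        excl = set(truth.de_up) | set(truth.de_down) | set(truth.ifng_genes)
        sub = expr.subset_genes([g for g in expr.genes if g not in excl][:240])
        A = ps.adjacency_matrix(sub, 6)
        mods = ps.detect_modules(1 - ps.tom_similarity(A), sub.genes, 12)
        eig = ps.module_eigengenes(sub, mods)
        _, selected = ps.module_trait(eig, traits)
        sel = set(mods.genes_in(selected))
        block0 = set(truth.block_genes(0))
        assert len(sel & block0) / len(block0) >= 0.5


@pytest.mark.parametrize("a,b,expected", [
    (["a", "b", "c"], ["b", "c", "d"], ["b", "c"]),
    (["a"], ["b"], []),
    (["x", "y"], ["x", "y"], ["x", "y"]),
])
def test_overlap_report(a, b, expected):
    rep = ps.overlap_report(a, b)
    assert rep["intersection"] == sorted(expected)
    assert rep["counts"]["shared"] == len(expected)
    assert sorted(rep["module_only"] + rep["intersection"]) == sorted(a)
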