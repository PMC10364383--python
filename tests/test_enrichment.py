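"""ssGSEA statistic, directional composite score, phenotype GSEA."""

import numpy as np
import pandas as pd
import pytest

import pyroscore as ps
from conftest import toy_expression
from oracles import ssgsea_oracle


def random_instance(rng, n_genes=None, n_samples=None, set_size=None):
    N = n_genes or int(rng.integers(5, 13))
    S = n_samples or int(rng.integers(2, 5))
    k = set_size or int(rng.integers(2, min(5, N)))
    genes = [f"g{j}" for j in range(N)]
    expr = toy_expression(rng.normal(5, 2, (N, S)), gene_ids=genes)
    gene_set = list(rng.choice(genes, size=k, replace=False))
    return expr, gene_set


class TestSsgsea:
    def test_identical_samples_get_identical_scores(self):
        col = np.random.default_rng(0).normal(5, 1, 30)
        expr = toy_expression(np.column_stack([col, col]),
                              groups=["case", "control"])
        s = ps.ssgsea_score(expr, expr.genes[:4])
        assert s.iloc[0] == s.iloc[1]

    def test_score_monotone_in_set_rank(self):
        # 5 distinct values; the top-2 set must outscore the bottom-2 set
        expr = toy_expression(np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]),
                              groups=["case"])
        top = ps.ssgsea_score(expr, ["g1", "g2"]).iloc[0]
        bottom = ps.ssgsea_score(expr, ["g4", "g5"]).iloc[0]
        assert top > bottom

    def test_matches_ecdf_summation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            expr, gene_set = random_instance(rng)
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            scores = ps.ssgsea_score(expr, gene_set, alpha=alpha)
            for s in expr.samples:
                ref = ssgsea_oracle(dict(expr.values[s]), set(gene_set), alpha)
                assert abs(scores[s] - ref) < 1e-12

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(18)
        expr, gene_set = random_instance(rng, n_genes=20, n_samples=4)
        base = ps.ssgsea_score(expr, gene_set)
        for f in (np.exp, lambda x: 3 * x + 10, lambda x: x**3):
            t = ps.ExpressionMatrix(values=f(expr.values),
                                    metadata=expr.metadata.copy())
            assert np.allclose(ps.ssgsea_score(t, gene_set), base, atol=1e-12)

    def test_tiny_overlap_rejected(self):
        expr = toy_expression(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="need >= 2"):
            ps.ssgsea_score(expr, ["g1"])


class TestSplitDirection:
    def test_recovers_planted_18_8_split(self, derivation_cohort):
        _, expr, truth = derivation_cohort
        de = ps.de_test(expr)
        pro, anti = ps.split_direction(de, truth.pyro_up + truth.pyro_down)
        assert sorted(pro) == sorted(truth.pyro_up)
        assert sorted(anti) == sorted(truth.pyro_down)
        assert (len(pro), len(anti)) == (18, 8)

    def test_null_cohort_raises_with_fallback_hint(self):
        spec = ps.SyntheticSpec(n_genes=500, n_case=10, n_control=10,
                                n_batches=1, de_log2fc=0.0,
                                celltype_profiles={}, driver_coupling=0.0,
                                de_fraction=0.06, pyro_up_size=5,
                                pyro_down_size=5, seed=19)
        expr, truth = ps.make_cohort(spec)
        de = ps.de_test(expr)
        with pytest.raises(ValueError, match="[Ff]all ?back"):
            ps.split_direction(de, truth.pyro_up + truth.pyro_down)

    def test_split_flips_under_group_swap(self, small_cohort):
        _, expr, truth = small_cohort
        de = ps.de_test(expr)
        swapped = ps.ExpressionMatrix(
            values=expr.values,
            metadata=expr.metadata.assign(
                group=expr.groups.map({"case": "control", "control": "case"})),
        )
        de_sw = ps.de_test(swapped)
        pag = truth.pyro_up + truth.pyro_down
        pro, anti = ps.split_direction(de, pag)
        pro_sw, anti_sw = ps.split_direction(de_sw, pag)
        assert sorted(pro) == sorted(anti_sw)
        assert sorted(anti) == sorted(pro_sw)


class TestDirectionalScore:
    def test_identical_sets_cancel_exactly(self):
        rng = np.random.default_rng(20)
        expr = toy_expression(rng.normal(7, 1, (30, 8)))
        s = ps.directional_score(expr, expr.genes[:5], expr.genes[:5])
        assert (s.score == 0).all()

    def test_composite_bounded_and_planted_direction_recovered(self, small_cohort):
        _, expr, truth = small_cohort
        s = ps.directional_score(expr, truth.pyro_up, truth.pyro_down)
        assert s.score.between(-1, 1).all()
        case = s.score[expr.groups == "case"]
        ctrl = s.score[expr.groups == "control"]
        assert case.median() > ctrl.median()

    def test_constant_component_maps_to_midpoint(self):
        col = np.random.default_rng(1).normal(5, 1, 20)
        expr = toy_expression(np.column_stack([col, col, col]),
                              groups=["case", "case", "control"])
        s = ps.directional_score(expr, expr.genes[:3], expr.genes[5:8])
        assert (s.table["norm_up"] == 0.5).all()
        assert (s.table["norm_down"] == 0.5).all()
        assert (s.score == 0).all()

    def test_four_sample_toy_matches_oracle_end_to_end(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(6, 1, (8, 4))
        expr = toy_expression(vals)
        pro, anti = expr.genes[:2], expr.genes[4:6]
        s = ps.directional_score(expr, pro, anti)
        es_up = np.array([ssgsea_oracle(dict(expr.values[c]), set(pro), 0.25)
                          for c in expr.samples])
        es_down = np.array([ssgsea_oracle(dict(expr.values[c]), set(anti), 0.25)
                            for c in expr.samples])

        def mm(v):
            return (v - v.min()) / (v.max() - v.min())
        assert np.allclose(s.table["es_up"], es_up, atol=1e-12)
        assert np.allclose(s.score, mm(es_up) - mm(es_down), atol=1e-12)

    def test_single_set_variant_stays_in_unit_interval(self, small_cohort):
        _, expr, truth = small_cohort
        s = ps.directional_score(expr, truth.ifng_genes)
        assert s.score.between(0, 1).all()


class TestGseaPhenotype:
    def test_planted_signal_set_attains_minimal_p(self):
        spec = ps.SyntheticSpec(n_genes=400, n_case=15, n_control=15,
                                n_batches=1, de_log2fc=2.0,
                                celltype_profiles={}, driver_coupling=0.0,
                                de_fraction=0.1, seed=22)
        expr, truth = ps.make_cohort(spec)
        sets = ps.GeneSetCollection(sets={"planted": truth.de_up[:15]})
        res = ps.gsea_phenotype(expr, sets, n_perm=200, seed=1)
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "p"] <= 1 / (200 + 1) + 1e-12
        assert np.sign(res.loc["planted", "nes"]) == np.sign(res.loc["planted", "es"])

    def test_set_and_complement_have_opposite_es(self):
        rng = np.random.default_rng(23)
        vals = rng.normal(7, 1, (30, 12))
        vals[:10, :6] += 1.5
        expr = toy_expression(vals)
        genes = expr.genes
        res = ps.gsea_phenotype(
            expr, ps.GeneSetCollection(sets={"s": genes[:10],
                                             "comp": genes[10:]}),
            n_perm=100, seed=2)
        assert res.loc["s", "es"] * res.loc["comp", "es"] < 0

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest
        pvals = []
        for rep in range(60):
            spec = ps.SyntheticSpec(n_genes=300, n_case=10, n_control=10,
                                    n_batches=1, de_log2fc=0.0,
                                    celltype_profiles={}, driver_coupling=0.0,
                                    de_fraction=0.02, pyro_up_size=2,
                                    pyro_down_size=2, ifng_size=2,
                                    seed=31 + rep)
            expr, truth = ps.make_cohort(spec)
            rs = np.random.default_rng(rep)
            genes = [truth.genes[j] for j in rs.choice(300, 15, replace=False)]
            res = ps.gsea_phenotype(expr, ps.GeneSetCollection(sets={"s": genes}),
                                    n_perm=200, seed=rep)
            pvals.append(res["p"].iloc[0])
        assert kstest(pvals, "uniform").statistic < 0.15
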