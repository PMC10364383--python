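import numpy as np
import pandas as pd
import pytest

import pyroscore as ps


def toy_expression(values, gene_ids=None, groups=None, batches=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    groups = groups or ["case"] * (n_samples // 2) + \
        ["control"] * (n_samples - n_samples // 2)
    meta = {"group": groups}
    if batches is not None:
        meta["batch"] = batches
    return ps.ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        metadata=pd.DataFrame(meta, index=samples),
    )


@pytest.fixture(scope="session")
def derivation_cohort():
    """Default synthetic derivation cohort (48 cases / 51 controls, 3 batches)."""
    spec = ps.SyntheticSpec(seed=7)
    expr, truth = ps.make_cohort(spec)
    return spec, expr, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small single-batch cohort used by fast per-module tests."""
    spec = ps.SyntheticSpec(n_genes=1000, n_case=30, n_control=30, n_batches=1,
                            seed=5)
    expr, truth = ps.make_cohort(spec)
    return spec, expr, truth


@pytest.fixture(scope="session")
def feature_fixture(small_cohort):
    """Hub-gene + score feature table built from the small cohort."""
    spec, expr, truth = small_cohort
    pes = ps.directional_score(expr, truth.pyro_up, truth.pyro_down).score
    gs = ps.make_genesets(spec, truth)
    tgd = ps.score_cell_types(expr, gs.subset(["Tgd"]))["Tgd"]
    ifng = ps.directional_score(expr, truth.ifng_genes).score
    scores = pd.DataFrame({"PES": pes, "ifng_response": ifng, "tgd_score": tgd})
    hubs = (truth.pyro_up + [g for g in truth.de_up
                             if g not in truth.pyro_up])[:20]
    return ps.build_features(expr, scores, hubs)
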