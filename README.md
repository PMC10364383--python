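# pyroscore

Quantifying pyroptosis — gasdermin-mediated inflammatory cell death — in
case/control transcriptome cohorts, and tying it to immune infiltration,
co-expression modules, interaction hubs and a sparse diagnostic model.

The package grew out of the computational workflow used to study pyroptosis
in celiac-disease duodenal tissue, where intraepithelial γδT cells and the
interferon-γ response drive epithelial gasdermin D activation. It
re-implements that workflow as a tested, reusable Python library operating
on genes × samples log2 expression matrices with case/control metadata, and
ships a first-class synthetic-cohort generator so every stage can be
validated against planted ground truth.

## What it computes

**Pyroptosis enrichment score (PES).** For a sample with genes ranked by
expression (descending, deterministic tie-breaks), the single-sample
enrichment statistic of a gene set *S* is

    ES(S) = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i) = Σ_{g∈S, pos(g)≤i} r_g^α / Σ_{g∈S} r_g^α,
    P_out(i) = #{g∉S : pos(g)≤i} / (N − |S|),

with rank weight `r_g = N − pos(g) + 1` and exponent `α = 0.25`. A pathway
list is split by the cohort's differential-expression screen into
pro-pyroptotic (up in cases) and anti-pyroptotic (down) sets; each set's
ES is min–max normalised across samples to [0, 1] and

    PES = norm(ES_pro) − norm(ES_anti)  ∈ [−1, 1].

The same construction scores the response-to-IFN-γ pathway (single set) and
cell-type marker signatures (per-sample infiltration scores with a
random-signature permutation gate).

**Around the score:** Welch differential expression with Benjamini–Hochberg
control and hypergeometric over-representation; location/scale batch
adjustment with PCA QC; a Spearman co-expression network over all
per-sample scores; a compact weighted co-expression module workflow
(soft threshold powers 1–30 at scale-free fit R² > 0.8, topological
overlap, average-linkage clustering, minimum module size 12, eigengenes,
Pearson module–trait selection); MCODE complex detection on an interaction
graph filtered at score > 0.4 with degree ranking; and an L1-penalised
logistic model along a cross-validated λ path (lambda.min, natural-log
reporting) with a ridge re-fit on a validation cohort and exact
Mann–Whitney-equivalent ROC/AUC.

## Worked example

```python
import pyroscore as ps
from scipy.stats import mannwhitneyu

spec = ps.SyntheticSpec(seed=3)          # 48 cases / 51 controls, 3 batches
expr, truth = ps.make_cohort(spec)
expr = ps.adjust_batch(expr)

de = ps.de_test(expr)
pro, anti = ps.split_direction(de, truth.pyro_up + truth.pyro_down)
pes = ps.directional_score(expr, pro, anti).score
case, ctrl = pes[expr.groups == "case"], pes[expr.groups == "control"]
print(len(pro), len(anti))
print(round(case.median(), 3), round(ctrl.median(), 3))
print(mannwhitneyu(case, ctrl, alternative="two-sided")[1])
```

prints

```
17 8
0.516 -0.13
7.377e-14
```

— the pathway split recovers 17 pro- and 8 anti-pyroptotic genes in this
cohort, and the median PES is clearly higher in cases (Mann–Whitney
p ≈ 7 × 10⁻¹⁴): the score separates the groups, as it should when a
pyroptotic program is planted. The `examples/` directory walks through each
capability the same way (cohort generation, batch QC, PES, infiltration
networking, module discovery, hub complexes, the predictive model).

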