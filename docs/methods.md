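# Methods

This note documents the models and procedures implemented in `pyroscore`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make every
stage deterministic.

## Data model

All stages operate on an `ExpressionMatrix`: a genes × samples table of
finite log2 expression values (microarray intensities or log-transformed
sequencing estimates) with per-sample metadata carrying a two-level
`group` label (`case` / `control`) and a `batch` label. Gene symbols are
matched case-insensitively (upper-cased on read) and duplicate symbols are
collapsed to the row with the highest mean expression. Cohorts are merged
on the **intersection** of their gene sets — union merging would require
imputation — with the source cohort becoming the batch label. The package
does not model raw counts; sequencing data is expected on a log2(x+1)-type
scale, and negative-binomial modelling is out of scope.

## Batch adjustment

`adjust_batch` is a per-gene location/scale standardisation: each batch's
values are centred and scaled by that batch's own mean and population SD,
then rescaled to the gene's grand mean and its **pooled within-batch SD**
(the size-weighted mean of batch variances). Using the within-batch pooled
SD rather than the total SD matters: the total SD contains the
between-batch variance being removed, and rescaling to it would inflate
within-batch signal (about 34% at a 2-log2-unit shift on unit-SD noise).
With the pooled-within convention the per-gene grand mean and pooled SD
are preserved exactly, the adjustment is idempotent, and a group effect
balanced across batches passes through essentially unchanged. This is the
location/scale core of empirical-Bayes batch correction without the
shrinkage prior; at the cohort sizes targeted here the prior has no
verifiable surface, and the simpler adjuster is fully specifiable and
testable. Group labels are not protected covariates: in strongly
unbalanced designs the batch means absorb group signal and the adjustment
attenuates it — a known limitation, not silently corrected.

## Differential expression and over-representation

Per-gene Welch (unequal-variance) t tests on log2 values, case minus
control, with Benjamini–Hochberg control across genes. Welch rather than a
moderated t: no shrinkage hyper-parameters, and the validation surface is
recovery of planted effects, not replication of a specific package's
output. Genes constant across the cohort get p = 1 by convention and are
flagged; within-group-constant genes with differing means get p = 0. DEG
selection defaults to fold change > 2 (|log2FC| > 1) and adjusted
p < 0.05 — the fold-change reading of the threshold, exposed as arguments.
Over-representation uses the upper-tail hypergeometric test against a
user-supplied universe, BH across sets, and reports a directional z-score
(n_up − n_down)/√k over each set's overlapping query genes.

## Single-sample enrichment and the PES

The ssGSEA statistic walks each sample's expression ranking once,
accumulating the difference between the in-set ECDF (weighted by
r^α, r = N − position + 1) and the uniform out-of-set ECDF; ties in
expression break by gene id, so scores are reproducible across platforms
and invariant to any strictly monotone per-sample transform. The exponent
defaults to α = 0.25, the original ssGSEA choice, and is exposed.

The PES is directional: the pathway list is split by the cohort's DE
screen into pro-pyroptotic (significantly up in cases) and anti-pyroptotic
(significantly down) sets — non-significant members are excluded — and the
composite is the difference of the two components after each is min–max
normalised across the cohort's samples. "Normalised" is not further
specified in the source workflow; min–max keeps the composite in a fixed
[−1, 1] range, makes it exactly 0 when the sets coincide, and a z-score
variant is available. A constant component maps to 0.5 for every sample,
so a fully degenerate composite is 0. The raw (un-rescaled) ES feeds the
normalisation; no other rescaling is applied. By default the split is
derived once from a derivation cohort and reused on validation cohorts;
re-deriving per cohort is a caller's choice. When only one direction is
significant, `split_direction` raises and the single-set composite
(`anti_set=None`, range [0, 1]) is the documented fallback — also how the
interferon-γ response score is computed from its single GO-derived set.

Phenotype GSEA ranks genes by signal-to-noise ((μ₁−μ₂)/(σ₁+σ₂), each SD
floored at 0.2|μ|, or 0.2 when μ = 0), integrates the weighted KS running
sum (weight exponent 1), and permutes group labels for the null. NES
divides the observed score by the mean |same-sign null|. The p-value is
the +1-smoothed upper-tail exceedance over the full permutation null: this
is exactly uniform under label exchange and attains 1/(n_perm + 1),
whereas the same-sign-conditional convention cannot reach that floor;
depletion is tested by swapping the group labels.

## Infiltration scoring

Cell-type abundance is approximated by scoring marker-gene signatures with
the same ssGSEA statistic — a deliberate simplification of
signature-ensemble deconvolution tools, whose spillover compensation and
platform-specific signature versions are not reproducible from a method
description. Signatures are user-supplied GMT files with the category in
the description field. The significance gate is per cell type: the
observed mean score is compared with the mean scores of `n_null` random
same-size gene sets (empirical p with +1 smoothing, retain p < 0.05); the
gate is honest at the nominal level under the null by construction, and
same-size signatures share one null for speed. Group comparison is
Mann–Whitney per score column with BH across columns. The co-expression
network is pairwise Spearman correlation with t-approximation p-values, BH
over pairs, and an explicit readout of the cell type with maximal |ρ|
against the PES column. A proportion display mode rescales each sample's
scores to sum to 1 for stacked plots; these are not fractional abundances.

## Co-expression modules

A compact, fully deterministic version of the weighted co-expression
workflow. Adjacency is unsigned, |cor|^β (Pearson), with β screened over
1–30: connectivity is binned (10 equal-width bins, reduced with a warning
when too many are empty), and the signed scale-free fit is
−sign(slope)·cor²(log₁₀ mean-k, log₁₀ freq); the smallest β exceeding 0.8
wins, else the argmax with a warning. Topological overlap follows the
standard formula with unit diagonal; dissimilarity 1 − ω is clustered with
average linkage and a **static** cut at 0.99 × the maximum merge height —
dynamic hybrid tree cutting is replaced because the static cut is fully
specifiable and recovers well-separated blocks exactly; the cut fraction
is exposed. Clusters under 12 genes fall into `grey`; colours are assigned
by decreasing size through a fixed palette, so labels are invariant to
gene input order. Eigengenes are the first principal component of the
gene-standardised module submatrix, unit-norm, sign-aligned to the module
mean profile; constant genes are dropped. Module–trait selection maximises
the mean |Pearson r| across the supplied traits (here: PES, γδT score,
IFN-γ response). Note that planted-block synthetic data is *not*
scale-free, so on such cohorts the β screen drifts high; the replicate
recovery simulations therefore fix β = 6 (the classic unsigned default),
while the screen keeps its own deterministic test.

## Interaction complexes

`load_graph` keeps edges with interaction score strictly above 0.4 (the
conventional medium-confidence cut), collapsing duplicates to the maximum
weight and dropping self-loops. MCODE follows its original three phases
with the usual defaults (vertex weight percentage 0.2, haircut on, fluff
off, all exposed): vertex weight = k × density of the highest k-core of
the closed neighbourhood; seeded greedy expansion in decreasing weight
with each node joining at most one complex; iterative removal of degree-1
members and rejection of complexes without a 2-core; ranking by
density × size. Ties break by node id everywhere, so results are
deterministic and invariant to relabelling. Hub genes are defined as the
members of the top-ranked complex. The greedy search is not a global
optimiser on dense graphs; on the sparse planted-complex topology it
targets, the top complex matches exhaustive enumeration on all structured
test graphs of ≤ 8 nodes.

## Predictive model

Features are hub-gene expression columns plus the PES, IFN-γ response and
γδT infiltration scores. The lasso is the glmnet formulation — mean
binomial deviance + λ‖β‖₁, intercept unpenalised, features standardised
internally, coefficients reported on the original scale — solved by cyclic
coordinate descent inside an IRLS loop with warm starts along a geometric
λ grid from λ_max = max_j |x_jᵀ(y − ȳ)|/n (the exact all-zero KKT
boundary) down by a factor of 100. Convergence is declared when no
coefficient moves by more than 1e-7; a tiny relative slack in the
soft-threshold keeps the λ_max boundary exactly sparse under float noise,
and probabilities are clipped so separation cannot blow up the weights
(the grid never reaches λ = 0). The penalty is lambda.min — the minimiser
of stratified k-fold cross-validated deviance (10 folds by default,
seeded; folds differ in size by at most one) — and is reported with its
natural log, the convention under which a printed pair like
(0.0119, −4.431) is self-consistent. Validation uses a ridge re-fit of the
selected variables (scikit-learn's L2 logistic, penalty chosen by CV
deviance over a geometric grid) scored by its in-sample ROC AUC, mirroring
how such models are usually reported; scoring a frozen lasso model on the
validation features is equally possible from the returned fit. ROC curves
sweep all unique scores with half-credit ties, so the trapezoid AUC equals
the Mann–Whitney U statistic divided by n₁n₂ exactly.

## Synthetic cohorts

The generator plants every structure the pipeline estimates, on the log2
scale, with all randomness through one seeded generator (identical seeds
give identical bytes). Defaults are the study conditions the package
targets: 48 cases / 51 controls across three sub-cohort batches, baseline
expression i.i.d. Normal(7, 1) per gene and sample (microarray-like), 5%
of genes differentially expressed at 1 log2 unit (half up, half down), a
pyroptosis list splitting 18 up / 8 down drawn from the planted DE genes,
a 20-gene interferon-response set elevated in cases, and eight cell-type
signature profiles of 25 genes each. The γδT profile is the designated
latent driver: its per-sample abundance is the group elevation plus a
standard-normal latent axis ε, and the pyroptosis and interferon genes are
coupled to ε at 0.5 log2 units per SD — so pyroptosis, the interferon
response and γδT infiltration co-vary sample by sample, as they do in the
tissue this emulates. Module blocks add loading·v to disjoint gene blocks
with the loading set so within-block correlation equals the requested r; a
designated block can reuse ε as its latent, making it the trait-driving
module. Batch distortion is an additive shift plus a multiplicative scale
per batch around each gene's mean; batches are assigned round-robin so
groups stay balanced across them. Planted gene classes (DE, interferon,
signatures, blocks) occupy disjoint index ranges and a spec that cannot be
laid out disjointly is rejected.

What the generator does **not** emulate: count noise and
mean–variance coupling, correlated background genes, probe effects,
signature overlap between related cell types, fractional cell mixtures
(signatures are shifted, not mixed), and label noise. Passing recovery
tests on these cohorts therefore demonstrates that the estimators are
correct and calibrated under their stated assumptions — not that they are
robust to every pathology of real microarray or RNA-seq data.

## Problem sizes and replicate counts

Simulation-based checks use cohorts of 30+30 samples with 800–2000 genes
and 100 seed-swept replicates for the headline recovery claims (PES group
separation, γδT as the top PES correlate, trait-module selection); the
sparsity-of-selection check runs 15 replicate fits at 5 CV folds and a
40-point λ grid, and the Monte-Carlo power check of the DE screen runs 100
replicates at a 10% DE fraction — the power of a 1-log2-unit effect at
30+30 under BH depends on the true-positive fraction, and 10% reflects the
strongly remodelled disease tissue the cohorts emulate (at 5% the same
design yields ≈ 0.74 mean recall). These sizes keep the full suite around
a minute while leaving the Monte-Carlo error far from every asserted
margin.

## Known limitations

- The batch adjuster ignores group labels (see above).
- Signature scores are enrichment scores, not cell fractions; the
  proportion display mode is cosmetic.
- The static tree cut has no per-branch adaptivity; heavily nested module
  structure will under-split.
- MCODE's greedy expansion can miss the globally densest subgraph on
  dense graphs.
- The lasso solver targets the small, dense feature tables of this
  workflow (tens of features); it is not tuned for p ≫ n genomics-scale
  design matrices.
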