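"""Generate a fully-labelled synthetic case/control cohort.

The generator emulates a merged duodenal transcriptome study on the log2
scale: planted differentially expressed genes, a directional pyroptosis
gene set (18 genes up in cases, 8 down), cell-type signature elevation with
a shared gamma-delta T-cell latent axis, and batch structure across three
sub-cohorts. Every planted feature is returned as ground truth.
"""

import pyroscore as ps

spec = ps.SyntheticSpec(seed=1)  # defaults: 48 cases / 51 controls, 3 batches
expr, truth = ps.make_cohort(spec)

print(f"cohort: {len(expr.genes)} genes x {len(expr.samples)} samples")
print(f"groups: {expr.groups.value_counts().to_dict()}")
print(f"batches: {expr.batches.value_counts().to_dict()}")
print(f"planted DE genes: {len(truth.de_up)} up, {len(truth.de_down)} down "
      f"at {spec.de_log2fc} log2 units")
print(f"pyroptosis set: {len(truth.pyro_up)} pro / {len(truth.pyro_down)} anti")
print(f"cell-type signatures: {list(truth.celltype_genes)}")

gs = ps.make_genesets(spec, truth, n_decoys=2)
print(f"gene-set collection: {gs.names()}")
# The matrix, metadata, gene sets and ground truth can be written as TSV /
# GMT / JSON fixtures with write_expression, write_gmt and truth.to_json.
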