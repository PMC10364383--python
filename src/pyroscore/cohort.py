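"""Expression-matrix container, TSV I/O, cohort merging, batch adjustment, PCA QC.

The substrate of the whole pipeline is a genes x samples matrix of log2
expression (microarray intensities or log-transformed sequencing values)
with per-sample metadata carrying a two-level ``group`` label (case /
control) and a ``batch`` label identifying the source cohort. Multi-study
cohorts are merged on the intersection of gene symbols and the batch effect
is removed by per-gene location/scale standardisation within batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with aligned sample metadata.

    ``values`` is a DataFrame indexed by unique gene symbol with unique
    sample-id columns; ``metadata`` is indexed by sample id with at least a
    ``group`` column (levels ``case`` / ``control``) and a ``batch`` column.
    All expression values must be finite.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        extra = [s for s in self.metadata.index if s not in self.values.columns]
        if missing or extra:
            raise ValueError(
                "matrix/metadata sample mismatch: "
                f"missing from metadata {missing[:10]}, "
                f"missing from matrix {extra[:10]}"
            )
        # align metadata row order to matrix column order
        self.metadata = self.metadata.loc[self.values.columns]
        if "group" not in self.metadata.columns:
            raise ValueError("metadata must have a 'group' column")
        bad = set(self.metadata["group"]) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(f"group labels must be in {GROUP_LEVELS}, got {sorted(bad)}")
        if "batch" not in self.metadata.columns:
            self.metadata = self.metadata.assign(batch="batch1")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValueError(f"expression matrix contains {n_bad} non-finite values")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    @property
    def batches(self) -> pd.Series:
        return self.metadata["batch"]

    def group_samples(self, level: str) -> list[str]:
        return self.metadata.index[self.metadata["group"] == level].tolist()

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[present], metadata=self.metadata)


@dataclass
class PcaResult:
    """Sample coordinates on the leading principal components of a cohort."""

    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if ((vf < -1e-12) | (vf > 1 + 1e-12)).any():
            raise ValueError("variance fractions must lie in [0, 1]")
        if (np.diff(vf) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV and a sample-metadata TSV.

    The matrix TSV has a header row of sample ids and gene ids in the first
    column. The metadata TSV has columns ``sample, group, batch``. Gene
    symbols are upper-cased (symbol matching is case-insensitive) and
    duplicate symbols are collapsed to the row with the highest mean
    expression, which is logged.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    try:
        values = values.astype(float)
    except ValueError:
        for j, col in enumerate(values.columns):
            for i, v in enumerate(values[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {values.index[i]!r}, sample {col!r} "
                        f"(row {i + 1}, column {j + 1}): {v!r}"
                    ) from None
        raise
    if values.index.duplicated().any():
        means = values.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = values.iloc[order]
        keep = ~deduped.index.duplicated(keep="first")
        dropped = sorted(deduped.index[~keep].unique())
        logger.info("collapsed %d duplicate gene symbols by max mean expression: %s",
                    len(dropped), dropped[:10])
        values = deduped.loc[keep].loc[sorted(deduped.index[keep])]
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata must have a 'sample' column")
    meta = meta.set_index("sample")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return ExpressionMatrix(values=values, metadata=meta.loc[values.columns])


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    """Write the matrix and metadata back as TSV (round-trips with the reader)."""
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def merge_cohorts(matrices: list[ExpressionMatrix],
                  cohort_labels: list[str] | None = None) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their gene sets.

    The batch label of each output sample is its source cohort; sample ids
    colliding across cohorts are prefixed with the cohort label.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two cohorts to merge")
    if cohort_labels is None:
        cohort_labels = [f"cohort{i + 1}" for i in range(len(matrices))]
    if len(cohort_labels) != len(matrices):
        raise ValueError("one cohort label per matrix required")
    common: set[str] | None = None
    for m in matrices:
        common = set(m.genes) if common is None else common & set(m.genes)
    if not common:
        raise ValueError("gene intersection of the cohorts is empty")
    genes = sorted(common)
    seen: set[str] = set()
    blocks, metas = [], []
    for m, label in zip(matrices, cohort_labels):
        vals = m.values.loc[genes]
        meta = m.metadata.copy()
        collide = [s for s in vals.columns if s in seen]
        if collide:
            mapping = {s: f"{label}:{s}" for s in collide}
            vals = vals.rename(columns=mapping)
            meta = meta.rename(index=mapping)
        seen.update(vals.columns)
        meta = meta.assign(batch=label, cohort=label)
        blocks.append(vals)
        metas.append(meta)
    return ExpressionMatrix(values=pd.concat(blocks, axis=1),
                            metadata=pd.concat(metas, axis=0))


def adjust_batch(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove per-gene batch location/scale differences.

    For every gene, each batch's values are standardised by that batch's own
    mean and (population) SD, then rescaled to the pooled pre-adjustment gene
    moments: the grand mean and the pooled within-batch SD (the square root
    of the sample-size-weighted mean of the batch variances, so the
    between-batch shift variance being removed does not leak into the
    scale). Both pooled moments are preserved exactly by construction. A
    batch-gene cell with zero variance passes through centred only. Group
    labels are untouched; the adjustment does not look at them.
    """
    batches = expr.batches
    levels = batches.unique().tolist()
    if len(levels) < 2:
        raise ValueError("batch adjustment needs >= 2 batches")
    counts = batches.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"each batch needs >= 3 samples; too small: {small.to_dict()}"
        )
    X = expr.values.to_numpy(dtype=float)
    grand_mean = X.mean(axis=1, keepdims=True)
    batch_cols = {level: (batches == level).to_numpy() for level in levels}
    # pooled within-batch variance (ddof=0), weighted by batch size
    pooled_var = np.zeros((X.shape[0], 1))
    for level in levels:
        cols = batch_cols[level]
        pooled_var += cols.sum() * X[:, cols].var(axis=1, keepdims=True)
    pooled_sd = np.sqrt(pooled_var / X.shape[1])
    out = np.empty_like(X)
    for level in levels:
        cols = batch_cols[level]
        block = X[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (block - mu) / np.where(sd > 0, sd, 1.0), block - mu)
        scale = np.where(sd > 0, pooled_sd, 1.0)
        out[:, cols] = z * scale + grand_mean
    values = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=values, metadata=expr.metadata.copy())


def pca_qc(expr: ExpressionMatrix, n_components: int = 2) -> PcaResult:
    """Principal components of the column-centred matrix via SVD.

    Samples are observations; genes are features. Deterministic up to the
    usual sign ambiguity, which is fixed by making the largest-magnitude
    loading of each component positive.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    n_genes, n_samples = expr.values.shape
    if n_components > min(n_genes, n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(len(s)):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    vf = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PcaResult(
        coordinates=pd.DataFrame(
            coords, index=expr.values.columns,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        variance_fraction=vf,
    )
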