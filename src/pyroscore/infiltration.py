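"""Signature-based cell-type scoring, significance gating, group comparison,
and the Spearman co-expression network over per-sample scores.

Cell-type abundance is approximated by scoring each cell type's marker-gene
signature with the ssGSEA statistic per sample. A permutation gate keeps
only cell types whose mean score exceeds what random same-size gene sets
achieve (empirical p < 0.05). Scores, together with pathway scores such as
the PES and the interferon-gamma response, feed a pairwise Spearman
correlation network whose headline readout is the cell type most correlated
with the PES column.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionMatrix
from .diffexpr import bh_adjust
from .enrichment import DEFAULT_ALPHA, _es_from_orders, _sample_orders
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)


def score_cell_types(expr: ExpressionMatrix, signatures: GeneSetCollection,
                     alpha: float = DEFAULT_ALPHA,
                     proportions: bool = False) -> pd.DataFrame:
    """Per-sample ssGSEA score of every cell-type signature.

    Returns a samples x cell-types table. Signatures overlapping the matrix
    in fewer than 2 genes are skipped with a warning. With
    ``proportions=True`` the scores of each sample are shifted to be
    non-negative and rescaled to sum to 1 across cell types (stacked-display
    convention only; they are not fractional abundances).
    """
    orders = _sample_orders(expr.values)
    cols: dict[str, np.ndarray] = {}
    for name, genes in signatures.sets.items():
        member = expr.values.index.isin(set(genes)).astype(float)
        if member.sum() < 2 or member.sum() == len(member):
            logger.warning("signature %r overlaps the matrix in <2 genes; skipped", name)
            continue
        cols[name] = _es_from_orders(orders, member, alpha)
    if not cols:
        raise ValueError("no signature overlaps the matrix in >= 2 genes")
    scores = pd.DataFrame(cols, index=expr.values.columns)
    if proportions:
        shifted = scores.to_numpy() - scores.to_numpy().min(axis=1, keepdims=True)
        row_sum = shifted.sum(axis=1, keepdims=True)
        row_sum[row_sum == 0] = 1.0
        scores = pd.DataFrame(shifted / row_sum, index=scores.index,
                              columns=scores.columns)
    return scores


def significance_filter(expr: ExpressionMatrix, signatures: GeneSetCollection,
                        n_null: int = 1000, seed: int = 0,
                        alpha: float = DEFAULT_ALPHA,
                        p_threshold: float = 0.05) -> list[str]:
    """Keep cell types whose mean score beats a random-signature null.

    For each signature, ``n_null`` random gene sets of the same size are
    scored and the empirical p-value is
    ``(1 + #{null mean >= observed mean}) / (n_null + 1)``; cell types with
    p below ``p_threshold`` are retained.
    """
    if n_null < 100:
        raise ValueError("need at least 100 null draws")
    rng = np.random.default_rng(seed)
    orders = _sample_orders(expr.values)
    n_genes = len(expr.genes)
    retained = []
    # cache null distributions per signature size: same-size sets share a null
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in signatures.sets.items():
        member = expr.values.index.isin(set(genes)).astype(float)
        size = int(member.sum())
        if size < 2 or size == n_genes:
            continue
        observed = _es_from_orders(orders, member, alpha).mean()
        if size not in null_cache:
            null_means = np.empty(n_null)
            for b in range(n_null):
                idx = rng.choice(n_genes, size=size, replace=False)
                mem = np.zeros(n_genes)
                mem[idx] = 1.0
                null_means[b] = _es_from_orders(orders, mem, alpha).mean()
            null_cache[size] = null_means
        null_means = null_cache[size]
        p = (1 + int((null_means >= observed).sum())) / (n_null + 1)
        if p < p_threshold:
            retained.append(name)
    return retained


def compare_groups(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mann-Whitney comparison of every score column between case and control.

    Returns per-column two-sided p, BH-adjusted q, and the direction of the
    case-vs-control median shift.
    """
    groups = groups.loc[scores.index]
    case = scores.loc[groups == "case"]
    ctrl = scores.loc[groups == "control"]
    if len(case) < 3 or len(ctrl) < 3:
        raise ValueError("each group needs >= 3 samples")
    rows = []
    for col in scores.columns:
        u, p = stats.mannwhitneyu(case[col], ctrl[col], alternative="two-sided")
        delta = case[col].median() - ctrl[col].median()
        rows.append({"score": col, "u": float(u), "p": float(p),
                     "median_diff": float(delta),
                     "direction": "up" if delta > 0 else ("down" if delta < 0 else "none")})
    out = pd.DataFrame(rows).set_index("score")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def correlation_network(scores: pd.DataFrame, q_threshold: float = 0.05,
                        pes_column: str = "PES",
                        celltype_columns: list[str] | None = None):
    """Pairwise Spearman network over score columns.

    Constant columns (rho undefined) are dropped with a warning. Returns a
    dict with the symmetric ``rho`` matrix, per-pair ``p``, a long-format
    ``edges`` table of BH-significant pairs (q below ``q_threshold``), and —
    when ``pes_column`` is present — ``top_pes_correlate``: the cell-type
    column with maximal |rho| against the PES column (restricted to
    ``celltype_columns`` when given, else every other column).
    """
    if len(scores) < 5:
        raise ValueError("need >= 5 samples for the correlation network")
    keep = [c for c in scores.columns if scores[c].nunique() > 1]
    dropped = [c for c in scores.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant score columns: %s", dropped)
    S = scores[keep]
    cols = list(S.columns)
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        r, p = stats.spearmanr(S.iloc[:, i], S.iloc[:, j])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    pairs = list(itertools.combinations(range(k), 2))
    pvec = np.array([pmat[i, j] for i, j in pairs])
    qvec = bh_adjust(np.clip(pvec, 0, 1)) if len(pvec) else pvec
    edges = pd.DataFrame(
        [{"score_a": cols[i], "score_b": cols[j], "rho": rho[i, j],
          "p": pmat[i, j], "q": q}
         for (i, j), q in zip(pairs, qvec)]
    )
    sig_edges = edges[edges["q"] < q_threshold].reset_index(drop=True) if len(edges) \
        else edges
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    result = {"rho": rho_df, "p": pd.DataFrame(pmat, index=cols, columns=cols),
              "edges": sig_edges, "all_pairs": edges}
    if pes_column in cols:
        candidates = [c for c in (celltype_columns or cols) if c in cols and c != pes_column]
        if candidates:
            series = rho_df.loc[pes_column, candidates].abs()
            result["top_pes_correlate"] = str(series.idxmax())
    return result
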