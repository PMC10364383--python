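"""Two-group differential expression and gene-set over-representation.

Per-gene Welch two-sample t tests on log2 expression (case minus control),
Benjamini-Hochberg control across genes, threshold-based DEG selection
(default: fold change > 2, i.e. |log2FC| > 1, and adjusted p < 0.05), and
upper-tail hypergeometric over-representation of a query list against a
user-supplied gene-set collection with a directional z-score per set
(z = (n_up - n_down) / sqrt(k) over the overlapping query genes).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix
from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

DE_COLUMNS = ["log2fc", "t", "p", "p_adj", "direction"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(expr: ExpressionMatrix, fc_threshold: float = 2.0,
            q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t test of case vs control on log2 values.

    Returns a table indexed by gene with columns ``log2fc`` (case mean minus
    control mean), ``t``, two-sided ``p``, BH-adjusted ``p_adj`` and a
    ``direction`` label in {up, down, ns} at the given fold-change /
    adjusted-p thresholds. Genes constant across the whole cohort get p = 1
    by convention and are flagged via the ``constant`` column.
    """
    case = expr.values[expr.group_samples("case")].to_numpy(dtype=float)
    ctrl = expr.values[expr.group_samples("control")].to_numpy(dtype=float)
    if case.shape[1] < 3 or ctrl.shape[1] < 3:
        raise ValueError(
            f"each group needs >= 3 samples (case {case.shape[1]}, "
            f"control {ctrl.shape[1]})"
        )
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    var_case = case.var(axis=1, ddof=1)
    var_ctrl = ctrl.var(axis=1, ddof=1)
    zero_var = (var_case == 0) & (var_ctrl == 0)
    constant = zero_var & (log2fc == 0)
    # degenerate rows: no within-group variance
    p[zero_var & (log2fc != 0)] = 0.0
    t[zero_var & (log2fc != 0)] = np.sign(log2fc[zero_var & (log2fc != 0)]) * np.inf
    p[constant] = 1.0
    t[constant] = 0.0
    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "p_adj": p_adj, "constant": constant},
        index=expr.values.index,
    )
    table["direction"] = _directions(table, fc_threshold, q_threshold)
    return table


def _directions(table: pd.DataFrame, fc_threshold: float, q_threshold: float) -> pd.Series:
    lfc_cut = math.log2(fc_threshold) if math.isfinite(fc_threshold) else math.inf
    sig = table["p_adj"] < q_threshold
    up = sig & (table["log2fc"] > lfc_cut)
    down = sig & (table["log2fc"] < -lfc_cut)
    out = pd.Series("ns", index=table.index)
    out[up] = "up"
    out[down] = "down"
    return out


def select_degs(table: pd.DataFrame, fc_threshold: float = 2.0,
                q_threshold: float = 0.05) -> tuple[list[str], list[str]]:
    """Split a DE table into (upregulated, downregulated) gene lists.

    ``fc_threshold`` is a fold change on the linear scale (2 means
    |log2FC| > 1); ``q_threshold`` applies to the BH-adjusted p.
    """
    if fc_threshold <= 0 or q_threshold < 0:
        raise ValueError("fc_threshold must be positive and q_threshold non-negative")
    direction = _directions(table, fc_threshold, q_threshold)
    up = table.index[direction == "up"].tolist()
    down = table.index[direction == "down"].tolist()
    return up, down


def ora_enrich(query: list[str], universe: list[str], sets: GeneSetCollection,
               directions: dict[str, str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first; sets disjoint from the
    universe are dropped with a warning. The per-set p-value is the
    upper-tail hypergeometric probability of drawing at least the observed
    overlap; BH adjustment is applied across sets. When ``directions`` maps
    query genes to ``up`` / ``down``, a directional z-score
    ``(n_up - n_down) / sqrt(k)`` is reported per set.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    uni = set(universe)
    qry = set(query)
    if not qry <= uni:
        raise ValueError(f"query genes outside universe: {sorted(qry - uni)[:10]}")
    N, n = len(uni), len(qry)
    rows = []
    for name, genes in sets.sets.items():
        members = set(genes) & uni
        if not members:
            logger.warning("gene set %r is disjoint from the universe; dropped", name)
            continue
        K = len(members)
        overlap = members & qry
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        if directions and k:
            n_up = sum(1 for g in overlap if directions.get(g) == "up")
            n_down = sum(1 for g in overlap if directions.get(g) == "down")
            z = (n_up - n_down) / math.sqrt(k)
        else:
            z = float("nan")
        rows.append({"set": name, "overlap": k, "set_size": K, "query_size": n,
                     "universe_size": N, "p": min(max(p, 0.0), 1.0), "z": z,
                     "genes": ",".join(sorted(overlap))})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")
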