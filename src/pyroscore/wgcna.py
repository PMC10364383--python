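"""Weighted co-expression module discovery and module-trait correlation.

A scaled-down, fully deterministic version of the classic weighted
co-expression workflow: soft-threshold selection by scale-free topology fit
over candidate powers 1-30 (accepting the smallest power whose signed fit
R^2 exceeds 0.8), unsigned adjacency |cor|^beta, topological overlap,
average-linkage hierarchical clustering with a static tree cut and a
minimum module size of 12, module eigengenes (first principal component of
the gene-standardised module submatrix), and Pearson module-trait
correlation selecting the module most related to the supplied traits (here:
PES, gamma-delta T infiltration, interferon-gamma response).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class SoftThresholdTable:
    """Scale-free fit per candidate power and the chosen power."""

    table: pd.DataFrame  # index: power; columns: r2_signed, mean_connectivity
    chosen: int
    passed: bool  # whether the chosen power cleared the target R^2


@dataclass
class ModuleSet:
    """Gene-to-module assignment with optional eigengenes.

    ``labels`` maps every gene to a colour-style module name; ``grey`` marks
    genes left unassigned (clusters below the minimum size).
    """

    labels: pd.Series
    eigengenes: pd.DataFrame | None = field(default=None)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique().tolist() if m != GREY]

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def genes_in(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()


def adjacency_matrix(expr: ExpressionMatrix, power: int) -> pd.DataFrame:
    """Unsigned weighted adjacency |cor(x_i, x_j)|^power with zero diagonal."""
    X = expr.values.to_numpy(dtype=float)
    corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    A = np.abs(corr) ** power
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=expr.values.index, columns=expr.values.index)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Connectivity is binned into equal-width bins; the fit is the squared
    correlation of log10 mean connectivity vs log10 frequency over non-empty
    bins, with the sign of the slope folded in (positive means a decaying
    degree distribution).
    """
    k = k[k > 0]
    if len(k) == 0:
        return 0.0, 0.0
    while n_bins > 2:
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        means, freqs = [], []
        for b in range(n_bins):
            mask = idx == b
            if mask.sum() > 0:
                means.append(k[mask].mean())
                freqs.append(mask.sum())
        if len(means) >= 3:
            break
        n_bins -= 1
        logger.warning("too few non-empty connectivity bins; reducing to %d", n_bins)
    if len(means) < 3 or len(set(means)) < 2 or len(set(freqs)) < 2:
        return 0.0, 0.0
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs, dtype=float))
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(expr: ExpressionMatrix,
                        powers: range | list[int] = range(1, 31),
                        target_r2: float = 0.8,
                        n_bins: int = 10) -> SoftThresholdTable:
    """Screen candidate powers for scale-free topology.

    The chosen power is the smallest with signed fit R^2 above ``target_r2``;
    when none qualifies, the best-fitting power is chosen with a warning.
    """
    if expr.values.shape[1] < 10:
        raise ValueError("need >= 10 samples for soft-threshold screening")
    X = expr.values.to_numpy(dtype=float)
    corr = np.nan_to_num(np.corrcoef(X), nan=0.0)
    abscor = np.abs(corr)
    np.fill_diagonal(abscor, 0.0)
    rows = []
    for beta in powers:
        A = abscor**beta
        k = A.sum(axis=1)
        r2, _ = _scale_free_fit(k, n_bins)
        rows.append({"power": int(beta), "r2_signed": r2,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table.index[table["r2_signed"] > target_r2]
    if len(qualifying):
        chosen, passed = int(qualifying[0]), True
    else:
        chosen, passed = int(table["r2_signed"].idxmax()), False
        logger.warning("no power reached signed R^2 > %.2f; using best power %d "
                       "(R^2 = %.3f)", target_r2, chosen,
                       table.loc[chosen, "r2_signed"])
    return SoftThresholdTable(table=table, chosen=chosen, passed=passed)


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap of an unsigned adjacency matrix.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u distinct from i and j; the diagonal is 1.
    """
    A = adjacency.to_numpy(dtype=float) if isinstance(adjacency, pd.DataFrame) \
        else np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (A < -1e-12).any() or (A > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(A)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    L = A @ A  # with a zero diagonal this is exactly the shared-neighbour sum
    denom = np.minimum.outer(k, k) + 1.0 - A
    omega = (L + A) / denom
    np.fill_diagonal(omega, 1.0)
    return omega


def detect_modules(diss_tom: np.ndarray, gene_ids: list[str],
                   min_size: int = 12, cut_fraction: float = 0.99) -> ModuleSet:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The tree is cut at ``cut_fraction`` times the maximum merge height;
    clusters smaller than ``min_size`` fall into ``grey``. Module colours are
    assigned by decreasing size (ties by first member's position, so labels
    are invariant to gene input order given the same dissimilarity).
    """
    D = np.asarray(diss_tom, dtype=float)
    if D.shape[0] != len(gene_ids):
        raise ValueError("dissimilarity size does not match gene ids")
    condensed = squareform(np.clip((D + D.T) / 2.0, 0, None), checks=False)
    Z = linkage(condensed, method="average")
    height = cut_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(gene_ids, name="gene"))
    clusters = []
    for cid in np.unique(raw):
        members = np.flatnonzero(raw == cid)
        if len(members) >= min_size:
            clusters.append((len(members), int(members[0]), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    if not clusters:
        logger.warning("no cluster reached the minimum module size; all genes grey")
    for rank, (_, _, members) in enumerate(clusters):
        name = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module{rank + 1}"
        labels.iloc[members] = name
    return ModuleSet(labels=labels)


def module_eigengenes(expr: ExpressionMatrix, modules: ModuleSet) -> pd.DataFrame:
    """First principal component of each module's gene-standardised submatrix.

    Eigengenes are unit-norm over samples and sign-aligned so that their
    correlation with the module's mean expression profile is non-negative.
    Constant genes carry no direction and are dropped; a module with no
    varying gene raises.
    """
    if not modules.module_names:
        raise ValueError("module set is empty")
    cols: dict[str, np.ndarray] = {}
    for module in modules.module_names:
        genes = [g for g in modules.genes_in(module) if g in expr.values.index]
        sub = expr.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        varying = sd > 0
        if not varying.any():
            raise ValueError(f"module {module!r} consists of constant genes")
        Z = (sub[varying] - sub[varying].mean(axis=1, keepdims=True)) / sd[varying, None]
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = Vt[0]
        profile = sub.mean(axis=0)
        align = np.corrcoef(eig, profile)[0, 1] if profile.std() > 0 else eig.sum()
        if align < 0:
            eig = -eig
        cols[module] = eig / np.linalg.norm(eig)
    out = pd.DataFrame(cols, index=expr.values.columns)
    modules.eigengenes = out
    return out


def module_trait(eigengenes: pd.DataFrame, traits: pd.DataFrame):
    """Pearson correlation of every module eigengene with every trait.

    Constant traits are dropped with a warning. Returns the long-format
    correlation table and the selected module: the one maximising the mean
    |r| across traits.
    """
    traits = traits.loc[eigengenes.index]
    keep = [c for c in traits.columns if traits[c].nunique() > 1]
    dropped = [c for c in traits.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant traits: %s", dropped)
    if not keep:
        raise ValueError("no non-constant trait")
    rows = []
    for module in eigengenes.columns:
        for trait in keep:
            r, p = stats.pearsonr(eigengenes[module], traits[trait])
            rows.append({"module": module, "trait": trait, "r": float(r),
                         "p": float(p)})
    table = pd.DataFrame(rows)
    mean_abs = table.groupby("module")["r"].apply(lambda s: s.abs().mean())
    selected = str(mean_abs.idxmax())
    return table, selected


def overlap_report(module_genes: list[str], hub_genes: list[str]) -> dict:
    """Venn-style intersection report between a module and a hub-gene list."""
    a, b = set(module_genes), set(hub_genes)
    return {
        "intersection": sorted(a & b),
        "module_only": sorted(a - b),
        "hub_only": sorted(b - a),
        "counts": {"module": len(a), "hub": len(b), "shared": len(a & b)},
    }
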