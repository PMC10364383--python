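"""Independent brute-force reference implementations used only by tests.

Each oracle is written as directly as possible from the definition of the
quantity it checks — explicit loops, enumeration, closed forms — and shares
no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def ssgsea_oracle(sample_values: dict[str, float], gene_set: set[str],
                  alpha: float) -> float:
    """Position-by-position ECDF summation for one sample.

    Materialises both cumulative distributions explicitly: genes sorted by
    expression descending (ties by gene id), rank weight r = N - pos + 1,
    the in-set ECDF weighted by r**alpha and the out-of-set ECDF uniform.
    """
    ordered = sorted(sample_values, key=lambda g: (-sample_values[g], g))
    N = len(ordered)
    r = {g: N - pos for pos, g in enumerate(ordered)}  # pos 0-based -> r = N-pos
    total_in = sum(r[g] ** alpha for g in ordered if g in gene_set)
    n_out = N - sum(1 for g in ordered if g in gene_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for g in ordered:
        if g in gene_set:
            cum_in += r[g] ** alpha / total_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Quadratic-time Benjamini-Hochberg step-up adjustment.

    adj_i = min over all j with p_j >= p_i of m * p_j / rank(p_j), capped at 1.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    rank = {}
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    adj = []
    for i in range(m):
        candidates = [m * pvalues[j] / rank[j] for j in range(m)
                      if pvalues[j] >= pvalues[i]]
        adj.append(min(1.0, min(candidates)))
    return adj


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n) by direct summation."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (average ranks for ties), then Pearson."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = A.shape[0]
    k = A.sum(axis=1)
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            omega[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return omega


def eigengene_oracle(Z: np.ndarray) -> np.ndarray:
    """Leading right eigenvector of Z via the eigen-decomposition of Z'Z,
    unit norm; sign is left ambiguous (compare up to sign)."""
    M = Z.T @ Z
    w, V = np.linalg.eigh(M)
    v = V[:, np.argmax(w)]
    return v / np.linalg.norm(v)


def auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney pair counting with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def logistic_ml_oracle(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                       tol: float = 1e-12) -> np.ndarray:
    """Unpenalised logistic maximum likelihood by Newton-Raphson.

    Returns (intercept, coefficients...).
    """
    n, p = X.shape
    D = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = D @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        W = prob * (1 - prob)
        grad = D.T @ (y - prob)
        H = D.T @ (D * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def densest_subgraph_oracle(G: nx.Graph, seed=None) -> float:
    """Best density * size over connected induced subgraphs with a 2-core.

    Exhaustive enumeration; ``seed`` restricts to subgraphs containing that
    node. Feasible for graphs of at most ~8 nodes.
    """
    nodes = list(G.nodes)
    best = 0.0
    for size in range(3, len(nodes) + 1):
        for combo in itertools.combinations(nodes, size):
            if seed is not None and seed not in combo:
                continue
            sub = G.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            if nx.k_core(sub, 2).number_of_nodes() == 0:
                continue
            n, m = sub.number_of_nodes(), sub.number_of_edges()
            best = max(best, (2.0 * m / (n * (n - 1))) * n)
    return best


def degree_recount_oracle(G: nx.Graph) -> dict[str, int]:
    """Count each node's incident edges by scanning the edge list."""
    deg = {str(v): 0 for v in G.nodes}
    for a, b in G.edges:
        deg[str(a)] += 1
        deg[str(b)] += 1
    return deg
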