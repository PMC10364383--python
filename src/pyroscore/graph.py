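"""Hub-gene recognition on an interaction graph.

Edges of a user-supplied weighted interaction network (e.g. a STRING export)
are filtered at a confidence threshold (default: keep interaction score
> 0.4), dense complexes are detected with the MCODE procedure (vertex
weighting by the core-clustering coefficient of the closed neighbourhood,
greedy seeded expansion, haircut post-processing, ranking by density x
size), and nodes are ranked by degree. Hub genes are the members of the
top-ranked complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class Complex:
    members: list[str]
    density: float
    score: float  # density * size


@dataclass
class ComplexResult:
    complexes: list[Complex]  # ranked by score descending

    @property
    def hub_genes(self) -> list[str]:
        return self.complexes[0].members if self.complexes else []


def load_graph(edge_list_path: str | Path, weight_threshold: float = 0.4) -> nx.Graph:
    """Read a weighted edge list (TSV ``node_a  node_b  score`` or SIF).

    Edges with weight strictly above ``weight_threshold`` are retained;
    duplicate edges collapse to the maximum weight; self-loops and nodes left
    isolated by the filter are dropped.
    """
    path = Path(edge_list_path)
    G = nx.Graph()
    lines = path.read_text().splitlines()
    is_sif = path.suffix.lower() == ".sif"
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and not is_sif:
            # tolerate a header row
            try:
                float(fields[2])
            except (IndexError, ValueError):
                if len(fields) >= 3:
                    continue
        if is_sif:
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: SIF needs 'node rel node'")
            a, b, w = fields[0], fields[2], 1.0
        else:
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 'node_a node_b score'")
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric weight {fields[2]!r}"
                ) from None
        if a == b:
            continue
        if w > weight_threshold:
            if G.has_edge(a, b):
                G[a][b]["weight"] = max(G[a][b]["weight"], w)
            else:
                G.add_edge(a, b, weight=w)
    if G.number_of_edges() == 0:
        logger.warning("no edge passed the weight threshold %.3f", weight_threshold)
    return G


def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def _highest_k_core(G: nx.Graph) -> tuple[int, nx.Graph]:
    """The last non-empty k-core under repeated pruning, with its k."""
    if G.number_of_nodes() == 0:
        return 0, G
    core = nx.core_number(G)
    k_max = max(core.values())
    nodes = [v for v, c in core.items() if c >= k_max]
    return k_max, G.subgraph(nodes)


def mcode_vertex_weights(G: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: k * density of the highest k-core of N[v]."""
    weights: dict[str, float] = {}
    for v in G.nodes:
        closed = list(G.neighbors(v)) + [v]
        k, core = _highest_k_core(G.subgraph(closed))
        weights[v] = k * _density(core)
    return weights


def mcode(G: nx.Graph, vwp: float = 0.2, haircut: bool = True,
          fluff: bool = False) -> ComplexResult:
    """Detect dense complexes with the MCODE procedure.

    Seeds are visited in decreasing vertex weight (ties by node id); from
    each unused seed a breadth-first expansion includes neighbours whose
    weight is at least ``seed_weight * (1 - vwp)``, each node joining at most
    one complex. ``haircut`` iteratively removes degree-1 members; complexes
    without a 2-core are discarded. Complexes are ranked by density x size.
    ``fluff`` is accepted for interface parity and is a no-op.
    """
    if fluff:
        logger.warning("fluff post-processing is not implemented; ignored")
    weights = mcode_vertex_weights(G)
    order = sorted(G.nodes, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in used:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(G.neighbors(v), key=str):
                    if u in used or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        used |= members
        sub = nx.Graph(G.subgraph(members))
        if haircut:
            while True:
                leaves = [v for v in sub.nodes if sub.degree(v) <= 1]
                if not leaves or sub.number_of_nodes() <= len(leaves):
                    break
                sub.remove_nodes_from(leaves)
        # a complex must contain a 2-core
        if sub.number_of_nodes() < 3:
            continue
        core = nx.k_core(sub, 2)
        if core.number_of_nodes() == 0:
            continue
        dens = _density(sub)
        complexes.append(Complex(members=sorted(sub.nodes, key=str), density=dens,
                                 score=dens * sub.number_of_nodes()))
    complexes.sort(key=lambda c: (-c.score, c.members))
    return ComplexResult(complexes=complexes)


def degree_ranking(G: nx.Graph) -> list[tuple[str, int]]:
    """Nodes sorted by unweighted degree descending, ties by node id."""
    return sorted(((str(v), int(d)) for v, d in G.degree()),
                  key=lambda t: (-t[1], t[0]))
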