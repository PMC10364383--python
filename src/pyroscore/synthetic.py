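"""Synthetic two-group cohorts with fully known ground truth.

The generator emulates the statistical structure of a merged case/control
duodenal transcriptome study on the log2 scale: microarray-like baseline
expression, planted differentially expressed genes with known direction,
directional pyroptosis gene sets drawn from the planted DE genes (default
split 18 up / 8 down of a 65-gene pathway list), cell-type signature
elevation in cases with a shared latent abundance driver (a gamma-delta
T-cell-like axis that co-varies with the pyroptosis and interferon-gamma
response genes), block-correlated gene modules driven by latent traits,
additive/multiplicative batch effects across sub-cohorts, and interaction
graphs with planted dense complexes. Every downstream stage of the
pipeline can therefore be checked against planted truth.

All randomness flows through one seeded generator; identical seeds yield
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix
from .genesets import GeneSetCollection


@dataclass
class CellTypeProfile:
    """A planted cell-type signature: size, case elevation, category.

    ``latent_driver`` marks the cell type whose per-sample abundance follows
    the cohort's shared latent axis (the gamma-delta T-cell analogue); other
    profiles shift by ``elevation`` in cases only.
    """

    n_genes: int = 25
    elevation: float = 0.5  # log2 shift added to signature genes in cases
    category: str = "lymphoid"
    latent_driver: bool = False


def default_celltype_profiles() -> dict[str, CellTypeProfile]:
    """Cell types emulated by default, with the gamma-delta T axis dominant."""
    return {
        "Tgd": CellTypeProfile(25, 1.0, "lymphoid", latent_driver=True),
        "CD8_T": CellTypeProfile(25, 0.5, "lymphoid"),
        "NK": CellTypeProfile(25, 0.5, "lymphoid"),
        "B_cells": CellTypeProfile(25, 0.3, "lymphoid"),
        "Macrophage": CellTypeProfile(25, 0.5, "myeloid"),
        "Dendritic": CellTypeProfile(25, 0.3, "myeloid"),
        "Fibroblast": CellTypeProfile(25, 0.0, "stromal"),
        "Epithelial": CellTypeProfile(25, -0.5, "epithelial"),
    }


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the merged derivation cohort: 48 cases vs 51 controls
    across 3 sub-cohort batches, log2-scale baseline ~ Normal(7, 1), 5% of
    genes differentially expressed at 1 log2 unit, and a pyroptosis gene set
    splitting 18 up / 8 down.
    """

    n_genes: int = 2000
    n_case: int = 48
    n_control: int = 51
    n_batches: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    pyro_up_size: int = 18
    pyro_down_size: int = 8
    ifng_size: int = 20
    celltype_profiles: dict[str, CellTypeProfile] = field(
        default_factory=default_celltype_profiles)
    module_blocks: list[tuple[int, float]] = field(default_factory=list)
    driver_block: int | None = None   # block whose latent is the shared driver
    driver_coupling: float = 0.5      # log2 shift per driver SD on pyro/IFN genes
    batch_shift: float = 0.0          # additive shift per batch step
    batch_scale: float = 1.0          # multiplicative scale per batch step
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_case", "n_control", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must lie in (0, 1)")
        n_de = round(self.de_fraction * self.n_genes)
        n_up = (n_de + 1) // 2
        n_down = n_de - n_up
        if self.pyro_up_size > n_up or self.pyro_down_size > n_down:
            raise ValueError(
                f"pyroptosis set sizes ({self.pyro_up_size} up, "
                f"{self.pyro_down_size} down) exceed planted DE genes "
                f"({n_up} up, {n_down} down)"
            )
        if self.pyro_up_size < 2 or self.pyro_down_size < 2:
            raise ValueError("pyroptosis sets need >= 2 genes each")
        budget = n_de + self.ifng_size + sum(
            p.n_genes for p in self.celltype_profiles.values()
        ) + sum(size for size, _ in self.module_blocks)
        if budget > self.n_genes:
            raise ValueError(
                f"planted structures need {budget} genes but the universe has "
                f"{self.n_genes}; planted sets must be disjoint"
            )
        for size, r in self.module_blocks:
            if size < 2 or not 0 < r < 1:
                raise ValueError("module blocks need size >= 2 and r in (0, 1)")
        if self.driver_block is not None and not (
                0 <= self.driver_block < len(self.module_blocks)):
            raise ValueError("driver_block out of range")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    genes: list[str]
    de_up: list[str]
    de_down: list[str]
    pyro_up: list[str]
    pyro_down: list[str]
    ifng_genes: list[str]
    celltype_genes: dict[str, list[str]]
    celltype_abundance: pd.DataFrame      # samples x cell types (planted shift)
    driver_latent: pd.Series              # the shared latent axis per sample
    module_labels: pd.Series              # gene -> block name ('' = background)
    block_latents: pd.DataFrame           # samples x blocks
    batch: pd.Series

    def block_genes(self, index: int) -> list[str]:
        name = f"block{index}"
        return self.module_labels.index[self.module_labels == name].tolist()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "de_up": self.de_up, "de_down": self.de_down,
            "pyro_up": self.pyro_up, "pyro_down": self.pyro_down,
            "ifng_genes": self.ifng_genes,
            "celltype_genes": self.celltype_genes,
            "celltype_abundance": self.celltype_abundance.to_dict(orient="index"),
            "driver_latent": self.driver_latent.to_dict(),
            "module_labels": {g: m for g, m in self.module_labels.items() if m},
            "block_latents": self.block_latents.to_dict(orient="index"),
            "batch": self.batch.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a labelled synthetic cohort from a :class:`SyntheticSpec`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_case + spec.n_control
    width = max(5, len(str(spec.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    samples = [f"case_{i + 1}" for i in range(spec.n_case)] + \
              [f"ctrl_{i + 1}" for i in range(spec.n_control)]
    groups = ["case"] * spec.n_case + ["control"] * spec.n_control
    batches = [f"batch{(i % spec.n_batches) + 1}" for i in range(n_samples)]
    case_mask = np.array([g == "case" for g in groups])

    # disjoint planted-gene layout
    n_de = round(spec.de_fraction * spec.n_genes)
    n_up = (n_de + 1) // 2
    cursor = 0
    de_up_idx = np.arange(cursor, cursor + n_up); cursor += n_up
    de_down_idx = np.arange(cursor, cursor + (n_de - n_up)); cursor += n_de - n_up
    pyro_up_idx = de_up_idx[: spec.pyro_up_size]
    pyro_down_idx = de_down_idx[: spec.pyro_down_size]
    ifng_idx = np.arange(cursor, cursor + spec.ifng_size); cursor += spec.ifng_size
    celltype_idx: dict[str, np.ndarray] = {}
    for name, prof in spec.celltype_profiles.items():
        celltype_idx[name] = np.arange(cursor, cursor + prof.n_genes)
        cursor += prof.n_genes
    block_idx: list[np.ndarray] = []
    for size, _ in spec.module_blocks:
        block_idx.append(np.arange(cursor, cursor + size))
        cursor += size

    X = rng.normal(spec.baseline_mean, spec.baseline_sd,
                   size=(spec.n_genes, n_samples))

    # planted group effects
    X[np.ix_(de_up_idx, np.flatnonzero(case_mask))] += spec.de_log2fc
    X[np.ix_(de_down_idx, np.flatnonzero(case_mask))] -= spec.de_log2fc
    X[np.ix_(ifng_idx, np.flatnonzero(case_mask))] += spec.de_log2fc

    # shared latent axis (gamma-delta T abundance analogue), standard normal
    eps = rng.normal(0.0, 1.0, size=n_samples)
    abundance = {}
    for name, prof in spec.celltype_profiles.items():
        a = prof.elevation * case_mask.astype(float)
        if prof.latent_driver:
            a = a + eps
        abundance[name] = a
        X[celltype_idx[name]] += a[None, :]
    # couple pyroptosis and interferon-response genes to the driver axis
    X[pyro_up_idx] += spec.driver_coupling * eps[None, :]
    X[pyro_down_idx] -= spec.driver_coupling * eps[None, :]
    X[ifng_idx] += spec.driver_coupling * eps[None, :]

    # block-correlated modules
    block_latents = {}
    for b, (size, r) in enumerate(spec.module_blocks):
        v = eps if b == spec.driver_block else rng.normal(0.0, 1.0, n_samples)
        loading = spec.baseline_sd * np.sqrt(r / (1.0 - r))
        X[block_idx[b]] += loading * v[None, :]
        block_latents[f"block{b}"] = v

    # batch distortion: location/scale around the per-gene mean
    if spec.n_batches > 1 and (spec.batch_shift != 0 or spec.batch_scale != 1):
        gene_mean = X.mean(axis=1, keepdims=True)
        for bi in range(spec.n_batches):
            cols = np.flatnonzero(np.array(batches) == f"batch{bi + 1}")
            shift = spec.batch_shift * bi
            scale = spec.batch_scale**bi
            X[:, cols] = (X[:, cols] - gene_mean) * scale + gene_mean + shift

    values = pd.DataFrame(X, index=genes, columns=samples)
    metadata = pd.DataFrame({"group": groups, "batch": batches},
                            index=pd.Index(samples, name="sample"))
    expr = ExpressionMatrix(values=values, metadata=metadata)

    module_labels = pd.Series("", index=pd.Index(genes, name="gene"))
    for b, idx in enumerate(block_idx):
        module_labels.iloc[idx] = f"block{b}"
    truth = GroundTruth(
        genes=genes,
        de_up=[genes[i] for i in de_up_idx],
        de_down=[genes[i] for i in de_down_idx],
        pyro_up=[genes[i] for i in pyro_up_idx],
        pyro_down=[genes[i] for i in pyro_down_idx],
        ifng_genes=[genes[i] for i in ifng_idx],
        celltype_genes={n: [genes[i] for i in idx] for n, idx in celltype_idx.items()},
        celltype_abundance=pd.DataFrame(abundance, index=samples),
        driver_latent=pd.Series(eps, index=samples, name="driver"),
        module_labels=module_labels,
        block_latents=pd.DataFrame(block_latents, index=samples),
        batch=metadata["batch"],
    )
    return expr, truth


def make_genesets(spec: SyntheticSpec, truth: GroundTruth, n_decoys: int = 0,
                  decoy_size: int = 20, seed: int | None = None) -> GeneSetCollection:
    """Gene sets matching the planted structure, plus optional random decoys.

    Emits ``pyro_up`` / ``pyro_down`` / ``pyro_all`` (the directional
    pyroptosis sets and their union), ``ifng_response``, one signature per
    cell type (category-tagged), and ``decoy_<i>`` sets drawn uniformly from
    the gene universe.
    """
    if n_decoys and decoy_size <= 0:
        raise ValueError("decoy_size must be positive")
    sets: dict[str, list[str]] = {
        "pyro_up": list(truth.pyro_up),
        "pyro_down": list(truth.pyro_down),
        "pyro_all": list(truth.pyro_up) + list(truth.pyro_down),
        "ifng_response": list(truth.ifng_genes),
    }
    categories = {name: "pathway" for name in sets}
    for name, prof in spec.celltype_profiles.items():
        sets[name] = list(truth.celltype_genes[name])
        categories[name] = prof.category
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    for d in range(n_decoys):
        draw = rng.choice(len(truth.genes), size=decoy_size, replace=False)
        sets[f"decoy_{d + 1}"] = [truth.genes[i] for i in sorted(draw)]
        categories[f"decoy_{d + 1}"] = "decoy"
    return GeneSetCollection(sets=sets, categories=categories)


def make_graph(n_nodes: int, planted_cliques: list[int],
               background_edge_p: float, seed: int = 0,
               ) -> tuple[nx.Graph, list[list[str]]]:
    """Random background graph with planted fully-connected complexes.

    Cliques occupy disjoint node ranges; background edges appear
    independently with probability ``background_edge_p`` and carry a weight
    above the conventional 0.4 confidence cut so the loader keeps them.
    """
    if any(size < 3 for size in planted_cliques):
        raise ValueError("planted clique sizes must be >= 3")
    if sum(planted_cliques) > n_nodes:
        raise ValueError("planted cliques exceed the number of nodes")
    if not 0 <= background_edge_p <= 1:
        raise ValueError("background_edge_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:03d}" for i in range(1, n_nodes + 1)]
    G = nx.Graph()
    G.add_nodes_from(nodes)
    if background_edge_p > 0:
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < background_edge_p:
                    G.add_edge(nodes[i], nodes[j],
                               weight=float(rng.uniform(0.41, 1.0)))
    cliques: list[list[str]] = []
    cursor = 0
    for size in planted_cliques:
        members = nodes[cursor: cursor + size]
        cursor += size
        for i in range(size):
            for j in range(i + 1, size):
                G.add_edge(members[i], members[j], weight=0.9)
        cliques.append(members)
    return G, cliques


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Write a graph as a ``node_a  node_b  score`` TSV."""
    lines = ["node_a\tnode_b\tscore"]
    for a, b, data in sorted(G.edges(data=True)):
        lines.append(f"{a}\t{b}\t{data.get('weight', 1.0):.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
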