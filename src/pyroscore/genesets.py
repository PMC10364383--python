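"""Named gene-set collections and GMT input/output.

A gene-set collection maps set names to gene lists and optionally carries a
category tag per set (used for cell-type signatures, e.g. ``lymphoid`` /
``myeloid``). The on-disk format is GMT: one set per line, tab-separated as
``name <tab> description <tab> gene1 <tab> gene2 ...``. Readers tolerate
space-delimited description fields, which some exporters produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


@dataclass
class GeneSetCollection:
    """Mapping of unique set names to non-empty gene lists.

    Parameters
    ----------
    sets
        ``name -> list of gene ids``. Names must be unique (enforced by the
        dict) and every set must be non-empty.
    categories
        Optional ``name -> category`` tags; any subset of ``sets`` keys.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        unknown = set(self.categories) - set(self.sets)
        if unknown:
            raise ValueError(f"categories refer to unknown sets: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: list[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"unknown gene sets: {missing}")
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            categories={n: c for n, c in self.categories.items() if n in names},
        )

    def restrict_to(self, universe: list[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that vanish."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if inter:
                kept[name] = inter
        return GeneSetCollection(
            sets=kept,
            categories={n: c for n, c in self.categories.items() if n in kept},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    The second field is the description; when it carries a ``category=...``
    token (our writer's convention) it becomes the set's category tag. Lines
    whose name and description are separated by spaces instead of a tab are
    accepted.
    """
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            # tolerate "name description<TAB>genes..." with a space-separated
            # description field
            head, *rest = line.split("\t")
            parts = head.split(None, 1)
            if len(parts) == 2 and rest:
                fields = [parts[0], parts[1], *rest]
            else:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        sets[name] = genes
        for token in desc.split():
            if token.startswith("category="):
                categories[name] = token.split("=", 1)[1]
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, encoding categories in the description."""
    lines = []
    for name, genes in collection.sets.items():
        cat = collection.categories.get(name)
        desc = f"category={cat}" if cat else "na"
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
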