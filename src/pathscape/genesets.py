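"""Gene-set collections: GMT ingestion, symbol harmonization, size filtering.

Gene sets ("pathways") are unordered sets of HUGO-style gene symbols with a
source-database tag.  Pathway topology is deliberately ignored: the scoring
engine only asks whether a gene is a member.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

KNOWN_SOURCES = ("KEGG", "BIOCARTA", "PWC", "GO", "WIKIPW")


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than 3 tab-separated fields)."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase gene symbols with an origin tag."""

    name: str
    genes: frozenset[str]
    source: str = "USER"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered list of uniquely named gene sets, optionally restricted to a
    measured-gene universe."""

    sets: list[GeneSet] = field(default_factory=list)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)


def read_gmt(path: str | Path, source: str = "USER") -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, genes...).

    Symbols are uppercased and deduplicated within each line; the description
    field is kept as metadata.  Blank lines are skipped.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, source=source, description=description))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT; genes sorted for reproducible output."""
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def harmonize_symbols(
    collection: GeneSetCollection, alias_map: Mapping[str, str]
) -> GeneSetCollection:
    """Map alias symbols to canonical ones and re-deduplicate each set.

    Unmapped symbols pass through unchanged.  Keys and values are compared
    case-insensitively (everything is uppercased).
    """
    norm: dict[str, str] = {}
    for alias, canon in alias_map.items():
        if not canon or not str(canon).strip():
            raise ValueError(f"alias {alias!r} maps to an empty canonical symbol")
        norm[str(alias).strip().upper()] = str(canon).strip().upper()
    new_sets = [
        replace(s, genes=frozenset(norm.get(g, g) for g in s.genes)) for s in collection.sets
    ]
    return GeneSetCollection(sets=new_sets, universe=collection.universe)


def filter_sets(
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_size: int = 10,
    max_size: int = 1000,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Restrict sets to a measured-gene universe and drop out-of-bounds sets.

    Sizes are counted AFTER intersection with the universe, because the
    scoring null depends only on members actually present in the ranked
    list.  A set is retained iff ``min_size <= size <= max_size``.

    Returns the filtered collection and a removal report with columns
    (name, original_size, effective_size, reason).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    uni = frozenset(g.upper() for g in universe) if universe is not None else None

    kept: list[GeneSet] = []
    removed: list[dict] = []
    for s in collection.sets:
        genes = s.genes & uni if uni is not None else s.genes
        size = len(genes)
        if size < min_size:
            removed.append(
                {"name": s.name, "original_size": s.size, "effective_size": size,
                 "reason": f"too_small(<{min_size})"}
            )
        elif size > max_size:
            removed.append(
                {"name": s.name, "original_size": s.size, "effective_size": size,
                 "reason": f"too_large(>{max_size})"}
            )
        else:
            kept.append(replace(s, genes=frozenset(genes)))
    report = pd.DataFrame(removed, columns=["name", "original_size", "effective_size", "reason"])
    return GeneSetCollection(sets=kept, universe=uni), report
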