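"""Pathway gene-set curation.

Reads Reactome-style gene-set collections from GMT files and applies the
size/blacklist filters that define the prediction label space: pathways with
more than ``max_genes`` members are considered too generic to describe a
specific mechanism of action, and explicitly blacklisted sets (by default the
substrate-organised cytochrome-P450 collection, a metabolism catalogue rather
than a mechanism) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Pathway",
    "PathwayCollection",
    "PathwayFilterConfig",
    "GMTParseError",
    "read_gmt",
    "write_gmt",
    "filter_pathways",
]

DEFAULT_MAX_GENES = 65
DEFAULT_BLACKLIST = ("CYTOCHROME_P450_ARRANGED_BY_SUBSTRATE_TYPE",)


class GMTParseError(ValueError):
    """Raised for malformed GMT input; message carries the line number."""


@dataclass(frozen=True)
class Pathway:
    """A named gene set.

    Parameters
    ----------
    id : str
        Unique pathway name, non-empty.
    description : str
        Free-text description (second GMT column).
    genes : frozenset of str
        Member gene symbols; duplicates collapse by set semantics.
    """

    id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pathway id must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """Ordered collection of pathways with unique ids.

    Order is the load order and is stable: it defines each pathway's index in
    the model's output layer.
    """

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: list[Pathway] = list(pathways)
        self.index: dict[str, int] = {}
        for pos, p in enumerate(self.pathways):
            if p.id in self.index:
                raise ValueError(f"duplicate pathway id: {p.id!r}")
            self.index[p.id] = pos

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __getitem__(self, key: int | str) -> Pathway:
        if isinstance(key, str):
            return self.pathways[self.index[key]]
        return self.pathways[key]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self.pathways == other.pathways

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]


@dataclass(frozen=True)
class PathwayFilterConfig:
    """Label-space filter settings.

    max_genes : keep pathways with at most this many genes (default 65;
        "large" means strictly more than 65 members).
    blacklist : pathway names to drop regardless of size.
    substring_match : when True, a blacklist entry removes any pathway whose
        name contains it; default is exact-name matching.
    """

    max_genes: int = DEFAULT_MAX_GENES
    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST
    substring_match: bool = False

    def __post_init__(self) -> None:
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")
        object.__setattr__(self, "blacklist", tuple(self.blacklist))

    def blacklisted(self, pathway_id: str) -> bool:
        if self.substring_match:
            return any(entry in pathway_id for entry in self.blacklist)
        return pathway_id in self.blacklist


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file into a :class:`PathwayCollection`.

    Each non-blank line is ``name<TAB>description<TAB>gene[<TAB>gene...]``.
    Genes are deduplicated; line order is preserved; gene-symbol case is kept
    exactly as read.

    Raises
    ------
    GMTParseError
        If a line has fewer than three tab-separated fields.
    ValueError
        If two lines share a pathway name.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GMTParseError(f"{path.name}:{lineno}: gene set is empty")
            pathways.append(Pathway(id=name, description=description, genes=genes))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection back to GMT; genes are written sorted for stability."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.id, p.description, *sorted(p.genes)]) + "\n")


def filter_pathways(
    collection: PathwayCollection,
    config: PathwayFilterConfig | None = None,
) -> PathwayCollection:
    """Apply the size and blacklist filters, preserving relative order.

    A pathway is retained iff its gene count is at most ``config.max_genes``
    and its name is not blacklisted. Idempotent by construction.
    """
    if config is None:
        config = PathwayFilterConfig()
    kept = [
        p
        for p in collection
        if p.size <= config.max_genes and not config.blacklisted(p.id)
    ]
    return PathwayCollection(kept)
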