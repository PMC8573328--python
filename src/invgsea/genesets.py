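"""Gene sets and GMT-format I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (GMT row analogue)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(g.strip().upper() for g in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        return self.members & set(universe)


@dataclass
class SignedGeneSet:
    """A gene set with a per-gene regulation direction (+1 up, -1 down).

    Used for direction-aware enrichment: when scored against a ranked list,
    down-genes have their ranking metric negated so that concordant
    regulation accumulates at the top of the list.
    """

    name: str
    directions: dict[str, int]
    description: str = ""

    def __post_init__(self) -> None:
        self.directions = {
            g.strip().upper(): (1 if d > 0 else -1) for g, d in self.directions.items()
        }

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene-set names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def filter_by_size(
        self, universe: Iterable[str], min_size: int = 1, max_size: int | None = None
    ) -> "GeneSetCollection":
        """Keep sets whose overlap with ``universe`` lies in [min_size, max_size]."""
        uni = set(universe)
        kept = []
        for s in self.sets:
            n = len(s.members & uni)
            if n >= min_size and (max_size is None or n <= max_size):
                kept.append(s)
        return GeneSetCollection(kept)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: name, description, member genes."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields")
        name, desc, *members = parts
        members = [m for m in members if m.strip()]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name=name, members=frozenset(members), description=desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
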