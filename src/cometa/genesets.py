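"""Gene-set / drug-set collections and the GMT file format.

GMT is one set per line: name, description, then tab-separated members.
The same container serves gene sets (pathway libraries) and drug sets
(therapeutic classes over perturbation ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class GeneSetCollection:
    """Named sets of items over an optional universe.

    ``sets`` maps set name to an ordered, duplicate-free member list.
    ``universe`` is the item namespace the sets live in; empty means
    unrestricted.
    """

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate set name {name!r}")
            clean[name] = list(dict.fromkeys(members))
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe: list[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe`` (order of ``universe`` kept)."""
        uni = set(universe)
        return GeneSetCollection(
            {n: [m for m in mem if m in uni] for n, mem in self.sets.items()},
            list(universe),
        )

    def filter_size(self, min_size: int = 5, max_size: int = 500) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: m for n, m in self.sets.items() if min_size <= len(m) <= max_size},
            self.universe,
        )

    def write_gmt(self, path: str | Path, descriptions: dict[str, str] | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *members]) + "\n")
        return path


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} in {path}")
            sets[name] = members
    return GeneSetCollection(sets, universe or [])
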