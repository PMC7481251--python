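"""Signed gene sets and GMT serialization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class SignedGeneSets:
    """Up- and down-regulated gene sets with their universe.

    Invariants: up and down are disjoint and both contained in the universe.
    """

    up: frozenset
    down: frozenset
    universe: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        self.universe = frozenset(self.universe)
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("up/down sets not contained in the universe")

    def restricted_to(self, universe) -> "SignedGeneSets":
        u = frozenset(universe)
        return SignedGeneSets(self.up & u, self.down & u, self.universe & u, self.label)

    @property
    def all_signed(self) -> frozenset:
        return self.up | self.down


def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file: name TAB description TAB member TAB member...

    Duplicate members within a line are deduplicated with a warning; lines
    with fewer than three fields or no members raise with the line number.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(f"{path}:{lineno}: duplicated members in {name!r} deduplicated")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {"description": desc, "genes": unique}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, rec in sets.items():
            genes = rec["genes"]
            if not genes:
                raise ValueError(f"gene set {name!r} has no members")
            fh.write("\t".join([name, rec.get("description", "")] + list(genes)) + "\n")
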