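"""Set algebra over DEG programs: Venn partitions, shared cores, and
unique up-regulated genes between two datasets restricted to a common
universe (e.g. a fibrotic vs a carcinoma EMT program matched by gene id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

__all__ = ["DEGProgram", "overlap_report", "core_genes", "unique_up_sets"]


@dataclass
class DEGProgram:
    """A named differential-expression program: disjoint up/down gene
    sets in a declared identifier space."""

    name: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    id_space: str = "symbol"

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        both = self.up & self.down
        if both:
            raise ValueError(
                f"program {self.name}: {len(both)} genes both up and down"
            )

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def restricted(self, universe: set[str]) -> "DEGProgram":
        return DEGProgram(
            name=self.name,
            up=self.up & universe,
            down=self.down & universe,
            id_space=self.id_space,
        )


def _check_id_spaces(programs: Sequence[DEGProgram]) -> None:
    spaces = {p.id_space for p in programs}
    if len(spaces) > 1:
        raise ValueError(f"programs mix id spaces: {sorted(spaces)}")


def overlap_report(programs: Sequence[DEGProgram]) -> dict[str, int]:
    """Counts for every non-empty region of the Venn partition.

    Keys name the region by the programs a gene belongs to, joined with
    ``&`` (e.g. ``"CM-CE&T1E-CE"``); region counts sum to the size of
    the union.
    """
    if not programs:
        raise ValueError("need at least one program")
    _check_id_spaces(programs)
    names = [p.name for p in programs]
    if len(set(names)) != len(names):
        raise ValueError("program names must be unique")
    report: dict[str, int] = {}
    for r in range(1, len(programs) + 1):
        for members in combinations(range(len(programs)), r):
            inside = set.intersection(*(programs[i].genes for i in members))
            for i in range(len(programs)):
                if i not in members:
                    inside -= programs[i].genes
            report["&".join(names[i] for i in members)] = len(inside)
    return report


def core_genes(programs: Sequence[DEGProgram]) -> set[str]:
    """Genes of the first program shared with at least one other —
    e.g. the TGFβ-regulated genes also responsive to TNF at either
    time point."""
    if len(programs) < 2:
        raise ValueError("core needs a reference program plus >=1 other")
    _check_id_spaces(programs)
    others: set[str] = set()
    for p in programs[1:]:
        others |= p.genes
    return programs[0].genes & others


def unique_up_sets(
    a: DEGProgram, b: DEGProgram, common_universe: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Up-regulated genes exclusive to each of two programs after
    restriction to a shared detected-gene universe."""
    universe = set(common_universe)
    if not universe:
        raise ValueError("empty common universe")
    _check_id_spaces([a, b])
    ra, rb = a.restricted(universe), b.restricted(universe)
    return ra.up - rb.up, rb.up - ra.up
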