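"""EC/TM/IC region annotation of a membrane receptor chain.

A seven-transmembrane receptor threads the membrane so that each helix end
faces either the extracellular (EC) or intracellular (IC) compartment,
alternating from helix to helix.  Each helix is split into three
sub-regions: a central transmembrane (TM) stretch and two flanking
stretches that are assigned to the compartment the corresponding helix end
faces.  Inter-helix turns are halved, each half joining the adjacent
helix's flanking region; the termini join the first/last helix's outward
region.  The result is a total partition of the chain into labels of the
form ``TM{h}_{EC|TM|IC}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "Helix",
    "HelixTable",
    "RegionMap",
    "RegionError",
    "build_region_map",
    "assign_region",
    "load_helix_table",
    "default_cxcr4_table",
]

_SIDES = ("EC", "IC")


class RegionError(ValueError):
    """Raised for invalid helix tables or out-of-range residue queries."""


@dataclass(frozen=True)
class Helix:
    helix_id: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise RegionError(f"helix {self.helix_id}: end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HelixTable:
    """Ordered helix boundaries plus membrane topology of the chain.

    ``n_term_side`` is the compartment (``"EC"`` or ``"IC"``) faced by the
    chain's N-terminus; helix orientations alternate from there.
    """

    helices: tuple[Helix, ...]
    n_term_side: str
    chain_range: tuple[int, int]
    name: str = "receptor"

    def __post_init__(self) -> None:
        if self.n_term_side not in _SIDES:
            raise RegionError(f"n_term_side must be one of {_SIDES}, got {self.n_term_side!r}")
        if not self.helices:
            raise RegionError("helix table is empty")
        lo, hi = self.chain_range
        if lo > hi:
            raise RegionError(f"invalid chain_range {self.chain_range}")
        prev_end = lo - 1
        for h in self.helices:
            if h.start <= prev_end:
                raise RegionError(
                    f"helix {h.helix_id} ({h.start}..{h.end}) overlaps or is out of order"
                )
            prev_end = h.end
        if self.helices[0].start < lo or self.helices[-1].end > hi:
            raise RegionError("helices fall outside chain_range")

    def n_side(self, helix_id: int) -> str:
        """Compartment faced by the N-terminal end of helix ``helix_id``."""
        flip = (helix_id - self.helices[0].helix_id) % 2
        base = _SIDES.index(self.n_term_side)
        return _SIDES[(base + flip) % 2]

    def c_side(self, helix_id: int) -> str:
        return _SIDES[1 - _SIDES.index(self.n_side(helix_id))]


@dataclass
class RegionMap:
    """Total partition residue number -> ``TM{h}_{EC|TM|IC}`` label."""

    assignment: dict[int, str]
    flank: int
    chain_range: tuple[int, int]
    table: HelixTable | None = field(default=None, repr=False)

    def __getitem__(self, residue: int) -> str:
        return assign_region(residue, self)

    def __len__(self) -> int:
        return len(self.assignment)

    def region_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.assignment.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def residues(self, label: str) -> list[int]:
        return sorted(r for r, lab in self.assignment.items() if lab == label)

    def to_frame(self) -> pd.DataFrame:
        resids = sorted(self.assignment)
        return pd.DataFrame(
            {"residue": resids, "region": [self.assignment[r] for r in resids]}
        )


def build_region_map(table: HelixTable, flank: int = 8) -> RegionMap:
    """Partition the chain into per-helix EC/TM/IC regions.

    For helix ``h`` spanning ``[s, e]`` the TM stretch runs from the
    ``flank``-th residue counting ``s`` as the first to the ``flank``-th
    residue counting ``e`` as the last, i.e. ``[s+flank-1, e-flank+1]``.
    The flanking residues join the compartment that helix end faces.  Each
    inter-helix turn is split at its midpoint (the extra residue of an
    odd-length turn staying with the N-side half), the halves joining the
    adjacent flanking regions.  Residues before the first helix join its
    N-side region; residues after the last helix join its C-side region.
    """
    if flank < 1:
        raise RegionError(f"flank must be >= 1, got {flank}")
    for h in table.helices:
        if h.length <= 2 * flank:
            raise RegionError(
                f"helix {h.helix_id} ({h.start}..{h.end}, length {h.length}) "
                f"is too short for flank {flank}"
            )

    lo, hi = table.chain_range
    assignment: dict[int, str] = {}

    def put(a: int, b: int, label: str) -> None:
        for r in range(a, b + 1):
            assignment[r] = label

    first, last = table.helices[0], table.helices[-1]
    put(lo, first.start - 1, f"TM{first.helix_id}_{table.n_side(first.helix_id)}")
    put(last.end + 1, hi, f"TM{last.helix_id}_{table.c_side(last.helix_id)}")

    for h in table.helices:
        put(h.start, h.start + flank - 2, f"TM{h.helix_id}_{table.n_side(h.helix_id)}")
        put(h.start + flank - 1, h.end - flank + 1, f"TM{h.helix_id}_TM")
        put(h.end - flank + 2, h.end, f"TM{h.helix_id}_{table.c_side(h.helix_id)}")

    for prev, nxt in zip(table.helices, table.helices[1:]):
        a, b = prev.end + 1, nxt.start - 1
        if a > b:
            continue
        n_half = (b - a + 2) // 2  # odd turn: extra residue stays N-side
        put(a, a + n_half - 1, f"TM{prev.helix_id}_{table.c_side(prev.helix_id)}")
        put(a + n_half, b, f"TM{nxt.helix_id}_{table.n_side(nxt.helix_id)}")

    assert set(assignment) == set(range(lo, hi + 1))
    return RegionMap(assignment=assignment, flank=flank, chain_range=table.chain_range, table=table)


def assign_region(residue: int, region_map: RegionMap) -> str:
    """Label of ``residue``; raises :class:`RegionError` outside the chain."""
    try:
        return region_map.assignment[residue]
    except KeyError:
        raise RegionError(
            f"residue {residue} outside chain range {region_map.chain_range}"
        ) from None


def _table_from_dict(payload: Mapping) -> HelixTable:
    helices = tuple(
        Helix(int(h["helix_id"]), int(h["start"]), int(h["end"]))
        for h in payload["helices"]
    )
    return HelixTable(
        helices=helices,
        n_term_side=str(payload["n_term_side"]),
        chain_range=(int(payload["chain_range"][0]), int(payload["chain_range"][1])),
        name=str(payload.get("name", "receptor")),
    )


def load_helix_table(path_or_rows) -> HelixTable:
    """Load a helix table from a JSON file path or an already-parsed mapping."""
    if isinstance(path_or_rows, Mapping):
        return _table_from_dict(path_or_rows)
    with open(path_or_rows) as fh:
        return _table_from_dict(json.load(fh))


def default_cxcr4_table() -> HelixTable:
    """The CXCR4 helix-boundary table shipped with the package (281 residues)."""
    payload = json.loads(
        resources.files("dioscope.data").joinpath("cxcr4_helices.json").read_text()
    )
    return _table_from_dict(payload)
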