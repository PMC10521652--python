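"""Blueprint data model and register-shift arithmetic for TIM barrels.

A closed beta barrel is summarized by two integers: the strand count ``n``
and the shear number ``S`` — the total residue offset accumulated when the
hydrogen-bond ladder is traversed once around the barrel.  A blueprint
decomposes ``S`` into per-junction register shifts ``r_j`` (one per adjacent
strand pair, cyclic), so that ``S = sum(r_j)``.  The twofold ovoid blueprint
used throughout this package has strands of length 5, 5, 7, 7 per repeat
with shifts of 2 at the junctions following strands 3 and 4, giving a
per-repeat shift of 4 and an overall shear of 8 with n = 8.

Ladder coordinates
------------------
Residue ``j`` (1-based within its strand) of strand ``i`` is assigned the
ladder coordinate ``m = j - c_i`` where ``c_i`` is the cumulative register
shift before strand ``i``.  Hydrogen-bonded partner residues on adjacent
strands share ``m``; crossing junction ``i -> i+1`` the within-strand index
therefore advances by ``r_i``.  Core-facing parity is a function of ``m``
alone (even ``m`` faces the barrel interior, anchoring strand 1 residue 2 —
a core-layer position of the ovoid design — on the inside), which propagates
consistently across junctions and around barrel closure whenever ``S`` is
even.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SecondaryStructureElement",
    "Blueprint",
    "Layer",
    "CBetaStrip",
    "make_ovoid_blueprint",
    "make_circular_blueprint",
    "compute_shear",
    "repeat_shift",
    "repeat_partner",
    "enumerate_layers",
    "enumerate_cbeta_strips",
]

_KINDS = ("strand", "helix", "loop")


@dataclass(frozen=True)
class SecondaryStructureElement:
    """One secondary-structure element of a blueprint."""

    kind: str
    length: int
    index_within_kind: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("element length must be >= 1")


@dataclass(frozen=True)
class Blueprint:
    """Ordered secondary-structure elements plus cyclic register shifts.

    ``register_shifts[i]`` is the residue offset at the junction between
    strand ``i+1`` and its successor (cyclic; the last entry closes the
    barrel back onto strand 1).
    """

    elements: tuple[SecondaryStructureElement, ...]
    register_shifts: tuple[int, ...]
    repeat_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "register_shifts", tuple(self.register_shifts))
        if self.n_strands >= 2 and len(self.register_shifts) != self.n_strands:
            raise ValueError(
                f"need one register shift per strand junction "
                f"({self.n_strands}), got {len(self.register_shifts)}"
            )
        if self.repeat_count < 1:
            raise ValueError("repeat_count must be >= 1")
        if self.total_residues % self.repeat_count:
            raise ValueError("total residue count not divisible by repeat_count")

    # -- derived sizes -------------------------------------------------
    @property
    def n_strands(self) -> int:
        return sum(1 for e in self.elements if e.kind == "strand")

    @property
    def total_residues(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def residues_per_repeat(self) -> int:
        return self.total_residues // self.repeat_count

    @property
    def strand_lengths(self) -> tuple[int, ...]:
        return tuple(e.length for e in self.elements if e.kind == "strand")

    # -- residue bookkeeping -------------------------------------------
    def element_ranges(self) -> list[tuple[SecondaryStructureElement, int, int]]:
        """(element, first, last) 1-based inclusive global residue ranges."""
        out, pos = [], 1
        for e in self.elements:
            out.append((e, pos, pos + e.length - 1))
            pos += e.length
        return out

    def strand_ranges(self) -> list[tuple[int, int]]:
        """1-based inclusive global residue range of each strand, in order."""
        return [(a, b) for e, a, b in self.element_ranges() if e.kind == "strand"]

    def cumulative_shifts(self) -> list[int]:
        """c_i for each strand: total register shift accumulated before it."""
        c, acc = [], 0
        for r in self.register_shifts[: self.n_strands]:
            c.append(acc)
            acc += r
        return c

    def ladder_coordinate(self, strand: int, local_index: int) -> int:
        """Ladder coordinate m = j - c_i (strand 0-based, local 1-based)."""
        return local_index - self.cumulative_shifts()[strand]

    def is_core_facing(self, strand: int, local_index: int) -> bool:
        """Interior-facing parity: even ladder coordinate faces the core."""
        return self.ladder_coordinate(strand, local_index) % 2 == 0

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "elements": [
                {"kind": e.kind, "length": e.length, "index_within_kind": e.index_within_kind}
                for e in self.elements
            ],
            "register_shifts": list(self.register_shifts),
            "repeat_count": self.repeat_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Blueprint":
        elements = tuple(
            SecondaryStructureElement(
                kind=e["kind"],
                length=int(e["length"]),
                index_within_kind=int(e.get("index_within_kind", 0)),
            )
            for e in d["elements"]
        )
        return cls(
            elements=elements,
            register_shifts=tuple(int(r) for r in d["register_shifts"]),
            repeat_count=int(d.get("repeat_count", 1)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Blueprint":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Layer:
    """Core-facing positions sharing one height along the barrel axis.

    Positions are (strand index 0-based, local residue index 1-based).
    """

    height_index: int
    positions: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class CBetaStrip:
    """Interior-facing positions winding around the barrel at constant
    ladder coordinate; consecutive members differ in residue index by the
    junction's register shift."""

    ladder_coordinate: int
    positions: tuple[tuple[int, int], ...]


def _repeat_elements(
    strand_lengths: Sequence[int],
    ba_loops: Sequence[int],
    helices: Sequence[int],
    ab_turns: Sequence[int],
) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for s, l1, h, l2 in zip(strand_lengths, ba_loops, helices, ab_turns):
        out += [("strand", s), ("loop", l1), ("helix", h), ("loop", l2)]
    return out


def _build(elements: Iterable[tuple[str, int]], shifts: Sequence[int], repeats: int) -> Blueprint:
    counts = {"strand": 0, "helix": 0, "loop": 0}
    elems = []
    for kind, length in elements:
        counts[kind] += 1
        elems.append(SecondaryStructureElement(kind, length, counts[kind]))
    return Blueprint(tuple(elems), tuple(shifts), repeat_count=repeats)


def make_ovoid_blueprint(
    helix_lengths: Sequence[int] = (14, 14, 14, 14),
    ba_loop_lengths: Sequence[int] = (8, 4, 7, 3),
) -> Blueprint:
    """The twofold ovoid TIM-barrel blueprint.

    Per repeat: strands of length 5, 5, 7, 7 with register shifts of 2 at
    the junctions following strands 3 and 4; alpha-beta turns fixed at
    three residues.  Helix and beta-alpha loop lengths are configurable
    but must close the 114-residue repeat budget (228 residues total,
    shear 8, per-repeat shift 4).  The default loop lengths place the
    strands at residues 1-5, 31-35, 57-63 and 88-94 of each repeat, so
    that the design's referenced core positions (residues 2, 60, 93 and
    their repeat partners 116, 174, 207) fall on interior-facing strand
    positions.
    """
    strands = (5, 5, 7, 7)
    ab_turns = (3, 3, 3, 3)
    per_repeat = sum(strands) + sum(ab_turns) + sum(helix_lengths) + sum(ba_loop_lengths)
    if per_repeat != 114:
        raise ValueError(f"helix/loop lengths give {per_repeat} residues per repeat, need 114")
    rep = _repeat_elements(strands, ba_loop_lengths, helix_lengths, ab_turns)
    return _build(rep * 2, (0, 0, 2, 2) * 2, repeats=2)


def make_circular_blueprint() -> Blueprint:
    """Fourfold circular TIM-barrel blueprint: eight equal strands of
    length five, uniform register shift of one (shear 8)."""
    rep = _repeat_elements((5, 5), (4, 4), (10, 10), (4, 4))
    return _build(rep * 4, (1, 1) * 4, repeats=4)


def compute_shear(bp: Blueprint) -> int:
    """Cyclic sum of register shifts around the barrel (the shear number)."""
    if bp.n_strands < 2:
        raise ValueError("shear undefined for fewer than 2 strands")
    if len(bp.register_shifts) != bp.n_strands:
        raise ValueError("register shift missing for some junction")
    return sum(bp.register_shifts)


def _repeat_junctions(bp: Blueprint) -> int:
    if bp.repeat_count < 2:
        raise ValueError("blueprint is not repetitive")
    if bp.n_strands % bp.repeat_count:
        raise ValueError("strands not evenly divided among repeats")
    return bp.n_strands // bp.repeat_count


def repeat_shift(bp: Blueprint) -> int:
    """Register shift accumulated within one repeat (shear per repeat)."""
    k = _repeat_junctions(bp)
    per_repeat = [bp.register_shifts[i * k : (i + 1) * k] for i in range(bp.repeat_count)]
    if len(set(per_repeat)) != 1:
        raise ValueError("register shifts differ between repeats")
    n_elem = len(bp.elements) // bp.repeat_count
    reps = [bp.elements[i * n_elem : (i + 1) * n_elem] for i in range(bp.repeat_count)]
    if any(
        tuple((e.kind, e.length) for e in r) != tuple((e.kind, e.length) for e in reps[0])
        for r in reps
    ):
        raise ValueError("elements differ between repeats")
    return sum(per_repeat[0])


def repeat_partner(residue_index: int, bp: Blueprint) -> int:
    """Symmetry-equivalent residue in the other repeat of a twofold barrel.

    1-based; e.g. with a 114-residue repeat, 2 <-> 116 and 60 <-> 174.
    """
    if bp.repeat_count != 2:
        raise ValueError("repeat partners are defined for twofold blueprints")
    total = bp.total_residues
    if not 1 <= residue_index <= total:
        raise IndexError(f"residue {residue_index} outside 1..{total}")
    rpp = bp.residues_per_repeat
    return residue_index + rpp if residue_index <= rpp else residue_index - rpp


def _core_positions(bp: Blueprint) -> list[tuple[int, int]]:
    out = []
    for i, (a, b) in enumerate(bp.strand_ranges()):
        for j in range(1, b - a + 2):
            if bp.is_core_facing(i, j):
                out.append((i, j))
    return out


def enumerate_layers(bp: Blueprint) -> list[Layer]:
    """Group core-facing strand positions into horizontal layers.

    Height along the barrel axis of position (strand i, ladder m) is
    proportional to ``m + i * S / n`` (the inter-strand step climbs by
    S/n residues of rise).  Positions whose heights agree to within half
    a residue rise form one layer; with S = n the height index is the
    integer ``m + i`` and layers collect core-facing positions from
    alternating strands.
    """
    n = bp.n_strands
    if n == 1:
        return [
            Layer(height_index=j, positions=((0, j),))
            for (_, j) in _core_positions(bp)
        ]
    s_over_n = compute_shear(bp) / n
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, j in _core_positions(bp):
        h = bp.ladder_coordinate(i, j) + i * s_over_n
        key = round(h)
        if abs(h - key) > 0.5 - 1e-9:
            key = int(h)  # boundary case: bin by floor
        groups.setdefault(key, []).append((i, j))
    return [Layer(height_index=k, positions=tuple(sorted(v))) for k, v in sorted(groups.items())]


def enumerate_cbeta_strips(bp: Blueprint) -> list[CBetaStrip]:
    """Interior-facing strips at constant ladder coordinate.

    Each strip lists, strand by strand around the barrel, the residue
    whose ladder coordinate equals the strip's; crossing the junction
    after strand ``i`` the residue index advances by the register shift
    ``r_i``, so strips run perpendicular to the strand direction.
    """
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, j in _core_positions(bp):
        groups.setdefault(bp.ladder_coordinate(i, j), []).append((i, j))
    return [
        CBetaStrip(ladder_coordinate=m, positions=tuple(sorted(v)))
        for m, v in sorted(groups.items())
    ]
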