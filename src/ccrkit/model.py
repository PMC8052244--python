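"""Domain model for complex chromosomal rearrangement (CCR) analysis.

A CCR is described by a set of *fragments* — oriented reference intervals,
each used once in a derivative chromosome — joined by *breakpoint junctions*
(BPJs).  Every junction fuses two *breakends*; a breakend is a chromosome,
a 1-based position, and a side saying in which direction the retained
sequence extends.

Coordinate conventions
----------------------
All internal coordinates are 1-based inclusive (VCF style).  BED/bedpe input
is converted at the parse boundary.  A fragment ``[start, end]`` has two
native ends: its *head* at ``start`` (retained sequence extends toward
higher coordinates) and its *tail* at ``end`` (retained sequence extends
toward lower coordinates).  A reference-collinear fusion is therefore
tail-to-head.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence


class CcrError(Exception):
    """Base class for all ccrkit errors."""


class ValidationError(CcrError):
    """An object violates a model invariant."""


class Side(str, Enum):
    """Direction in which retained sequence extends from a breakend."""

    HEAD = "head"  # retained sequence extends toward higher coordinates
    TAIL = "tail"  # retained sequence extends toward lower coordinates

    @property
    def opposite(self) -> "Side":
        return Side.TAIL if self is Side.HEAD else Side.HEAD


class Orientation(str, Enum):
    FORWARD = "+"
    REVERSE = "-"

    @property
    def flipped(self) -> "Orientation":
        return Orientation.REVERSE if self is Orientation.FORWARD else Orientation.FORWARD


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a junction: chromosome, 1-based position, and side."""

    chrom: str
    pos: int
    side: Side

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"breakend position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class Junction:
    """A breakpoint junction fusing two breakends.

    ``inserted_seq`` and ``microhomology_len`` are mutually exclusive:
    an inserted sequence separates the joined segments, so the breakpoint
    placement cannot also be ambiguous.  ``deleted_nt`` is the number of
    reference nucleotides lost at this junction.
    """

    id: str
    end_a: Breakend
    end_b: Breakend
    inserted_seq: str = ""
    microhomology_len: int = 0
    deleted_nt: int = 0
    supports: frozenset[str] = field(default_factory=frozenset)
    templated: bool = False

    def __post_init__(self) -> None:
        if self.microhomology_len < 0:
            raise ValidationError(f"junction {self.id}: negative microhomology")
        if self.deleted_nt < 0:
            raise ValidationError(f"junction {self.id}: negative deletion")
        if self.inserted_seq and self.microhomology_len:
            raise ValidationError(
                f"junction {self.id}: insertion and microhomology are mutually exclusive"
            )

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.end_a, self.end_b)

    def swapped(self) -> "Junction":
        """The same junction read in the opposite direction (breakends
        exchanged).  Signature fields are direction-symmetric."""
        return replace(self, end_a=self.end_b, end_b=self.end_a)


@dataclass(frozen=True)
class Fragment:
    """An oriented reference interval used once in a derivative chromosome.

    ``junction_head``/``junction_tail`` optionally name the junctions
    attached to the native head (at ``start``) and tail (at ``end``) ends —
    the explicit linkage carried by the fragment-table format.  When absent,
    linkage is recovered by coordinate matching.
    """

    id: str
    chrom: str
    start: int
    end: int
    origin_chrom: str = ""
    junction_head: Optional[str] = None
    junction_tail: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"fragment {self.id}: invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if not self.origin_chrom:
            object.__setattr__(self, "origin_chrom", self.chrom)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def breakend(self, side: Side) -> Breakend:
        """The native end of this fragment on the given side."""
        if side is Side.HEAD:
            return Breakend(self.chrom, self.start, Side.HEAD)
        return Breakend(self.chrom, self.end, Side.TAIL)

    def junction_at(self, side: Side) -> Optional[str]:
        return self.junction_head if side is Side.HEAD else self.junction_tail


@dataclass(frozen=True)
class PlacedFragment:
    """A fragment placed at a position in a derivative chain."""

    fragment: Fragment
    orientation: Orientation
    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError("placed fragment index must be >= 0")

    @property
    def leading_side(self) -> Side:
        """Native side at the derivative-upstream end of this placement."""
        return Side.HEAD if self.orientation is Orientation.FORWARD else Side.TAIL

    @property
    def trailing_side(self) -> Side:
        """Native side at the derivative-downstream end of this placement."""
        return self.leading_side.opposite


@dataclass
class DerivativeChromosome:
    """An ordered, oriented chain of fragments joined by junctions."""

    name: str
    chain: list[PlacedFragment]
    junctions: list[Junction]

    def __post_init__(self) -> None:
        if len(self.junctions) != max(len(self.chain) - 1, 0):
            raise ValidationError(
                f"derivative {self.name}: {len(self.chain)} fragments require "
                f"{max(len(self.chain) - 1, 0)} junctions, got {len(self.junctions)}"
            )
        ids = [p.fragment.id for p in self.chain]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"derivative {self.name}: duplicate fragment in chain")

    @property
    def fragment_ids(self) -> list[str]:
        return [p.fragment.id for p in self.chain]

    def reversed(self) -> "DerivativeChromosome":
        """The same chain walked from the other terminal end: fragment order
        and orientations flip, and each junction is re-expressed with its
        breakends in the new walking direction."""
        n = len(self.chain)
        chain = [
            replace(p, orientation=p.orientation.flipped, index=n - 1 - p.index)
            for p in reversed(self.chain)
        ]
        junctions = [j.swapped() for j in reversed(self.junctions)]
        return DerivativeChromosome(self.name, chain, junctions)


@dataclass(frozen=True)
class CallRecord:
    """A technology-labelled SV call: two breakends and a type."""

    technology: str
    end_a: Breakend
    end_b: Breakend
    svtype: str = "BND"


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class Tad:
    id: str
    chrom: str
    start: int
    end: int


@dataclass
class GenomeModel:
    """Chromosome lengths plus gene/TAD annotation and optional sequence."""

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)
    tads: list[Tad] = field(default_factory=list)
    sequences: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for _, length in self.chromosomes:
            if length < 1:
                raise ValidationError("chromosome length must be positive")
        lengths = self.lengths
        for g in self.genes:
            self._check_interval("gene", g.name, g.chrom, g.start, g.end, lengths)
        for t in self.tads:
            self._check_interval("TAD", t.id, t.chrom, t.start, t.end, lengths)
        if self.sequences is not None:
            for chrom, seq in self.sequences.items():
                if chrom in lengths and len(seq) != lengths[chrom]:
                    raise ValidationError(
                        f"sequence length for {chrom} ({len(seq)}) does not match "
                        f"declared length ({lengths[chrom]})"
                    )

    @staticmethod
    def _check_interval(
        kind: str, name: str, chrom: str, start: int, end: int, lengths: dict[str, int]
    ) -> None:
        if chrom not in lengths:
            raise ValidationError(f"{kind} {name}: unknown chromosome {chrom}")
        if not (1 <= start <= end <= lengths[chrom]):
            raise ValidationError(f"{kind} {name}: interval outside chromosome bounds")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def sequence(self, chrom: str) -> str:
        if self.sequences is None or chrom not in self.sequences:
            raise ValidationError(f"no sequence available for {chrom}")
        return self.sequences[chrom]


def validate_fragments(
    fragments: Sequence[Fragment], allow_overlap: bool = False
) -> None:
    """Check fragment-set invariants: unique ids and, unless duplications are
    expected (fold-back/replicative simulations), non-overlapping intervals
    per chromosome."""
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate fragment ids: {', '.join(dup)}")
    if allow_overlap:
        return
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, frags in by_chrom.items():
        frags = sorted(frags, key=lambda f: (f.start, f.end))
        for prev, cur in zip(frags, frags[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"overlapping fragments on {chrom}: "
                    f"{prev.id} ({prev.start}-{prev.end}) and {cur.id} ({cur.start}-{cur.end})"
                )


def check_referential_integrity(
    fragments: Iterable[Fragment], junctions: Iterable[Junction]
) -> None:
    """Every junction id referenced by a fragment must exist."""
    known = {j.id for j in junctions}
    for f in fragments:
        for jid in (f.junction_head, f.junction_tail):
            if jid is not None and jid not in known:
                raise ValidationError(
                    f"fragment {f.id} references unknown junction {jid}"
                )
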