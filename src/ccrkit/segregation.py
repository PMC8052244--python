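"""Meiotic segregation for carriers of balanced complex rearrangements.

Under alternate/adjacent-I segregation each involved homolog pair
contributes exactly one chromosome to a gamete — either the normal homolog
or the derivative.  For a carrier of independent balanced rearrangements,
a gamete is chromosomally balanced only when, within every rearrangement,
the choices are homogeneous: all normal or all derivative (mixing normal
and derivative chromosomes of one rearrangement leaves some fragments
missing and others duplicated).

With g independent rearrangements involving c chromosomes in total there
are 2^c gametes, of which 2^g are balanced.  A carrier of one reciprocal
translocation (c = 2, g = 1) therefore produces 2/4 = 50% balanced
gametes, while a carrier of a four-chromosome and a two-chromosome
rearrangement produces 4/64 = 6.25%.

3:1 segregation and recombination within the quadrivalent are outside this
model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .model import CcrError, ValidationError


@dataclass(frozen=True)
class RearrangementGroup:
    """The chromosomes participating in one balanced rearrangement."""

    chromosomes: tuple[str, ...]
    name: str = ""

    def __init__(self, chromosomes: Sequence[str], name: str = ""):
        chroms = tuple(chromosomes)
        if len(chroms) < 2:
            raise ValidationError("a rearrangement involves at least 2 chromosomes")
        if len(set(chroms)) != len(chroms):
            raise ValidationError("duplicate chromosome within a rearrangement group")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "name", name or "t(" + ";".join(chroms) + ")")


@dataclass(frozen=True)
class Gamete:
    """One segregation outcome: per chromosome, normal or derivative."""

    choices: tuple[tuple[str, str], ...]  # (chromosome, "normal" | "derivative")
    balanced: bool

    def choice(self, chrom: str) -> str:
        return dict(self.choices)[chrom]


def enumerate_gametes(groups: Sequence[RearrangementGroup]) -> list[Gamete]:
    """All 2^c alternate/adjacent-I gametes for c involved chromosomes.

    A gamete is balanced iff within every group the choices are all-normal
    or all-derivative.  Groups must be disjoint.  With no groups the single
    (balanced) trivial gamete is returned.
    """
    seen: set[str] = set()
    for group in groups:
        overlap = seen & set(group.chromosomes)
        if overlap:
            raise CcrError(f"rearrangement groups overlap on {sorted(overlap)}")
        seen.update(group.chromosomes)
    chroms = [c for g in groups for c in g.chromosomes]
    gametes = []
    for combo in itertools.product(("normal", "derivative"), repeat=len(chroms)):
        by_chrom = dict(zip(chroms, combo))
        balanced = all(
            len({by_chrom[c] for c in g.chromosomes}) == 1 for g in groups
        )
        gametes.append(Gamete(tuple(zip(chroms, combo)), balanced))
    return gametes


@dataclass(frozen=True)
class BalancedFraction:
    n_balanced: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_balanced / self.n_total

    @property
    def percentage(self) -> float:
        return 100.0 * self.fraction


def balanced_fraction(gametes: Sequence[Gamete]) -> BalancedFraction:
    """Fraction (and percentage) of balanced gametes; closed form
    2^groups / 2^chromosomes."""
    if not gametes:
        raise ValueError("gamete list is empty")
    return BalancedFraction(sum(g.balanced for g in gametes), len(gametes))
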