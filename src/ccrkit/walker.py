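"""Derivative-chromosome reconstruction by walking fragment/junction chains.

Except for terminal (telomere-bearing) fragments, each fragment of a complex
rearrangement is associated with two junctions, one at its head and one at
its tail, so fragments form chains fused through junctions.  The walker
starts at a terminal fragment's free end, enters each fragment through one
native end (entering at the head places the fragment forward, at the tail
reverse), exits through the other, and follows the junction attached there
until it reaches the terminal fragment at the far end of the chain.  The
path travelled is the derivative chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    CcrError,
    DerivativeChromosome,
    Fragment,
    Junction,
    Orientation,
    PlacedFragment,
    Side,
)

FragmentEnd = tuple[str, Side]  # (fragment id, native side)


class LinkageError(CcrError):
    """A junction breakend could not be attached to any fragment end."""


class AmbiguityError(CcrError):
    """A fragment end is claimed by more than one junction."""


class CycleError(CcrError):
    """The fragment chain closes on itself; germline derivatives are linear."""


@dataclass
class FragmentGraph:
    """Fragment ends linked by junction edges.

    Nodes are (fragment id, side) pairs; each node carries at most one
    junction edge (the implicit intra-fragment head<->tail edge is walked
    directly).  Ends without a junction edge are *free*: they belong to
    terminal fragments.
    """

    fragments: dict[str, Fragment]
    edges: dict[FragmentEnd, tuple[Junction, FragmentEnd]] = field(default_factory=dict)

    def free_ends(self) -> list[FragmentEnd]:
        return [
            (fid, side)
            for fid in self.fragments
            for side in (Side.HEAD, Side.TAIL)
            if (fid, side) not in self.edges
        ]

    @property
    def n_junction_edges(self) -> int:
        return len(self.edges) // 2


def _resolve_by_id(
    junction: Junction, fragments: Sequence[Fragment]
) -> Optional[tuple[FragmentEnd, FragmentEnd]]:
    """Resolve a junction to fragment ends through explicit linkage fields."""
    claims = [
        (f.id, side)
        for f in fragments
        for side in (Side.HEAD, Side.TAIL)
        if f.junction_at(side) == junction.id
    ]
    if not claims:
        return None
    if len(claims) != 2:
        raise AmbiguityError(
            f"junction {junction.id} is referenced by {len(claims)} fragment ends: {claims}"
        )
    return claims[0], claims[1]


def _resolve_by_coordinates(
    junction: Junction, fragments: Sequence[Fragment], tolerance: int
) -> tuple[FragmentEnd, FragmentEnd]:
    ends: list[FragmentEnd] = []
    taken: set[FragmentEnd] = set()
    for be in junction.breakends:
        candidates = []
        for f in fragments:
            fe = f.breakend(be.side)
            if fe.chrom == be.chrom and abs(fe.pos - be.pos) <= tolerance:
                if (f.id, be.side) not in taken:
                    candidates.append((abs(fe.pos - be.pos), f.id))
        if not candidates:
            raise LinkageError(
                f"junction {junction.id}: breakend {be.chrom}:{be.pos} ({be.side.value}) "
                f"matches no fragment end within {tolerance} bp"
            )
        candidates.sort()
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            raise AmbiguityError(
                f"junction {junction.id}: breakend {be.chrom}:{be.pos} matches "
                f"multiple fragment ends at equal distance"
            )
        chosen = (candidates[0][1], be.side)
        taken.add(chosen)
        ends.append(chosen)
    return ends[0], ends[1]


def build_fragment_graph(
    fragments: Sequence[Fragment],
    junctions: Sequence[Junction],
    tolerance: int = 0,
) -> FragmentGraph:
    """Attach each junction to two fragment ends.

    Explicit ``junction_head``/``junction_tail`` references take precedence
    (they disambiguate fold-back junctions whose two breakends share
    coordinates); otherwise breakends are matched to fragment ends by
    chromosome, side and position within ``tolerance`` bp (default exact,
    matching curated fragment tables; raise it for raw caller output).
    """
    graph = FragmentGraph(fragments={f.id: f for f in fragments})
    for junction in junctions:
        resolved = _resolve_by_id(junction, fragments)
        if resolved is None:
            resolved = _resolve_by_coordinates(junction, fragments, tolerance)
        end_a, end_b = resolved
        for end in (end_a, end_b):
            if end in graph.edges:
                raise AmbiguityError(
                    f"fragment end {end[0]}:{end[1].value} is claimed by junctions "
                    f"{graph.edges[end][0].id} and {junction.id}"
                )
        graph.edges[end_a] = (junction, end_b)
        graph.edges[end_b] = (junction, end_a)
    return graph


def walk_derivative(
    graph: FragmentGraph,
    start_fragment: str,
    start_end: Side,
    name: Optional[str] = None,
) -> DerivativeChromosome:
    """Walk the chain starting at a terminal fragment's free end.

    Entering a fragment at its head places it forward, at its tail reverse.
    Raises :class:`CycleError` if the chain revisits a fragment.
    """
    if start_fragment not in graph.fragments:
        raise LinkageError(f"unknown start fragment {start_fragment}")
    if (start_fragment, start_end) in graph.edges:
        raise CcrError(
            f"fragment {start_fragment} is not terminal at its {start_end.value} end"
        )
    chain: list[PlacedFragment] = []
    junctions: list[Junction] = []
    seen: set[str] = set()
    fid, enter_side = start_fragment, start_end
    while True:
        if fid in seen:
            raise CycleError(f"cycle detected at fragment {fid}")
        seen.add(fid)
        orientation = (
            Orientation.FORWARD if enter_side is Side.HEAD else Orientation.REVERSE
        )
        chain.append(
            PlacedFragment(graph.fragments[fid], orientation, index=len(chain))
        )
        exit_end = (fid, enter_side.opposite)
        if exit_end not in graph.edges:
            break
        junction, (next_fid, next_side) = graph.edges[exit_end]
        junctions.append(junction)
        fid, enter_side = next_fid, next_side
    if name is None:
        name = f"der({chain[0].fragment.chrom})"
    return DerivativeChromosome(name=name, chain=chain, junctions=junctions)


def _terminal_key(der: DerivativeChromosome, at_start: bool):
    """Sort key of the free fragment end at one extremity of a chain —
    identical to the walker's start-selection key."""
    if at_start:
        placed = der.chain[0]
        side = placed.leading_side
    else:
        placed = der.chain[-1]
        side = placed.trailing_side
    frag = placed.fragment
    return (frag.chrom, frag.start, frag.id, side.value)


def canonicalize_derivatives(
    derivatives: Sequence[DerivativeChromosome],
) -> list[DerivativeChromosome]:
    """Re-express chains in the orientation and order :func:`reconstruct_all`
    produces: each chain is walked from its lexicographically smaller free
    end, chains are sorted by that end, and names are reassigned from the
    first fragment's chromosome (deduplicated in order).  Used by the
    simulators so truth chains compare exactly against reconstruction."""
    canon = []
    for der in derivatives:
        if len(der.chain) > 1 and _terminal_key(der, False) < _terminal_key(der, True):
            der = der.reversed()
        canon.append(der)
    canon.sort(key=lambda d: _terminal_key(d, True))
    names: dict[str, int] = {}
    for der in canon:
        base = f"der({der.chain[0].fragment.chrom})"
        names[base] = names.get(base, 0) + 1
        der.name = base if names[base] == 1 else f"{base}.{names[base]}"
    return canon


def reconstruct_all(
    fragments: Sequence[Fragment],
    junctions: Sequence[Junction],
    tolerance: int = 0,
) -> list[DerivativeChromosome]:
    """Reconstruct every derivative chromosome.

    Chains are walked starting from the free end whose (chromosome, position)
    is lexicographically smallest among the remaining terminal fragments, so
    output order is reproducible.  Fragments left over after all free ends
    are exhausted (i.e. cycles) raise :class:`CycleError`.
    """
    graph = build_fragment_graph(fragments, junctions, tolerance=tolerance)

    def sort_key(end: FragmentEnd):
        frag = graph.fragments[end[0]]
        return (frag.chrom, frag.start, frag.id, end[1].value)

    remaining = set(graph.free_ends())
    used: set[str] = set()
    derivatives: list[DerivativeChromosome] = []
    names: dict[str, int] = {}
    while remaining:
        start = min(remaining, key=sort_key)
        der = walk_derivative(graph, start[0], start[1])
        base = der.name
        names[base] = names.get(base, 0) + 1
        if names[base] > 1:
            der.name = f"{base}.{names[base]}"
        derivatives.append(der)
        for placed in der.chain:
            used.add(placed.fragment.id)
        remaining = {end for end in remaining if end[0] not in used}
    leftover = sorted(set(graph.fragments) - used)
    if leftover:
        raise CycleError(
            f"fragments not reachable from any free end (cyclic chain?): {', '.join(leftover)}"
        )
    return derivatives
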