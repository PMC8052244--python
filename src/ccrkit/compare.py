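"""Benchmarking technology call sets against a confirmed-junction truth set.

A call represents a truth junction when both of its breakend positions lie
within ``max_dist`` (default 100 kbp) of the junction's confirmed
positions, on the matching chromosome pair.  A call close to several truth
junctions represents only the closest one — closest meaning the minimal
sum of the two breakend distances, with ties broken by junction id for
determinism.  Both pairings of call ends to junction ends are tried and
the better one used.  Calls are not consumed: several calls may detect the
same junction, since the benchmark counts detected truth junctions rather
than one-to-one pairings.  Breakend side/orientation is ignored during
matching (distance only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import CallRecord, CcrError, Junction

DEFAULT_MAX_DIST = 100_000


@dataclass(frozen=True)
class CallAssignment:
    call_index: int
    junction_id: Optional[str]
    distance: Optional[int]  # sum of both breakend distances


@dataclass
class MatchResult:
    technology: str
    assignments: list[CallAssignment]
    detected: set[str]
    truth_ids: frozenset[str]

    @property
    def n_calls(self) -> int:
        return len(self.assignments)

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    def detection_rate(self) -> float:
        return self.n_detected / len(self.truth_ids) if self.truth_ids else 0.0


def _pair_distance(call: CallRecord, junction: Junction, max_dist: int) -> Optional[int]:
    """Best valid summed distance over the two end-to-end pairings."""
    best: Optional[int] = None
    pairings = (
        ((call.end_a, junction.end_a), (call.end_b, junction.end_b)),
        ((call.end_a, junction.end_b), (call.end_b, junction.end_a)),
    )
    for pairing in pairings:
        total = 0
        ok = True
        for call_end, junc_end in pairing:
            if call_end.chrom != junc_end.chrom:
                ok = False
                break
            d = abs(call_end.pos - junc_end.pos)
            if d > max_dist:
                ok = False
                break
            total += d
        if ok and (best is None or total < best):
            best = total
    return best


def match_calls(
    calls: Sequence[CallRecord],
    truth: Sequence[Junction],
    max_dist: int = DEFAULT_MAX_DIST,
) -> MatchResult:
    """Assign each call to at most one truth junction (both-breakend
    distance rule, closest assignment); a junction is detected when at
    least one call matches it."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    technology = calls[0].technology if calls else ""
    assignments: list[CallAssignment] = []
    detected: set[str] = set()
    for i, call in enumerate(calls):
        best: Optional[tuple[int, str]] = None
        for junction in truth:
            d = _pair_distance(call, junction, max_dist)
            if d is not None and (best is None or (d, junction.id) < best):
                best = (d, junction.id)
        if best is None:
            assignments.append(CallAssignment(i, None, None))
        else:
            assignments.append(CallAssignment(i, best[1], best[0]))
            detected.add(best[1])
    return MatchResult(
        technology=technology,
        assignments=assignments,
        detected=detected,
        truth_ids=frozenset(j.id for j in truth),
    )


def pairwise_union(results: Mapping[str, MatchResult]) -> pd.DataFrame:
    """Detected-junction counts for each technology and technology pair:
    cell (i, j) = |detected_i ∪ detected_j|, diagonal = single-technology
    counts.  All results must be computed against the same truth set."""
    techs = list(results)
    truth_sets = {r.truth_ids for r in results.values()}
    if len(truth_sets) > 1:
        raise CcrError("match results were computed against different truth sets")
    matrix = pd.DataFrame(index=techs, columns=techs, dtype="Int64")
    for i, t1 in enumerate(techs):
        for j, t2 in enumerate(techs):
            matrix.loc[t1, t2] = len(results[t1].detected | results[t2].detected)
    return matrix
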