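"""Nucleotide-level junction signatures: microhomology, insertions, deletions.

The signature of a junction records how the two segments were joined:

* *microhomology* — short identical sequence shared by both joined segments,
  making the exact break position ambiguous over a range of shifts;
* *insertions* — nucleotides at the junction that belong to neither segment,
  *templated* when copied from reference sequence near either breakend;
* *deletions* — reference nucleotides adjacent to the fused ends that are
  retained nowhere ("balanced" junctions delete nothing).

Summaries bin these quantities the way breakpoint-characteristic tables are
conventionally printed (counts plus integer percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    Breakend,
    CcrError,
    Fragment,
    GenomeModel,
    Junction,
    Side,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nucleotides(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValidationError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# microhomology


def microhomology_length(left_ref: str, right_ref: str) -> int:
    """Number of junction-adjacent positions over which the breakpoint
    placement is ambiguous.

    ``left_ref`` spans the end of the upstream joined segment plus its
    reference continuation; ``right_ref`` spans the reference precedent of
    the downstream segment plus its retained start.  Both are given in
    junction (derivative) orientation with the break at their midpoint.

    The result is the maximal k for which the first k retained downstream
    bases equal the upstream reference continuation, plus the symmetric
    upstream extension — i.e. the width of the interval of breakpoint
    shifts that yield the identical junction sequence.
    """
    left_ref = _check_nucleotides(left_ref, "left_ref")
    right_ref = _check_nucleotides(right_ref, "right_ref")
    if len(left_ref) != len(right_ref) or len(left_ref) % 2:
        raise ValidationError(
            "flank sequences must have equal, even lengths (break at midpoint)"
        )
    w = len(left_ref) // 2
    forward = 0
    while forward < w and left_ref[w + forward] == right_ref[w + forward]:
        forward += 1
    backward = 0
    while backward < w and left_ref[w - backward - 1] == right_ref[w - backward - 1]:
        backward += 1
    return forward + backward


def _oriented_flank(genome: GenomeModel, end: Breakend, window: int) -> tuple[str, str]:
    """(retained, continuation) around a breakend, in the orientation that
    approaches the junction through the retained sequence."""
    seq = genome.sequence(end.chrom)
    if end.side is Side.TAIL:
        retained = seq[max(end.pos - window, 0) : end.pos]
        continuation = seq[end.pos : end.pos + window]
        return retained, continuation
    # head side: the fragment is entered from above in junction orientation
    retained = reverse_complement(seq[end.pos - 1 : end.pos - 1 + window])
    continuation = reverse_complement(seq[max(end.pos - 1 - window, 0) : end.pos - 1])
    return retained, continuation


def junction_flanks(
    junction: Junction, genome: GenomeModel, window: int = 20
) -> tuple[str, str]:
    """Build the (left_ref, right_ref) pair for :func:`microhomology_length`
    from genome sequence.  ``end_a`` is taken as the upstream (leaving) end
    and ``end_b`` as the downstream (entering) end of the junction."""
    up_ret, up_cont = _oriented_flank(genome, junction.end_a, window)
    # end_b is entered: its retained sequence leaves the junction, so the
    # precedent/retained pair is the mirror of the oriented flank.
    down_ret, down_cont = _oriented_flank(genome, junction.end_b, window)
    right_retained = reverse_complement(down_ret)
    right_precedent = reverse_complement(down_cont)
    left_ref = up_ret[-window:] + up_cont[:window]
    right_ref = right_precedent[-window:] + right_retained[:window]
    if len(left_ref) != 2 * window or len(right_ref) != 2 * window:
        raise CcrError(
            f"junction {junction.id}: breakend too close to a chromosome end "
            f"for a {window}-nt scan window"
        )
    return left_ref, right_ref


# ---------------------------------------------------------------------------
# insertions


@dataclass(frozen=True)
class InsertionClass:
    kind: str  # "templated" | "non_templated"
    source_flank: Optional[int] = None  # index into the searched flank list
    source_offset: Optional[int] = None
    reverse_complemented: bool = False

    @property
    def is_templated(self) -> bool:
        return self.kind == "templated"


def classify_insertion(
    inserted_seq: str,
    flank_sequences: Sequence[str],
    min_match: Optional[int] = None,
) -> InsertionClass:
    """Decide whether an insertion is templated from nearby sequence.

    An insertion is templated when a substring of length >= ``min_match``
    (the full insertion for insertions shorter than 20 nt, else 20 nt)
    occurs exactly — or reverse-complemented — in any of the supplied
    reference flanks (conventionally the four flanks within the search
    window of both breakends).
    """
    if not inserted_seq:
        raise ValidationError("classify_insertion requires a non-empty insertion")
    inserted_seq = _check_nucleotides(inserted_seq, "inserted_seq")
    flanks = [_check_nucleotides(f, "flank") for f in flank_sequences]
    if min_match is None:
        min_match = len(inserted_seq) if len(inserted_seq) < 20 else 20
    min_match = min(min_match, len(inserted_seq))
    queries = [
        inserted_seq[i : i + min_match]
        for i in range(len(inserted_seq) - min_match + 1)
    ]
    for fi, flank in enumerate(flanks):
        for q in queries:
            offset = flank.find(q)
            if offset >= 0:
                return InsertionClass("templated", fi, offset, False)
            offset = flank.find(reverse_complement(q))
            if offset >= 0:
                return InsertionClass("templated", fi, offset, True)
    return InsertionClass("non_templated")


def breakend_search_flanks(
    junction: Junction, genome: GenomeModel, window: int = 500
) -> list[str]:
    """The four reference flanks within ``window`` bp of both breakends."""
    flanks = []
    for end in junction.breakends:
        seq = genome.sequence(end.chrom)
        flanks.append(seq[max(end.pos - window, 0) : end.pos])
        flanks.append(seq[end.pos : end.pos + window])
    return flanks


# ---------------------------------------------------------------------------
# deletions


def _outward_gap(
    end: Breakend, by_chrom: dict[str, list[Fragment]]
) -> tuple[int, Optional[tuple[str, int, int]]]:
    """Distance from a fused fragment end to the nearest retained base in
    the outward direction, plus the identity of the spanned reference gap."""
    frags = by_chrom.get(end.chrom, [])
    if end.side is Side.TAIL:
        # nearest retained base above pos (a fragment start, or pos+1 when
        # another — duplicated — fragment covers it)
        cands = [max(f.start, end.pos + 1) for f in frags if f.end > end.pos]
        if not cands:
            return 0, None
        nxt = min(cands)
        gap = nxt - end.pos - 1
        interval = (end.chrom, end.pos + 1, nxt - 1)
    else:
        cands = [min(f.end, end.pos - 1) for f in frags if f.start < end.pos]
        if not cands:
            return 0, None
        prv = max(cands)
        gap = end.pos - prv - 1
        interval = (end.chrom, prv + 1, end.pos - 1)
    if gap < 0:
        raise ValidationError(
            f"negative gap at {end.chrom}:{end.pos} — overlapping retained "
            f"fragments must be modelled as separate (duplicated) fragments"
        )
    return gap, (interval if gap > 0 else None)


def junction_deletion(junction: Junction, fragments: Sequence[Fragment]) -> int:
    """Reference nucleotides lost at a junction: for each breakend, the
    distance to the nearest retained base of the adjacent reference segment.
    A gap flanked by both breakends (reference-adjacent rejoin) is counted
    once; a balanced junction returns 0."""
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    gap_a, interval_a = _outward_gap(junction.end_a, by_chrom)
    gap_b, interval_b = _outward_gap(junction.end_b, by_chrom)
    if interval_a is not None and interval_a == interval_b:
        return gap_a
    return gap_a + gap_b


# ---------------------------------------------------------------------------
# summary


def _pct(count: int, total: int) -> int:
    """Percentage rounded half-up to an integer, as printed in summary tables."""
    if total == 0:
        return 0
    return int(count * 100 / total + 0.5)


@dataclass(frozen=True)
class SignatureSummary:
    """Table of junction-signature bins (counts with integer percentages).

    Deletion bins partition all junctions (balanced = 0 nt; "<10" = 1–9;
    "<100" = 10–99; "<1,000" = 100–999; "<10,000" = 1,000–9,999;
    ">10,000" = 10,000+).  Microhomology bins partition junctions with
    microhomology ("<2" = 1 nt; "2–10"; ">10" kept so the bins stay
    exhaustive).  Insertion bins partition junctions with insertions
    ("<2" = 1 nt; "<20" = 2–19; "<100" = 20–99; ">100" = 100+).
    """

    n_junctions: int
    balanced: int
    del_lt10: int
    del_lt100: int
    del_lt1000: int
    del_lt10000: int
    del_gt10000: int
    mh_total: int
    mh_lt2: int
    mh_2_10: int
    mh_gt10: int
    ins_total: int
    ins_lt2: int
    ins_lt20: int
    ins_lt100: int
    ins_gt100: int
    templated_insertions: int

    def percent(self, field_name: str) -> int:
        return _pct(getattr(self, field_name), self.n_junctions)

    def to_rows(self) -> list[tuple[str, int, int]]:
        """(label, count, percent) rows in conventional table order."""
        labels = [
            ("Total number", "n_junctions"),
            ("Balanced", "balanced"),
            ("<10 nt deletion", "del_lt10"),
            ("<100 nt deletion", "del_lt100"),
            ("<1000 nt deletion", "del_lt1000"),
            ("<10,000 nt deletion", "del_lt10000"),
            (">10,000 nt deletion", "del_gt10000"),
            ("Microhomology, total", "mh_total"),
            ("Microhomology <2 nt", "mh_lt2"),
            ("Microhomology 2-10 nt", "mh_2_10"),
            ("Insertions, total", "ins_total"),
            ("Insertions <2 nt", "ins_lt2"),
            ("Insertions <20 nt", "ins_lt20"),
            ("Insertions <100 nt", "ins_lt100"),
            ("Insertions >100 nt", "ins_gt100"),
            ("Templated insertions", "templated_insertions"),
        ]
        return [(label, getattr(self, f), self.percent(f)) for label, f in labels]


def summarize_signatures(junctions: Sequence[Junction]) -> SignatureSummary:
    """Bin junction signatures; bins are half-open, mutually exclusive and
    invariant under junction reordering."""
    n = len(junctions)
    balanced = d10 = d100 = d1000 = d10000 = dmore = 0
    mh1 = mh210 = mh_more = 0
    i1 = i20 = i100 = imore = 0
    templated = 0
    for j in junctions:
        d = j.deleted_nt
        if d == 0:
            balanced += 1
        elif d < 10:
            d10 += 1
        elif d < 100:
            d100 += 1
        elif d < 1000:
            d1000 += 1
        elif d < 10000:
            d10000 += 1
        else:
            dmore += 1
        if j.microhomology_len == 1:
            mh1 += 1
        elif 2 <= j.microhomology_len <= 10:
            mh210 += 1
        elif j.microhomology_len > 10:
            mh_more += 1
        ilen = len(j.inserted_seq)
        if ilen == 1:
            i1 += 1
        elif 2 <= ilen < 20:
            i20 += 1
        elif 20 <= ilen < 100:
            i100 += 1
        elif ilen >= 100:
            imore += 1
        if ilen and j.templated:
            templated += 1
    return SignatureSummary(
        n_junctions=n,
        balanced=balanced,
        del_lt10=d10,
        del_lt100=d100,
        del_lt1000=d1000,
        del_lt10000=d10000,
        del_gt10000=dmore,
        mh_total=mh1 + mh210 + mh_more,
        mh_lt2=mh1,
        mh_2_10=mh210,
        mh_gt10=mh_more,
        ins_total=i1 + i20 + i100 + imore,
        ins_lt2=i1,
        ins_lt20=i20,
        ins_lt100=i100,
        ins_gt100=imore,
        templated_insertions=templated,
    )
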