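"""Readers and writers for the external formats the pipeline touches.

Formats
-------
Fragment table (TSV)
    One row per placed fragment, in derivative order, with columns
    ``fragment_id chrom start end orientation derivative junction_id_head
    junction_id_tail inserted_seq microhomology deleted_nt``.  Coordinates
    are 1-based inclusive.  ``junction_id_head``/``junction_id_tail`` name
    the junctions attached to the fragment's native head/tail ends; the
    three signature columns describe the junction linking the row to the
    next row of the same derivative (blank on each derivative's last row).

bedpe
    Standard 0-based half-open columns ``chrom1 start1 end1 chrom2 start2
    end2 name score strand1 strand2``; a "+" strand means the retained
    segment extends toward lower coordinates (tail side), "-" means head
    side.  Three extra columns (``inserted_seq microhomology deleted_nt``)
    are written and, when present, read back, so junction lists round-trip.

VCF (BND subset)
    Breakend bracket notation per the VCF specification; mate pairs are
    collapsed to single call records.

BED
    TAD and gene intervals, converted to 1-based inclusive at parse time.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam

from .model import (
    Breakend,
    CallRecord,
    CcrError,
    DerivativeChromosome,
    Fragment,
    Gene,
    Junction,
    Orientation,
    Side,
    Tad,
    validate_fragments,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

FRAGMENT_TABLE_COLUMNS = [
    "fragment_id",
    "chrom",
    "start",
    "end",
    "orientation",
    "derivative",
    "junction_id_head",
    "junction_id_tail",
    "inserted_seq",
    "microhomology",
    "deleted_nt",
]


class ParseError(CcrError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path: PathLike, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


# ---------------------------------------------------------------------------
# fragment table


def _parse_int(value: str, path: PathLike, line: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, line, f"invalid {what}: {value!r}") from None


def read_fragment_table(
    path: PathLike, allow_overlap: bool = False
) -> tuple[list[Fragment], list[Junction], list[str]]:
    """Parse a fragment table into fragments, junctions and derivative names.

    Junction breakends are reconstructed from the native ends of the two
    fragments each junction links.  Raises :class:`ParseError` on malformed
    rows and :class:`ValidationError` on overlapping fragments (unless
    ``allow_overlap``, for rearrangements with duplicated segments).
    """
    rows: list[tuple[int, dict[str, str]]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols != FRAGMENT_TABLE_COLUMNS:
            raise ParseError(path, 1, f"unexpected header: {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    path, lineno, f"expected {len(cols)} columns, got {len(fields)}"
                )
            rows.append((lineno, dict(zip(cols, fields))))

    fragments: list[Fragment] = []
    derivative_rows: dict[str, list[tuple[int, dict[str, str], Fragment]]] = {}
    derivative_names: list[str] = []
    for lineno, row in rows:
        if row["orientation"] not in ("+", "-"):
            raise ParseError(path, lineno, f"invalid orientation {row['orientation']!r}")
        frag = Fragment(
            id=row["fragment_id"],
            chrom=row["chrom"],
            start=_parse_int(row["start"], path, lineno, "start"),
            end=_parse_int(row["end"], path, lineno, "end"),
            junction_head=row["junction_id_head"] or None,
            junction_tail=row["junction_id_tail"] or None,
        )
        fragments.append(frag)
        der = row["derivative"]
        if der not in derivative_rows:
            derivative_rows[der] = []
            derivative_names.append(der)
        derivative_rows[der].append((lineno, row, frag))

    validate_fragments(fragments, allow_overlap=allow_overlap)

    junctions: list[Junction] = []
    for der in derivative_names:
        entries = derivative_rows[der]
        for (lineno, row, frag), (nlineno, nrow, nfrag) in zip(entries, entries[1:]):
            ori = Orientation(row["orientation"])
            nori = Orientation(nrow["orientation"])
            leaving_side = Side.TAIL if ori is Orientation.FORWARD else Side.HEAD
            entering_side = Side.HEAD if nori is Orientation.FORWARD else Side.TAIL
            jid = frag.junction_at(leaving_side)
            if jid is None:
                raise ParseError(
                    path, lineno, f"fragment {frag.id} lacks a junction toward {nfrag.id}"
                )
            if nfrag.junction_at(entering_side) != jid:
                raise ParseError(
                    path,
                    nlineno,
                    f"junction mismatch between {frag.id} ({jid}) and "
                    f"{nfrag.id} ({nfrag.junction_at(entering_side)})",
                )
            junctions.append(
                Junction(
                    id=jid,
                    end_a=frag.breakend(leaving_side),
                    end_b=nfrag.breakend(entering_side),
                    inserted_seq=row["inserted_seq"],
                    microhomology_len=_parse_int(
                        row["microhomology"] or "0", path, lineno, "microhomology"
                    ),
                    deleted_nt=_parse_int(
                        row["deleted_nt"] or "0", path, lineno, "deleted_nt"
                    ),
                )
            )
    return fragments, junctions, derivative_names


def write_fragment_table(derivatives: Sequence[DerivativeChromosome], path: PathLike) -> None:
    """Serialize derivative chains to the fragment-table TSV."""
    lines = ["\t".join(FRAGMENT_TABLE_COLUMNS)]
    for der in derivatives:
        for i, placed in enumerate(der.chain):
            frag = placed.fragment
            leading = der.junctions[i - 1].id if i > 0 else ""
            trailing = der.junctions[i].id if i < len(der.junctions) else ""
            if placed.orientation is Orientation.FORWARD:
                head_id, tail_id = leading, trailing
            else:
                head_id, tail_id = trailing, leading
            if i < len(der.junctions):
                j = der.junctions[i]
                sig = [j.inserted_seq, str(j.microhomology_len), str(j.deleted_nt)]
            else:
                sig = ["", "", ""]
            lines.append(
                "\t".join(
                    [
                        frag.id,
                        frag.chrom,
                        str(frag.start),
                        str(frag.end),
                        placed.orientation.value,
                        der.name,
                        head_id,
                        tail_id,
                    ]
                    + sig
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bedpe

_STRAND_TO_SIDE = {"+": Side.TAIL, "-": Side.HEAD}
_SIDE_TO_STRAND = {Side.TAIL: "+", Side.HEAD: "-"}


def read_bedpe(path: PathLike) -> list[Junction]:
    """Read junctions from a bedpe file (0-based half-open converted to
    1-based inclusive; the internal position is the bedpe *end* value)."""
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            fields = raw.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
            chrom1, _, end1, chrom2, _, end2 = fields[:6]
            name = fields[6] if len(fields) > 6 and fields[6] != "." else f"J{len(junctions) + 1}"
            if len(fields) >= 10:
                try:
                    side_a = _STRAND_TO_SIDE[fields[8]]
                    side_b = _STRAND_TO_SIDE[fields[9]]
                except KeyError as exc:
                    raise ParseError(path, lineno, f"invalid strand {exc.args[0]!r}") from None
            else:
                side_a, side_b = Side.TAIL, Side.HEAD
            inserted = fields[10] if len(fields) > 10 else ""
            micro = _parse_int(fields[11], path, lineno, "microhomology") if len(fields) > 11 else 0
            deleted = _parse_int(fields[12], path, lineno, "deleted_nt") if len(fields) > 12 else 0
            junctions.append(
                Junction(
                    id=name,
                    end_a=Breakend(chrom1, _parse_int(end1, path, lineno, "end1"), side_a),
                    end_b=Breakend(chrom2, _parse_int(end2, path, lineno, "end2"), side_b),
                    inserted_seq=inserted,
                    microhomology_len=micro,
                    deleted_nt=deleted,
                )
            )
    return junctions


def write_bedpe(junctions: Iterable[Junction], path: PathLike) -> None:
    lines = []
    for j in junctions:
        lines.append(
            "\t".join(
                [
                    j.end_a.chrom,
                    str(j.end_a.pos - 1),
                    str(j.end_a.pos),
                    j.end_b.chrom,
                    str(j.end_b.pos - 1),
                    str(j.end_b.pos),
                    j.id,
                    ".",
                    _SIDE_TO_STRAND[j.end_a.side],
                    _SIDE_TO_STRAND[j.end_b.side],
                    j.inserted_seq,
                    str(j.microhomology_len),
                    str(j.deleted_nt),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# VCF breakend notation

_BND_RE = re.compile(r"([\[\]])([^\[\]:]+):(\d+)([\[\]])")


def _parse_bnd_alt(alt: str) -> tuple[Side, str, int, Side]:
    """Decode a bracket ALT into (local side, mate chrom, mate pos, mate side).

    ``t[p[`` joins the local tail to the mate's head; ``t]p]`` tail-to-tail;
    ``]p]t`` head-to-tail; ``[p[t`` head-to-head.
    """
    m = _BND_RE.search(alt)
    if m is None:
        raise CcrError(f"not a breakend ALT: {alt!r}")
    local_side = Side.HEAD if alt[0] in "[]" else Side.TAIL
    mate_side = Side.HEAD if m.group(1) == "[" else Side.TAIL
    return local_side, m.group(2), int(m.group(3)), mate_side


def _format_bnd_alt(ref: str, local_side: Side, mate: Breakend) -> str:
    bracket = "[" if mate.side is Side.HEAD else "]"
    core = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
    return f"{ref}{core}" if local_side is Side.TAIL else f"{core}{ref}"


def read_vcf_bnd(path: PathLike, technology: Optional[str] = None) -> list[CallRecord]:
    """Read BND records, collapsing each mate pair to one call record.

    Mates are paired by ``MATEID`` when present, otherwise by reciprocal
    coordinates.  Unmatched mates are skipped with a logged warning.
    """
    if technology is None:
        technology = Path(path).stem
    records: dict[str, tuple[Breakend, Breakend, Optional[str]]] = {}
    order: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if not alts or _BND_RE.search(alts[0]) is None:
                continue
            local_side, mate_chrom, mate_pos, mate_side = _parse_bnd_alt(alts[0])
            mate_id = rec.info.get("MATEID")
            if isinstance(mate_id, tuple):
                mate_id = mate_id[0]
            rid = rec.id or f"{rec.chrom}:{rec.pos}:{len(order)}"
            records[rid] = (
                Breakend(rec.chrom, rec.pos, local_side),
                Breakend(mate_chrom, mate_pos, mate_side),
                mate_id,
            )
            order.append(rid)

    calls: list[CallRecord] = []
    consumed: set[str] = set()
    for rid in order:
        if rid in consumed:
            continue
        local, mate, mate_id = records[rid]
        if mate_id is not None and mate_id in records:
            other_local, other_mate, _ = records[mate_id]
            if other_mate == local and other_local == mate:
                consumed.add(rid)
                consumed.add(mate_id)
                calls.append(CallRecord(technology, local, mate))
                continue
        # fall back to reciprocal-coordinate pairing
        partner = None
        for oid in order:
            if oid == rid or oid in consumed:
                continue
            olocal, omate, _ = records[oid]
            if olocal == mate and omate == local:
                partner = oid
                break
        if partner is not None:
            consumed.add(rid)
            consumed.add(partner)
            calls.append(CallRecord(technology, local, mate))
        else:
            consumed.add(rid)
            logger.warning("skipping unmatched breakend %s in %s", rid, path)
    return calls


def write_vcf_bnd(
    calls: Iterable[CallRecord],
    path: PathLike,
    contigs: Sequence[tuple[str, int]],
    source: str = "ccrkit",
) -> None:
    """Write call records as BND mate pairs (VCF 4.2 subset)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    ]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, call in enumerate(calls, start=1):
        id_a, id_b = f"bnd_{i}a", f"bnd_{i}b"
        for rid, mid, local, mate in (
            (id_a, id_b, call.end_a, call.end_b),
            (id_b, id_a, call.end_b, call.end_a),
        ):
            alt = _format_bnd_alt("N", local.side, mate)
            lines.append(
                f"{local.chrom}\t{local.pos}\t{rid}\tN\t{alt}\t.\t.\t"
                f"SVTYPE=BND;MATEID={mid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED and FASTA


def _read_bed_rows(path: PathLike) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED rows need at least 3 columns")
            rows.append((lineno, fields))
    return rows


def read_tads(path: PathLike) -> list[Tad]:
    """Read TAD intervals from BED (0-based half-open -> 1-based inclusive)."""
    tads = []
    for lineno, fields in _read_bed_rows(path):
        name = fields[3] if len(fields) > 3 else f"tad{len(tads) + 1}"
        tads.append(
            Tad(
                id=name,
                chrom=fields[0],
                start=_parse_int(fields[1], path, lineno, "start") + 1,
                end=_parse_int(fields[2], path, lineno, "end"),
            )
        )
    return tads


def read_genes(path: PathLike) -> list[Gene]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    genes = []
    for lineno, fields in _read_bed_rows(path):
        name = fields[3] if len(fields) > 3 else f"gene{len(genes) + 1}"
        strand = fields[5] if len(fields) > 5 else "+"
        genes.append(
            Gene(
                name=name,
                chrom=fields[0],
                start=_parse_int(fields[1], path, lineno, "start") + 1,
                end=_parse_int(fields[2], path, lineno, "end"),
                strand=strand,
            )
        )
    return genes


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: PathLike) -> None:
    """Write (chrom, start, end, name) 1-based inclusive intervals as BED."""
    lines = [f"{c}\t{s - 1}\t{e}\t{n}" for c, s, e, n in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_fasta(path: PathLike) -> dict[str, str]:
    sequences: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            sequences[entry.name] = entry.sequence.upper()
    return sequences


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
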