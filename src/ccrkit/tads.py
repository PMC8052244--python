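"""Intersection of breakpoints and junctions with topologically associated
domains (TADs).

Breakpoints are assigned by point containment (a breakpoint increments
every TAD containing it, so nested/overlapping TADs are multi-assigned);
genes by >= 1 bp interval overlap.  A junction *bridges* TADs when its two
breakends share no containing TAD (including one end inside and one end
outside all TADs); junctions with both ends outside every TAD are not
counted as bridging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import Breakend, Gene, Junction, Tad


def _tad_trees(tads: Sequence[Tad]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in tads:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end + 1, t.id)
    return trees


def _containing_tads(trees: dict[str, IntervalTree], end: Breakend) -> set[str]:
    tree = trees.get(end.chrom)
    if tree is None:
        return set()
    return {iv.data for iv in tree.at(end.pos)}


@dataclass
class TadReport:
    """Per-TAD and global counts of rearrangement impact."""

    tads: list[Tad]
    breakpoint_counts: dict[str, int] = field(default_factory=dict)
    junction_counts: dict[str, int] = field(default_factory=dict)
    inter_tad_counts: dict[str, int] = field(default_factory=dict)
    gene_counts: dict[str, int] = field(default_factory=dict)
    unassigned_breakpoints: int = 0
    bridging_junctions: int = 0

    @property
    def affected_tads(self) -> int:
        return sum(1 for t in self.tads if self.breakpoint_counts.get(t.id, 0) > 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tads:
            rows.append(
                {
                    "tad": t.id,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "breakpoints": self.breakpoint_counts.get(t.id, 0),
                    "junctions": self.junction_counts.get(t.id, 0),
                    "inter_tad_junctions": self.inter_tad_counts.get(t.id, 0),
                    "genes": self.gene_counts.get(t.id, 0),
                }
            )
        return pd.DataFrame(rows)


def assign_breakpoints(breakpoints: Sequence[Breakend], tads: Sequence[Tad]) -> TadReport:
    """Assign each breakpoint to every TAD containing it; breakpoints in no
    TAD are tallied as unassigned.  Deterministic and independent of TAD
    input order."""
    trees = _tad_trees(tads)
    report = TadReport(tads=list(tads))
    for bp in breakpoints:
        containing = _containing_tads(trees, bp)
        if not containing:
            report.unassigned_breakpoints += 1
        for tid in containing:
            report.breakpoint_counts[tid] = report.breakpoint_counts.get(tid, 0) + 1
    return report


def inter_tad_junctions(junctions: Sequence[Junction], tads: Sequence[Tad]) -> int:
    """Junctions whose breakends fall in different TADs (or one inside and
    one outside every TAD)."""
    trees = _tad_trees(tads)
    count = 0
    for j in junctions:
        tads_a = _containing_tads(trees, j.end_a)
        tads_b = _containing_tads(trees, j.end_b)
        if (tads_a or tads_b) and not (tads_a & tads_b):
            count += 1
    return count


def genes_in_tads(tads: Sequence[Tad], genes: Sequence[Gene]) -> dict[str, int]:
    """Per-TAD gene counts; a gene counts in every TAD it overlaps by
    >= 1 bp (a gene straddling two TADs counts in both)."""
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.name)
    counts: dict[str, int] = {}
    for t in tads:
        tree = gene_trees.get(t.chrom)
        counts[t.id] = len(tree.overlap(t.start, t.end + 1)) if tree is not None else 0
    return counts


def build_tad_report(
    junctions: Sequence[Junction], tads: Sequence[Tad], genes: Sequence[Gene]
) -> TadReport:
    """Full TAD-disruption report: per-TAD breakpoint/junction/bridging/gene
    counts plus global affected-TAD, unassigned-breakpoint and bridging
    totals."""
    trees = _tad_trees(tads)
    breakpoints = [end for j in junctions for end in j.breakends]
    report = assign_breakpoints(breakpoints, tads)
    report.gene_counts = genes_in_tads(tads, genes)
    for j in junctions:
        tads_a = _containing_tads(trees, j.end_a)
        tads_b = _containing_tads(trees, j.end_b)
        for tid in tads_a | tads_b:
            report.junction_counts[tid] = report.junction_counts.get(tid, 0) + 1
        if (tads_a or tads_b) and not (tads_a & tads_b):
            report.bridging_junctions += 1
            for tid in tads_a | tads_b:
                report.inter_tad_counts[tid] = report.inter_tad_counts.get(tid, 0) + 1
    return report
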