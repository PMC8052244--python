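"""Mechanism-of-formation classification from rearrangement signatures.

Four formation mechanisms leave distinguishable footprints in a complex
rearrangement:

* **BFB** (breakage-fusion-bridge) — iterative telomere-loss cycles:
  fold-back (head-to-head/tail-to-tail) fusions, terminal losses,
  duplications;
* **chromothripsis** — one localized shattering of one or a few (< 4)
  chromosomes with random rejoining: clustered breakpoints, deletions and
  copy-neutral fragments, no duplications;
* **replicative** (chromoanasynthesis / FoSTeS / MMBIR) — template
  switching during replication: templated insertions, 2–10 nt
  microhomology, duplications, non-clustered breakpoints;
* **chromoplexy** — chained, largely balanced rearrangement of several
  (> 2) chromosomes with breakpoints clustered inside genes.

The classifier turns these narrative signatures into an explicit decision
table over a deterministic feature vector.  The thresholds (alpha, the
"balanced high" fraction, the window-dispersion cutoff) are declared
package constants — a formalization, not field-standard prescriptions.
Chromoanasynthesis and generic replicative error are merged into one
category because their junction-level signatures coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import DerivativeChromosome, GenomeModel, Junction
from .signatures import SignatureSummary, summarize_signatures
from .stats import (
    OrientationCounts,
    foldback_enrichment,
    monte_carlo_intragenic,
    orientation_counts,
)

MECHANISMS = ("bfb", "chromothripsis", "replicative", "chromoplexy")

#: significance level for the fold-back and intragenic-enrichment criteria
DEFAULT_ALPHA = 0.05
#: "balanced high": fraction of junctions deleting < 1 kbp
BALANCED_HIGH = 0.8
#: "clustering high": variance-to-mean ratio of per-window breakpoint counts
CLUSTERING_HIGH = 5.0
#: "microhomology elevated": fraction of junctions with 2-10 nt microhomology
MICROHOMOLOGY_ELEVATED = 0.2
#: window for the breakpoint-clustering dispersion statistic
CLUSTER_WINDOW = 1_000_000


@dataclass(frozen=True)
class MechanismFeatures:
    n_chromosomes_involved: int
    has_duplications: bool
    fraction_templated_insertions: float
    fraction_microhomology_2_10: float
    fraction_balanced: float  # junctions deleting < 1 kbp
    foldback_p: float
    intragenic_p: float
    breakpoint_clustering: float  # variance-to-mean ratio over windows
    terminal_loss: bool


@dataclass(frozen=True)
class CriterionResult:
    description: str
    satisfied: bool


@dataclass
class MechanismReport:
    criteria: dict[str, list[CriterionResult]]
    scores: dict[str, int] = field(init=False)
    verdict: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.scores = {
            m: sum(1 if c.satisfied else -1 for c in crits)
            for m, crits in self.criteria.items()
        }
        best = max(self.scores.values())
        self.verdict = tuple(m for m in MECHANISMS if self.scores[m] == best)

    @property
    def is_tie(self) -> bool:
        return len(self.verdict) > 1

    def to_dict(self) -> dict:
        return {
            "scores": dict(self.scores),
            "verdict": list(self.verdict),
            "criteria": {
                m: [{"criterion": c.description, "satisfied": c.satisfied} for c in crits]
                for m, crits in self.criteria.items()
            },
        }


def breakpoint_dispersion(
    derivatives: Sequence[DerivativeChromosome],
    chrom_lengths: dict[str, int],
    window: int = CLUSTER_WINDOW,
) -> float:
    """Variance-to-mean ratio of per-window breakpoint counts over the
    involved chromosomes (~1 for uniform scattering, large when breakpoints
    cluster).  Breakpoints are the distinct internal fragment boundaries."""
    positions: dict[str, set[int]] = {}
    for der in derivatives:
        for i, placed in enumerate(der.chain):
            f = placed.fragment
            # interior boundaries only: chromosome ends are not breakpoints
            for pos, boundary in ((f.start, f.start > 1), (f.end, f.end < chrom_lengths.get(f.chrom, f.end))):
                if boundary:
                    positions.setdefault(f.chrom, set()).add(pos)
    counts: list[int] = []
    for chrom in sorted(positions):
        length = chrom_lengths[chrom]
        edges = np.arange(0, length + window, window)
        hist, _ = np.histogram(sorted(positions[chrom]), bins=edges)
        counts.extend(hist.tolist())
    if not counts:
        return 0.0
    arr = np.asarray(counts, dtype=float)
    mean = arr.mean()
    return float(arr.var() / mean) if mean > 0 else 0.0


def _has_duplications(derivatives: Sequence[DerivativeChromosome]) -> bool:
    """Overlapping placed intervals on one chromosome indicate duplicated
    sequence (fold-back copies or replicative re-use)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for der in derivatives:
        for placed in der.chain:
            f = placed.fragment
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for intervals in by_chrom.values():
        intervals.sort()
        for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                return True
    return False


def _terminal_loss(
    derivatives: Sequence[DerivativeChromosome], chrom_lengths: dict[str, int]
) -> bool:
    """True when an involved chromosome's first or last base is retained
    nowhere (a telomeric segment was lost)."""
    covered_first: dict[str, bool] = {}
    covered_last: dict[str, bool] = {}
    for der in derivatives:
        for placed in der.chain:
            f = placed.fragment
            covered_first.setdefault(f.chrom, False)
            covered_last.setdefault(f.chrom, False)
            if f.start == 1:
                covered_first[f.chrom] = True
            if f.end == chrom_lengths.get(f.chrom, -1):
                covered_last[f.chrom] = True
    return any(
        not (covered_first[c] and covered_last[c]) for c in covered_first
    )


def extract_features(
    derivatives: Sequence[DerivativeChromosome],
    junctions: Sequence[Junction],
    genome: GenomeModel,
    signature_summary: Optional[SignatureSummary] = None,
    mc_iterations: int = 1000,
    seed: Optional[int] = None,
    cluster_window: int = CLUSTER_WINDOW,
) -> MechanismFeatures:
    """Deterministic feature vector for the mechanism decision table.

    The fold-back test aggregates orientation counts over all derivatives;
    the intragenic Monte Carlo uses the genome's gene annotation and the
    involved chromosomes' lengths.
    """
    if signature_summary is None:
        signature_summary = summarize_signatures(junctions)
    chroms = sorted({p.fragment.chrom for d in derivatives for p in d.chain})
    if not junctions or not chroms:
        return MechanismFeatures(
            n_chromosomes_involved=len(chroms),
            has_duplications=False,
            fraction_templated_insertions=0.0,
            fraction_microhomology_2_10=0.0,
            fraction_balanced=0.0,
            foldback_p=1.0,
            intragenic_p=1.0,
            breakpoint_clustering=0.0,
            terminal_loss=False,
        )
    n = signature_summary.n_junctions
    lengths = {c: L for c, L in genome.lengths.items() if c in chroms}
    totals = OrientationCounts("overall", 0, 0, 0, 0)
    for der in derivatives:
        if len(der.chain) > 1:
            totals = totals + orientation_counts(der)
    foldback_p = foldback_enrichment(totals).p_value if totals.n_junctions else 1.0
    genes = [g for g in genome.genes if g.chrom in chroms]
    intragenic_p = monte_carlo_intragenic(
        junctions, genes, lengths, iterations=mc_iterations, seed=seed
    ).p_value
    return MechanismFeatures(
        n_chromosomes_involved=len(chroms),
        has_duplications=_has_duplications(derivatives),
        fraction_templated_insertions=signature_summary.templated_insertions / n,
        fraction_microhomology_2_10=signature_summary.mh_2_10 / n,
        fraction_balanced=(n - signature_summary.del_lt10000 - signature_summary.del_gt10000) / n,
        foldback_p=foldback_p,
        intragenic_p=intragenic_p,
        breakpoint_clustering=breakpoint_dispersion(derivatives, lengths, cluster_window),
        terminal_loss=_terminal_loss(derivatives, genome.lengths),
    )


def score_mechanisms(
    features: MechanismFeatures, alpha: float = DEFAULT_ALPHA
) -> MechanismReport:
    """Evaluate the decision table; score = satisfied − violated criteria,
    verdict = argmax (ties reported as ties)."""
    f = features
    criteria = {
        "bfb": [
            CriterionResult(
                f"fold-back fusion enrichment p < {alpha}", f.foldback_p < alpha
            ),
            CriterionResult("terminal (telomeric) segment lost", f.terminal_loss),
        ],
        "chromothripsis": [
            CriterionResult(
                f"breakpoints clustered (dispersion > {CLUSTERING_HIGH})",
                f.breakpoint_clustering > CLUSTERING_HIGH,
            ),
            CriterionResult(
                "localized to one or a few (< 4) chromosomes",
                1 <= f.n_chromosomes_involved <= 3,
            ),
            CriterionResult("no duplications", not f.has_duplications),
        ],
        "replicative": [
            CriterionResult(
                "duplications or templated insertions present",
                f.has_duplications or f.fraction_templated_insertions > 0,
            ),
            CriterionResult(
                f"2-10 nt microhomology elevated (>= {MICROHOMOLOGY_ELEVATED})",
                f.fraction_microhomology_2_10 >= MICROHOMOLOGY_ELEVATED,
            ),
        ],
        "chromoplexy": [
            CriterionResult(
                f"intragenic breakpoint enrichment p < {alpha}", f.intragenic_p < alpha
            ),
            CriterionResult(
                f"largely balanced (fraction deleting < 1 kbp >= {BALANCED_HIGH})",
                f.fraction_balanced >= BALANCED_HIGH,
            ),
            CriterionResult(
                "involves several (> 2) chromosomes", f.n_chromosomes_involved > 2
            ),
        ],
    }
    return MechanismReport(criteria)
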