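"""Statistical assessment of rearrangement structure.

Three families of tests characterise how a complex rearrangement was
assembled:

* exact one-sided binomial tests of how fragments from each chromosome of
  origin distribute across the derivative chromosomes (null: uniform,
  p0 = 1/#derivatives);
* exact one-sided binomial tests of fusion-orientation classes
  (tail-to-head, head-to-tail, head-to-head, tail-to-tail; null p0 = 1/4),
  plus a fold-back enrichment test (head-to-head + tail-to-tail vs p0 = 1/2)
  that screens for breakage-fusion-bridge cycles;
* a Monte Carlo test of intragenic breakpoint enrichment: the observed
  number of junctions with a breakend inside a gene is compared with
  junction sets drawn uniformly over the involved chromosomes.

All binomial tails are exact cumulative sums of point probabilities, never
normal approximations.  The direction is chosen toward the observed
deviation; at k exactly equal to n*p0 the lower tail is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom

from .model import (
    CcrError,
    DerivativeChromosome,
    Fragment,
    Gene,
    Junction,
    Orientation,
)

ORIENTATION_CLASSES = ("tail_to_head", "head_to_tail", "head_to_head", "tail_to_tail")

# native ends fused when (upstream, downstream) orientations meet at a junction
_FUSION_CLASS = {
    (Orientation.FORWARD, Orientation.FORWARD): "tail_to_head",
    (Orientation.REVERSE, Orientation.REVERSE): "head_to_tail",
    (Orientation.FORWARD, Orientation.REVERSE): "tail_to_tail",
    (Orientation.REVERSE, Orientation.FORWARD): "head_to_head",
}


@dataclass(frozen=True)
class BinomialTestResult:
    n: int
    k: int
    p0: float
    direction: str  # "lower" | "upper"
    p_value: float


def exact_binomial_one_sided(n: int, k: int, p0: float) -> BinomialTestResult:
    """Exact one-sided binomial tail.

    ``direction`` is "upper" (P[X >= k]) when k > n*p0, else "lower"
    (P[X <= k]); ties at k = n*p0 use the lower tail.
    """
    if n < 0 or not (0 <= k <= n):
        raise ValueError(f"invalid trials/successes: n={n}, k={k}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    if k > n * p0:
        return BinomialTestResult(n, k, p0, "upper", float(binom.sf(k - 1, n, p0)))
    return BinomialTestResult(n, k, p0, "lower", float(binom.cdf(k, n, p0)))


# ---------------------------------------------------------------------------
# fragment distribution across derivatives


@dataclass
class DistributionMatrix:
    """Per (origin chromosome x derivative) fragment counts, fractions and
    exact binomial tests (p0 = 1/#derivatives, n = origin fragment total)."""

    origins: list[str]
    derivatives: list[str]
    counts: dict[tuple[str, str], int]
    tests: dict[tuple[str, str], BinomialTestResult]

    def origin_total(self, origin: str) -> int:
        return sum(self.counts[(origin, d)] for d in self.derivatives)

    def fraction(self, origin: str, derivative: str) -> float:
        total = self.origin_total(origin)
        return self.counts[(origin, derivative)] / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for der in self.derivatives:
            row: dict[str, Union[str, int, float]] = {"derivative": der}
            for origin in self.origins:
                row[f"{origin}_count"] = self.counts[(origin, der)]
                row[f"{origin}_fraction"] = round(self.fraction(origin, der), 2)
                row[f"{origin}_p"] = self.tests[(origin, der)].p_value
            rows.append(row)
        return pd.DataFrame(rows)


def fragment_distribution_test(
    fragments: Sequence[Fragment],
    derivatives: Sequence[DerivativeChromosome],
) -> DistributionMatrix:
    """Test whether fragments of each origin spread uniformly across the
    derivatives.  For origin o and derivative d: k = fragments of o placed
    on d, n = total fragments of o, p0 = 1/#derivatives, one exact
    one-sided test per cell.  Derivatives without fragments of an origin
    are retained as k = 0 cells."""
    if not derivatives:
        raise ValueError("at least one derivative is required")
    placement: dict[str, str] = {}
    for der in derivatives:
        for placed in der.chain:
            placement[placed.fragment.id] = der.name
    missing = [f.id for f in fragments if f.id not in placement]
    if missing:
        raise CcrError(f"fragments without derivative assignment: {', '.join(missing)}")
    origins = sorted({f.origin_chrom for f in fragments})
    der_names = [d.name for d in derivatives]
    p0 = 1.0 / len(derivatives)
    counts = {(o, d): 0 for o in origins for d in der_names}
    for f in fragments:
        counts[(f.origin_chrom, placement[f.id])] += 1
    tests = {}
    for o in origins:
        n = sum(counts[(o, d)] for d in der_names)
        for d in der_names:
            tests[(o, d)] = exact_binomial_one_sided(n, counts[(o, d)], p0)
    return DistributionMatrix(origins, der_names, counts, tests)


# ---------------------------------------------------------------------------
# fusion orientation


@dataclass(frozen=True)
class OrientationCounts:
    """Counts of the four fusion classes within one derivative."""

    derivative: str
    tail_to_head: int
    head_to_tail: int
    head_to_head: int
    tail_to_tail: int

    @property
    def n_junctions(self) -> int:
        return self.tail_to_head + self.head_to_tail + self.head_to_head + self.tail_to_tail

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in ORIENTATION_CLASSES}

    def __add__(self, other: "OrientationCounts") -> "OrientationCounts":
        return OrientationCounts(
            "overall",
            self.tail_to_head + other.tail_to_head,
            self.head_to_tail + other.head_to_tail,
            self.head_to_head + other.head_to_head,
            self.tail_to_tail + other.tail_to_tail,
        )


def orientation_counts(derivative: DerivativeChromosome) -> OrientationCounts:
    """Classify each adjacent fragment pair by the native ends it fuses:
    forward->forward is tail-to-head, reverse->reverse head-to-tail,
    forward->reverse tail-to-tail, reverse->forward head-to-head."""
    tally = dict.fromkeys(ORIENTATION_CLASSES, 0)
    for up, down in zip(derivative.chain, derivative.chain[1:]):
        tally[_FUSION_CLASS[(up.orientation, down.orientation)]] += 1
    return OrientationCounts(derivative.name, *(tally[c] for c in ORIENTATION_CLASSES))


def orientation_tests(counts: OrientationCounts) -> dict[str, BinomialTestResult]:
    """Exact one-sided test per fusion class (n = junctions, p0 = 1/4)."""
    n = counts.n_junctions
    if n < 1:
        raise ValueError("orientation tests require at least one junction")
    return {
        c: exact_binomial_one_sided(n, getattr(counts, c), 0.25)
        for c in ORIENTATION_CLASSES
    }


def foldback_enrichment(counts: OrientationCounts) -> BinomialTestResult:
    """Enrichment of fold-back fusions (head-to-head + tail-to-tail,
    p0 = 1/2) — the orientation signature of breakage-fusion-bridge."""
    n = counts.n_junctions
    if n < 1:
        raise ValueError("fold-back test requires at least one junction")
    return exact_binomial_one_sided(n, counts.head_to_head + counts.tail_to_tail, 0.5)


# ---------------------------------------------------------------------------
# intragenic enrichment


def count_intragenic(junctions: Sequence[Junction], genes: Sequence[Gene]) -> int:
    """Junctions with at least one breakend inside at least one gene
    (inclusive interval bounds)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.name)
    count = 0
    for j in junctions:
        for end in j.breakends:
            tree = trees.get(end.chrom)
            if tree is not None and tree.overlaps_point(end.pos):
                count += 1
                break
    return count


def _merged_gene_arrays(
    genes: Sequence[Gene], chrom_lengths: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Merged gene intervals in a concatenated-genome coordinate, plus
    chromosome offsets, for vectorised membership tests."""
    chroms = sorted(chrom_lengths)
    offsets = np.concatenate([[0], np.cumsum([chrom_lengths[c] for c in chroms])])
    starts, ends = [], []
    for ci, chrom in enumerate(chroms):
        ivals = sorted(
            (g.start, g.end) for g in genes if g.chrom == chrom
        )
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        off = offsets[ci]
        starts.extend(off + s for s, _ in merged)
        ends.extend(off + e for _, e in merged)
    return np.asarray(starts), np.asarray(ends), offsets, chroms


@dataclass(frozen=True)
class MonteCarloResult:
    p_value: float
    observed: int
    iterations: int
    sim_counts: np.ndarray = field(repr=False, compare=False, default=None)

    def formatted_p(self) -> str:
        """Strict-inequality Monte Carlo can return 0; report a bound then."""
        if self.p_value == 0.0:
            return f"p < {1.0 / self.iterations:g}"
        return f"p = {self.p_value:g}"


def monte_carlo_intragenic(
    junctions: Sequence[Junction],
    genes: Sequence[Gene],
    chrom_lengths: dict[str, int],
    iterations: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    observed: Optional[int] = None,
) -> MonteCarloResult:
    """Monte Carlo intragenic-enrichment test.

    Each iteration draws the observed number of junctions with both
    breakends uniform over the concatenated involved chromosomes (every
    base equally likely) and counts intragenic junctions; the p-value is
    the fraction of iterations whose count strictly exceeds the observed
    count (no pseudocount, so the minimum reportable p is 0).
    Reproducible bit-for-bit for a given (seed, iterations).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if observed is None:
        observed = count_intragenic(junctions, genes)
    n_junctions = len(junctions)
    if n_junctions == 0:
        # no junctions can be drawn, so no simulation exceeds the observed count
        return MonteCarloResult(0.0, observed, iterations, np.zeros(iterations, dtype=int))
    starts, ends, offsets, chroms = _merged_gene_arrays(genes, chrom_lengths)
    total = int(offsets[-1])
    draws = rng.integers(1, total + 1, size=(iterations, n_junctions, 2))
    if len(starts):
        # global position g on chromosome i occupies (offsets[i], offsets[i+1]]
        idx = np.searchsorted(starts, draws, side="right") - 1
        inside = (idx >= 0) & (draws <= ends[np.clip(idx, 0, len(ends) - 1)])
    else:
        inside = np.zeros_like(draws, dtype=bool)
    intragenic = inside.any(axis=2)
    sim_counts = intragenic.sum(axis=1)
    p = float(np.mean(sim_counts > observed))
    return MonteCarloResult(p, observed, iterations, sim_counts)
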