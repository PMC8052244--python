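"""Mechanism-specific synthetic complex-rearrangement generator.

Each simulator produces a :class:`SimulatedTruth`: a synthetic genome,
the retained fragments, the junctions (with signature ground truth), and
the derivative chains — in exactly the dialects the analysis side
consumes, so the simulator is the fixture generator for the whole
pipeline.  Four mechanisms are modelled:

* ``chromothripsis`` — clustered cuts within one window per chromosome
  (one or a few chromosomes), fragments shuffled and rejoined in uniform
  random orientation, per-cut deletions drawn log-uniform over the
  observed germline range [1, 26 000] nt;
* ``chromoplexy`` — cuts biased into genes across several (>= 3)
  chromosomes, chained into largely balanced derivatives (deletions
  absent or < 100 nt);
* ``bfb`` — breakage-fusion-bridge cycles on one chromosome: each cycle
  breaks the chromatid, discards the acentric distal part and fuses the
  retained part to its own inverted copy, producing fold-back
  (head-to-head/tail-to-tail) junctions, duplicated segments and terminal
  loss;
* ``chromoanasynthesis`` — replicative template switching: junctions
  carry planted 2–10 nt microhomology and templated insertions copied
  from near the breakends (requires simulated sequence), plus occasional
  duplicated fragments.

Technology call sets are derived from a truth by applying a per-technology
noise profile (sensitivity, positional jitter, uniform false positives).
All outputs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model import (
    Breakend,
    CallRecord,
    CcrError,
    DerivativeChromosome,
    Fragment,
    Gene,
    GenomeModel,
    Junction,
    Orientation,
    PlacedFragment,
    Side,
    Tad,
)
from .walker import canonicalize_derivatives

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome layout: equal-length chromosomes, non-overlapping
    genes placed one per slot, TADs tiling each chromosome."""

    n_chromosomes: int = 4
    chrom_length: int = 30_000_000
    genes_per_chrom: int = 60
    gene_length: int = 100_000
    tad_size: int = 1_000_000
    with_sequences: bool = False

    @property
    def gene_coverage(self) -> float:
        return self.genes_per_chrom * self.gene_length / self.chrom_length


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_genome(spec: GenomeSpec, seed: int) -> GenomeModel:
    """Deterministically generate a genome for a seed."""
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chromosomes)]
    genes: list[Gene] = []
    if spec.genes_per_chrom:
        slot = spec.chrom_length // spec.genes_per_chrom
        if slot < spec.gene_length:
            raise CcrError(
                f"gene density infeasible: slot {slot} bp < gene length {spec.gene_length} bp"
            )
        for chrom, _ in chroms:
            for g in range(spec.genes_per_chrom):
                start = g * slot + int(rng.integers(0, slot - spec.gene_length + 1)) + 1
                genes.append(
                    Gene(f"{chrom}.g{g + 1}", chrom, start, start + spec.gene_length - 1)
                )
    tads: list[Tad] = []
    for chrom, length in chroms:
        for k, s in enumerate(range(1, length + 1, spec.tad_size)):
            tads.append(Tad(f"{chrom}.tad{k + 1}", chrom, s, min(s + spec.tad_size - 1, length)))
    sequences = None
    if spec.with_sequences:
        sequences = {chrom: _random_sequence(rng, length) for chrom, length in chroms}
    return GenomeModel(chromosomes=chroms, genes=genes, tads=tads, sequences=sequences)


# ---------------------------------------------------------------------------
# truth container


@dataclass
class SimulatedTruth:
    """Ground truth emitted by a simulator."""

    genome: GenomeModel
    fragments: list[Fragment]
    junctions: list[Junction]
    derivatives: list[DerivativeChromosome]
    mechanism: str
    has_duplications: bool
    terminal_loss: bool
    junction_truth: dict[str, dict] = field(default_factory=dict)

    @property
    def breakpoints(self) -> list[Breakend]:
        return [end for j in self.junctions for end in j.breakends]


# ---------------------------------------------------------------------------
# shared machinery


def _draw_cuts(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    n: int,
    min_sep: int = 1_000,
) -> list[int]:
    """n distinct, sorted cut positions in (lo, hi) with pairwise spacing
    >= min_sep."""
    if n == 0:
        return []
    if (hi - lo) < (n + 1) * min_sep:
        raise CcrError(
            f"cannot place {n} cuts with {min_sep} bp spacing in a "
            f"{hi - lo} bp window"
        )
    for _ in range(100):
        cuts = np.sort(rng.integers(lo + min_sep, hi - min_sep + 1, size=n))
        if len(np.unique(cuts)) == n and (n == 1 or np.diff(cuts).min() >= min_sep):
            return [int(c) for c in cuts]
    # fall back to jittered even spacing (degenerate windows)
    step = (hi - lo) // (n + 1)
    return [lo + step * (i + 1) for i in range(n)]


def _log_uniform(rng: np.random.Generator, low: int, high: int) -> int:
    return int(math.exp(rng.uniform(math.log(low), math.log(high + 1))))


def _tile(
    chrom: str, length: int, cuts: Sequence[int], deletions: Sequence[int]
) -> list[tuple[int, int]]:
    """Partition [1, length] at the cut positions, deleting ``deletions[i]``
    bases immediately after cut i (clamped to keep every fragment >= 1 bp)."""
    intervals = []
    start = 1
    for i, p in enumerate(cuts):
        intervals.append((start, p))
        nxt = cuts[i + 1] if i + 1 < len(cuts) else length
        d = min(deletions[i], nxt - p - 1)
        start = p + d + 1
    intervals.append((start, length))
    return intervals


@dataclass
class _ChainBuilder:
    """Assemble fragments, junctions and derivatives from per-chromosome
    tilings and a chain plan, keeping per-junction deletion truth."""

    rng: np.random.Generator
    fragments: dict[str, Fragment] = field(default_factory=dict)
    links: dict[tuple[str, Side], str] = field(default_factory=dict)

    def add_fragment(self, fid: str, chrom: str, start: int, end: int) -> str:
        self.fragments[fid] = Fragment(fid, chrom, start, end)
        return fid

    def _gap(self, fid: str, side: Side) -> int:
        """Outward reference gap at a fragment end, given the full retained
        set (nearest retained base beyond the end)."""
        frag = self.fragments[fid]
        if side is Side.TAIL:
            pos = frag.end
            cands = [
                max(f.start, pos + 1)
                for f in self.fragments.values()
                if f.chrom == frag.chrom and f.end > pos
            ]
            return min(cands) - pos - 1 if cands else 0
        pos = frag.start
        cands = [
            min(f.end, pos - 1)
            for f in self.fragments.values()
            if f.chrom == frag.chrom and f.start < pos
        ]
        return pos - max(cands) - 1 if cands else 0

    def build(
        self, chains: list[tuple[str, list[tuple[str, Orientation]]]]
    ) -> tuple[list[Fragment], list[Junction], list[DerivativeChromosome], dict[str, dict]]:
        """Turn chain plans [(name, [(fragment id, orientation), ...])] into
        linked model objects.  Junction signature fields are left blank here
        (deletion truth filled in); callers decorate them afterwards."""
        junctions: list[Junction] = []
        truth: dict[str, dict] = {}
        derivatives: list[DerivativeChromosome] = []
        jnum = 0
        for name, plan in chains:
            chain_junctions: list[Junction] = []
            for (fid_a, ori_a), (fid_b, ori_b) in zip(plan, plan[1:]):
                jnum += 1
                jid = f"J{jnum:03d}"
                side_a = Side.TAIL if ori_a is Orientation.FORWARD else Side.HEAD
                side_b = Side.HEAD if ori_b is Orientation.FORWARD else Side.TAIL
                self.links[(fid_a, side_a)] = jid
                self.links[(fid_b, side_b)] = jid
                gap_a = self._gap(fid_a, side_a)
                gap_b = self._gap(fid_b, side_b)
                frag_a, frag_b = self.fragments[fid_a], self.fragments[fid_b]
                # a gap flanked by both ends (reference-adjacent rejoin) counts once
                same_gap = (
                    frag_a.chrom == frag_b.chrom
                    and gap_a == gap_b
                    and side_a != side_b
                    and (
                        (side_a is Side.TAIL and frag_b.start - frag_a.end - 1 == gap_a)
                        or (side_a is Side.HEAD and frag_a.start - frag_b.end - 1 == gap_a)
                    )
                )
                deleted = gap_a if same_gap else gap_a + gap_b
                junction = Junction(
                    id=jid,
                    end_a=frag_a.breakend(side_a),
                    end_b=frag_b.breakend(side_b),
                    deleted_nt=deleted,
                )
                chain_junctions.append(junction)
                junctions.append(junction)
                truth[jid] = {
                    "deleted": deleted,
                    "microhomology": 0,
                    "insertion_len": 0,
                    "templated": False,
                }
            derivatives.append((name, plan, chain_junctions))

        # attach explicit junction linkage to the final fragment objects
        final: dict[str, Fragment] = {}
        for fid, frag in self.fragments.items():
            final[fid] = Fragment(
                fid,
                frag.chrom,
                frag.start,
                frag.end,
                junction_head=self.links.get((fid, Side.HEAD)),
                junction_tail=self.links.get((fid, Side.TAIL)),
            )
        ders = []
        for name, plan, chain_junctions in derivatives:
            chain = [
                PlacedFragment(final[fid], ori, index=i)
                for i, (fid, ori) in enumerate(plan)
            ]
            ders.append(DerivativeChromosome(name, chain, chain_junctions))
        return list(final.values()), junctions, ders, truth


def _pick_chroms(genome: GenomeModel, chroms: Union[int, Sequence[str]]) -> list[str]:
    if isinstance(chroms, int):
        names = [c for c, _ in genome.chromosomes][:chroms]
        if len(names) < chroms:
            raise CcrError(f"genome has only {len(names)} chromosomes, need {chroms}")
        return names
    known = genome.lengths
    for c in chroms:
        if c not in known:
            raise CcrError(f"unknown chromosome {c}")
    return list(chroms)


def _split_breaks(n_breaks: int, k: int) -> list[int]:
    base, extra = divmod(n_breaks, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _shuffled_assembly(
    rng: np.random.Generator,
    tilings: dict[str, list[tuple[int, int]]],
    uniform_orientation: bool = True,
) -> list[tuple[str, list[tuple[str, Orientation]]]]:
    """Chain plans: each derivative keeps its chromosome's first fragment
    (with the low-coordinate telomere) and ends with some chromosome's last
    fragment; interior fragments are pooled, shuffled and dealt uniformly."""
    chroms = sorted(tilings)
    interior: list[str] = []
    first: dict[str, str] = {}
    last: dict[str, str] = {}
    for chrom in chroms:
        n = len(tilings[chrom])
        ids = [f"{chrom}.F{i + 1:03d}" for i in range(n)]
        first[chrom] = ids[0]
        last[chrom] = ids[-1]
        interior.extend(ids[1:-1])
    order = rng.permutation(len(interior))
    assignment = rng.integers(0, len(chroms), size=len(interior))
    perm = rng.permutation(len(chroms))
    chains = []
    for ci, chrom in enumerate(chroms):
        plan: list[tuple[str, Orientation]] = [(first[chrom], Orientation.FORWARD)]
        for pos in order:
            if assignment[pos] == ci:
                fid = interior[pos]
                ori = (
                    Orientation.FORWARD
                    if (not uniform_orientation or rng.random() < 0.5)
                    else Orientation.REVERSE
                )
                plan.append((fid, ori))
        plan.append((last[chroms[perm[ci]]], Orientation.FORWARD))
        chains.append((f"der({chrom})", plan))
    return chains


def _fragment_ids_to_builder(
    builder: _ChainBuilder, tilings: dict[str, list[tuple[int, int]]]
) -> None:
    for chrom in sorted(tilings):
        for i, (s, e) in enumerate(tilings[chrom]):
            builder.add_fragment(f"{chrom}.F{i + 1:03d}", chrom, s, e)


def _decorate_junction(
    junction: Junction,
    inserted_seq: str = "",
    microhomology: int = 0,
    templated: bool = False,
) -> Junction:
    return Junction(
        id=junction.id,
        end_a=junction.end_a,
        end_b=junction.end_b,
        inserted_seq=inserted_seq,
        microhomology_len=microhomology,
        deleted_nt=junction.deleted_nt,
        templated=templated,
    )


def _apply_signatures(
    rng: np.random.Generator,
    junctions: list[Junction],
    truth: dict[str, dict],
    insertion_prob: float,
    microhomology_prob: float,
    mh_sizes: Sequence[int] = (1, 1, 2, 3, 4),
    ins_len_bounds: tuple[int, int] = (1, 300),
) -> list[Junction]:
    """Assign blunt-repair-style signature fields (non-templated insertions,
    short microhomology) without sequence backing."""
    out = []
    for j in junctions:
        r = rng.random()
        if r < insertion_prob:
            length = _log_uniform(rng, *ins_len_bounds)
            seq = _random_sequence(rng, length)
            out.append(_decorate_junction(j, inserted_seq=seq))
            truth[j.id].update(insertion_len=length, templated=False)
        elif r < insertion_prob + microhomology_prob:
            m = int(rng.choice(mh_sizes))
            out.append(_decorate_junction(j, microhomology=m))
            truth[j.id].update(microhomology=m)
        else:
            out.append(j)
    return out


def _replace_junctions(
    derivatives: list[DerivativeChromosome], junctions: list[Junction]
) -> None:
    by_id = {j.id: j for j in junctions}
    for der in derivatives:
        der.junctions = [by_id[j.id] for j in der.junctions]


# ---------------------------------------------------------------------------
# chromothripsis


def simulate_chromothripsis(
    genome: GenomeModel,
    chroms: Union[int, Sequence[str]] = 2,
    n_breaks: int = 40,
    seed: int = 0,
    cluster_window: int = 2_000_000,
    deletion_prob: float = 0.64,
    deletion_bounds: tuple[int, int] = (1, 26_000),
    insertion_prob: float = 0.35,
    microhomology_prob: float = 0.30,
) -> SimulatedTruth:
    """Localized shattering with random rejoining.

    Cuts are confined to one random window per chromosome; fragments are
    shuffled uniformly with uniform orientation; each cut deletes
    (probability ``deletion_prob``) a log-uniform number of nucleotides.
    """
    rng = np.random.default_rng(seed)
    names = _pick_chroms(genome, chroms)
    if len(names) > 3:
        raise CcrError("chromothripsis is localized to one or a few (< 4) chromosomes")
    if n_breaks < len(names):
        raise CcrError("need at least one break per involved chromosome")
    lengths = genome.lengths
    tilings: dict[str, list[tuple[int, int]]] = {}
    for chrom, n_c in zip(names, _split_breaks(n_breaks, len(names))):
        length = lengths[chrom]
        window = min(cluster_window, length - 2)
        if n_c * 1_000 > window:
            raise CcrError(
                f"{n_c} breaks exceed the capacity of a {window} bp cluster window"
            )
        wstart = int(rng.integers(1, length - window))
        cuts = _draw_cuts(rng, wstart, wstart + window, n_c)
        deletions = [
            _log_uniform(rng, *deletion_bounds) if rng.random() < deletion_prob else 0
            for _ in cuts
        ]
        tilings[chrom] = _tile(chrom, length, cuts, deletions)
    builder = _ChainBuilder(rng)
    _fragment_ids_to_builder(builder, tilings)
    chains = _shuffled_assembly(rng, tilings)
    fragments, junctions, derivatives, truth = builder.build(chains)
    junctions = _apply_signatures(rng, junctions, truth, insertion_prob, microhomology_prob)
    _replace_junctions(derivatives, junctions)
    derivatives = canonicalize_derivatives(derivatives)
    junctions = [j for d in derivatives for j in d.junctions]
    return SimulatedTruth(
        genome, fragments, junctions, derivatives, "chromothripsis",
        has_duplications=False, terminal_loss=False, junction_truth=truth,
    )


# ---------------------------------------------------------------------------
# chromoplexy


def simulate_chromoplexy(
    genome: GenomeModel,
    chroms: Union[int, Sequence[str]] = 4,
    n_breaks: int = 60,
    seed: int = 0,
    intragenic_bias: float = 0.9,
    deletion_prob: float = 0.5,
    max_deletion: int = 100,
    insertion_prob: float = 0.35,
    microhomology_prob: float = 0.30,
) -> SimulatedTruth:
    """Chained, largely balanced rearrangement across several chromosomes
    with gene-biased breakpoints.

    Each cut falls inside a random gene with probability ``intragenic_bias``
    (else uniform); deletions are absent or small (<= ``max_deletion`` nt);
    fragment orientation is uniform.
    """
    rng = np.random.default_rng(seed)
    names = _pick_chroms(genome, chroms)
    if len(names) < 3:
        raise CcrError("chromoplexy involves several (> 2) chromosomes")
    if n_breaks < len(names):
        raise CcrError("need at least one break per involved chromosome")
    lengths = genome.lengths
    genes_by_chrom = {c: [g for g in genome.genes if g.chrom == c] for c in names}
    tilings: dict[str, list[tuple[int, int]]] = {}
    for chrom, n_c in zip(names, _split_breaks(n_breaks, len(names))):
        length = lengths[chrom]
        genes = genes_by_chrom[chrom]
        cuts: set[int] = set()
        attempts = 0
        while len(cuts) < n_c and attempts < 100 * max(n_c, 1):
            attempts += 1
            if genes and rng.random() < intragenic_bias:
                g = genes[int(rng.integers(0, len(genes)))]
                pos = int(rng.integers(g.start, g.end + 1))
            else:
                pos = int(rng.integers(2, length - 1))
            if all(abs(pos - c) >= 1_000 for c in cuts):
                cuts.add(pos)
        if len(cuts) < n_c:
            raise CcrError(f"could not place {n_c} spaced cuts on {chrom}")
        sorted_cuts = sorted(cuts)
        deletions = [
            int(rng.integers(1, max_deletion + 1)) if rng.random() < deletion_prob else 0
            for _ in sorted_cuts
        ]
        tilings[chrom] = _tile(chrom, length, sorted_cuts, deletions)
    builder = _ChainBuilder(rng)
    _fragment_ids_to_builder(builder, tilings)
    chains = _shuffled_assembly(rng, tilings)
    fragments, junctions, derivatives, truth = builder.build(chains)
    junctions = _apply_signatures(rng, junctions, truth, insertion_prob, microhomology_prob)
    _replace_junctions(derivatives, junctions)
    derivatives = canonicalize_derivatives(derivatives)
    junctions = [j for d in derivatives for j in d.junctions]
    return SimulatedTruth(
        genome, fragments, junctions, derivatives, "chromoplexy",
        has_duplications=False, terminal_loss=False, junction_truth=truth,
    )


# ---------------------------------------------------------------------------
# breakage-fusion-bridge


def simulate_bfb(
    genome: GenomeModel,
    chrom: Optional[str] = None,
    n_cycles: int = 12,
    seed: int = 0,
) -> SimulatedTruth:
    """Breakage-fusion-bridge cycles on one chromosome.

    Each cycle breaks the current chromatid at a random position, discards
    the acentric distal part, and fuses the retained part to its own
    inverted copy, adding one fold-back (head-to-head or tail-to-tail)
    junction and one truncated inverted duplicate of the trailing segment.
    The distal telomere is lost in the first break.
    """
    if n_cycles < 1:
        raise CcrError("BFB requires at least one cycle")
    rng = np.random.default_rng(seed)
    chrom = chrom or genome.chromosomes[0][0]
    length = genome.lengths[chrom]
    retain_low = bool(rng.random() < 0.5)
    p0 = int(rng.integers(length // 4, 3 * length // 4))
    builder = _ChainBuilder(rng)
    plan: list[tuple[str, Orientation]] = []
    if retain_low:
        fid = builder.add_fragment(f"{chrom}.F001", chrom, 1, p0)
        plan.append((fid, Orientation.FORWARD))
        lo, hi = 1, p0
    else:
        fid = builder.add_fragment(f"{chrom}.F001", chrom, p0, length)
        plan.append((fid, Orientation.REVERSE))
        lo, hi = p0, length
    cycles_done = 0
    for cycle in range(n_cycles):
        if hi - lo < 4:
            break  # chromatid too short for another informative break
        last_fid, last_ori = plan[-1]
        frag = builder.fragments[last_fid]
        new_fid = f"{chrom}.F{len(plan) + 1:03d}"
        # break within the distal 5-30% of the mirrored trailing segment:
        # the surviving chromatid keeps its centromere-proximal bulk, which
        # also keeps deep cycle counts representable without degenerating
        span = hi - lo
        retained = max(2, int(span * rng.uniform(0.70, 0.95)))
        if last_ori is Orientation.FORWARD:
            # trailing native tail at frag.end: tail-to-tail fold-back
            q = max(lo + 1, frag.end - retained + 1)
            builder.add_fragment(new_fid, chrom, q, frag.end)
            plan.append((new_fid, Orientation.REVERSE))
            lo, hi = q, frag.end
        else:
            # trailing native head at frag.start: head-to-head fold-back
            q = min(hi - 1, frag.start + retained - 1)
            builder.add_fragment(new_fid, chrom, frag.start, q)
            plan.append((new_fid, Orientation.FORWARD))
            lo, hi = frag.start, q
        cycles_done += 1
    fragments, junctions, derivatives, truth = builder.build(
        [(f"der({chrom})", plan)]
    )
    derivatives = canonicalize_derivatives(derivatives)
    junctions = [j for d in derivatives for j in d.junctions]
    return SimulatedTruth(
        genome, fragments, junctions, derivatives, "bfb",
        has_duplications=cycles_done > 0, terminal_loss=True, junction_truth=truth,
    )


# ---------------------------------------------------------------------------
# chromoanasynthesis (replicative)


def simulate_chromoanasynthesis(
    genome: GenomeModel,
    chroms: Union[int, Sequence[str]] = 2,
    n_breaks: int = 30,
    seed: int = 0,
    microhomology_sizes: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
    microhomology_prob: float = 0.7,
    insertion_prob: float = 0.25,
    templated_prob: float = 0.5,
    duplication_prob: float = 0.1,
    deletion_bounds: tuple[int, int] = (21, 5_000),
    ins_len_bounds: tuple[int, int] = (10, 120),
) -> SimulatedTruth:
    """Replicative (template-switching) rearrangement with sequence-level
    ground truth.

    Junction microhomology is *planted* into the genome sequence (the
    reference continuation of the upstream end is overwritten with the
    first bases of the downstream segment, with forced mismatches at both
    scan boundaries), so the analysis-side scan recovers exactly the
    planted length.  Templated insertions are copied from retained sequence
    within 500 bp of a breakend (possibly reverse-complemented).  Every cut
    deletes >= 21 nt so the planted flanks live in unretained sequence.
    Some fragments are duplicated (used twice across the derivatives).
    """
    if genome.sequences is None:
        raise CcrError("chromoanasynthesis simulation requires genome sequences")
    rng = np.random.default_rng(seed)
    names = _pick_chroms(genome, chroms)
    if n_breaks < len(names):
        raise CcrError("need at least one break per involved chromosome")
    lengths = genome.lengths
    tilings: dict[str, list[tuple[int, int]]] = {}
    for chrom, n_c in zip(names, _split_breaks(n_breaks, len(names))):
        length = lengths[chrom]
        cuts = _draw_cuts(rng, 1, length - 1, n_c, min_sep=max(2 * deletion_bounds[1], 2_000))
        deletions = [int(rng.integers(*deletion_bounds)) for _ in cuts]
        tilings[chrom] = _tile(chrom, length, cuts, deletions)

    builder = _ChainBuilder(rng)
    _fragment_ids_to_builder(builder, tilings)
    chains = _shuffled_assembly(rng, tilings, uniform_orientation=False)
    # duplicate some interior fragments: insert a second copy elsewhere
    interior = [
        fid
        for _, plan in chains
        for fid, _ in plan[1:-1]
    ]
    for fid in interior:
        if rng.random() < duplication_prob:
            src = builder.fragments[fid]
            dup_id = f"{fid}.d"
            builder.add_fragment(dup_id, src.chrom, src.start, src.end)
            ci = int(rng.integers(0, len(chains)))
            name, plan = chains[ci]
            slot = int(rng.integers(1, len(plan)))
            plan.insert(slot, (dup_id, Orientation.FORWARD))
    fragments, junctions, derivatives, truth = builder.build(chains)

    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    edits: dict[tuple[str, int], int] = {}  # (chrom, 0-based pos) -> byte

    def _set_equal(chrom: str, pos0: int, value: int) -> bool:
        key = (chrom, pos0)
        if key in edits and edits[key] != value:
            return False
        edits[key] = value
        seqs[chrom][pos0] = value
        return True

    def _set_different(chrom: str, pos0: int, avoid: int) -> bool:
        key = (chrom, pos0)
        if key in edits:
            return edits[key] != avoid
        current = seqs[chrom][pos0]
        value = current
        for b in b"ACGT":
            if b != avoid:
                value = b
                break
        if current != avoid:
            value = current
        edits[key] = value
        seqs[chrom][pos0] = value
        return True

    frag_by_id = {f.id: f for f in fragments}
    gaps_right: dict[str, int] = {}
    gaps_left: dict[str, int] = {}
    for chrom, tiling in tilings.items():
        for i, (s, e) in enumerate(tiling):
            fid = f"{chrom}.F{i + 1:03d}"
            if i + 1 < len(tiling):
                gaps_right[fid] = tiling[i + 1][0] - e - 1
            if i > 0:
                gaps_left[fid] = s - tiling[i - 1][1] - 1
    for fid in list(gaps_right):
        if f"{fid}.d" in frag_by_id:
            gaps_right[f"{fid}.d"] = gaps_right[fid]
    for fid in list(gaps_left):
        if f"{fid}.d" in frag_by_id:
            gaps_left[f"{fid}.d"] = gaps_left[fid]

    def _plant_microhomology(junction: Junction, m: int) -> bool:
        up, down = junction.end_a, junction.end_b  # tail@p -> head@s, both forward
        p, s = up.pos, down.pos
        ca, cb = up.chrom, down.chrom
        if gaps_right.get(_fid_of_end(junction, "a"), 0) < m + 1:
            return False
        if gaps_left.get(_fid_of_end(junction, "b"), 0) < 1:
            return False
        if p + m >= len(seqs[ca]) or s - 1 + m >= len(seqs[cb]) or s < 2 or p < 1:
            return False
        for i in range(m):
            if not _set_equal(ca, p + i, seqs[cb][s - 1 + i]):
                return False
        if not _set_different(ca, p + m, seqs[cb][s - 1 + m]):
            return False
        if not _set_different(cb, s - 2, seqs[ca][p - 1]):
            return False
        return True

    end_owner: dict[str, tuple[str, str]] = {}
    for der in derivatives:
        for (up, down), j in zip(zip(der.chain, der.chain[1:]), der.junctions):
            end_owner[j.id] = (up.fragment.id, down.fragment.id)

    def _fid_of_end(junction: Junction, which: str) -> str:
        a, b = end_owner[junction.id]
        return a if which == "a" else b

    decorated: list[Junction] = []
    for j in junctions:
        r = rng.random()
        if r < insertion_prob:
            length = int(rng.integers(*ins_len_bounds))
            templated = bool(rng.random() < templated_prob)
            seq = None
            if templated:
                # copy retained sequence within 500 bp of the upstream breakend
                frag = frag_by_id[_fid_of_end(j, "a")]
                max_off = min(500 - length, frag.end - frag.start + 1 - length)
                if max_off >= 1:
                    off = int(rng.integers(1, max_off + 1))
                    hi0 = j.end_a.pos - off  # 1-based inclusive end of source
                    seq = bytes(seqs[frag.chrom][hi0 - length : hi0]).decode("ascii")
                    if rng.random() < 0.5:
                        from .signatures import reverse_complement

                        seq = reverse_complement(seq)
            if seq is None:
                templated = False
                seq = _random_sequence(rng, length)
            decorated.append(_decorate_junction(j, inserted_seq=seq, templated=templated))
            truth[j.id].update(insertion_len=length, templated=templated)
        elif r < insertion_prob + microhomology_prob:
            m = int(rng.choice(list(microhomology_sizes)))
            if _plant_microhomology(j, m):
                decorated.append(_decorate_junction(j, microhomology=m))
                truth[j.id].update(microhomology=m)
            else:
                decorated.append(j)
        else:
            decorated.append(j)
    _replace_junctions(derivatives, decorated)
    derivatives = canonicalize_derivatives(derivatives)
    decorated = [j for d in derivatives for j in d.junctions]
    genome = GenomeModel(
        chromosomes=genome.chromosomes,
        genes=genome.genes,
        tads=genome.tads,
        sequences={c: s.decode("ascii") for c, s in seqs.items()},
    )
    has_dup = any(f.id.endswith(".d") for f in fragments)
    return SimulatedTruth(
        genome, fragments, decorated, derivatives, "chromoanasynthesis",
        has_duplications=has_dup, terminal_loss=False, junction_truth=truth,
    )


# ---------------------------------------------------------------------------
# technology noise


@dataclass(frozen=True)
class TechnologyProfile:
    """Per-technology call noise: detection probability per truth junction,
    positional jitter (sd, bp) on both breakends, and uniform false
    positives per megabase of genome."""

    name: str
    sensitivity: float
    jitter_sd: float
    fp_per_mbp: float


#: rough profiles for the four compared technologies (sensitivities from
#: their observed 132-junction detection rates; call volumes per genome Mbp)
TECHNOLOGY_PROFILES = {
    "illumina_pe": TechnologyProfile("illumina_pe", 0.90, 50, 1.6),
    "nanopore": TechnologyProfile("nanopore", 0.91, 100, 4.8),
    "linked_reads": TechnologyProfile("linked_reads", 0.66, 200, 0.6),
    "optical_mapping": TechnologyProfile("optical_mapping", 0.14, 5_000, 3.9),
}


def make_noisy_callset(
    truth: SimulatedTruth,
    profile: TechnologyProfile,
    seed: int = 0,
) -> list[CallRecord]:
    """Degrade a truth junction set into a technology call set."""
    if not (0.0 <= profile.sensitivity <= 1.0):
        raise CcrError("sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = truth.genome.lengths
    calls: list[CallRecord] = []
    for j in truth.junctions:
        if rng.random() >= profile.sensitivity:
            continue
        ends = []
        for end in j.breakends:
            jitter = int(round(rng.normal(0.0, profile.jitter_sd))) if profile.jitter_sd else 0
            pos = min(max(end.pos + jitter, 1), lengths[end.chrom])
            ends.append(Breakend(end.chrom, pos, end.side))
        calls.append(CallRecord(profile.name, ends[0], ends[1]))
    genome_mbp = sum(lengths.values()) / 1e6
    n_fp = int(rng.poisson(profile.fp_per_mbp * genome_mbp))
    chroms = sorted(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_fp):
        ends = []
        for _ in range(2):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(1, lengths[chrom] + 1))
            side = Side.TAIL if rng.random() < 0.5 else Side.HEAD
            ends.append(Breakend(chrom, pos, side))
        calls.append(CallRecord(profile.name, ends[0], ends[1]))
    return calls


# ---------------------------------------------------------------------------
# dispatch


_SIMULATORS = {
    "chromothripsis": simulate_chromothripsis,
    "chromoplexy": simulate_chromoplexy,
    "bfb": simulate_bfb,
    "chromoanasynthesis": simulate_chromoanasynthesis,
}


def simulate(mechanism: str, genome: GenomeModel, seed: int, **params) -> SimulatedTruth:
    """Run the named mechanism simulator with its default study conditions."""
    try:
        fn = _SIMULATORS[mechanism]
    except KeyError:
        raise CcrError(
            f"unknown mechanism {mechanism!r}; choose from {sorted(_SIMULATORS)}"
        ) from None
    return fn(genome, seed=seed, **params)
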