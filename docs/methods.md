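# Methods

## Coordinate model

All internal coordinates are 1-based inclusive (VCF convention); BED,
bedpe and other 0-based half-open inputs are converted at the parse
boundary, so a bedpe *end* column equals the internal position. A
fragment `[start, end]` has a **head** at `start` (retained sequence
extends toward higher coordinates) and a **tail** at `end` (retained
sequence extends toward lower coordinates); a reference-collinear fusion
is tail-to-head. In bedpe, strand `+` encodes the tail side and `-` the
head side on both breakends, matching common SV bedpe practice (a simple
deletion is `+`/`-`). VCF breakend brackets map as: `t[p[` tail→head,
`t]p]` tail→tail, `]p]t` head→tail, `[p[t` head→head.

Microhomology and insertion are stored as mutually exclusive on a
junction — an inserted sequence separates the joined segments, so the
breakpoint cannot simultaneously be placement-ambiguous — and a junction
carrying both is rejected at load time.

## Derivative reconstruction (the walker)

Every non-terminal fragment carries exactly two junctions, one per native
end, so fragments form linear chains. The walker enters a fragment
through one end (head ⇒ forward placement, tail ⇒ reverse), exits through
the other, and follows the junction attached there; chains terminate at
fragments with a free end (telomere-bearing). Junction breakends are
attached to fragment ends either by the explicit
`junction_id_head`/`junction_id_tail` references of the fragment table or,
for bare junction lists, by coordinate matching with a configurable
tolerance (default **0 bp**: curated tables are exact; raw caller output
may need slack). Explicit references are required for fold-back
junctions, whose two breakends share the same coordinates and side and
are therefore ambiguous under coordinate matching.

Reconstruction starts, deterministically, at the free end whose
(chromosome, position, fragment id, side) key is lexicographically
smallest among the remaining terminal fragments, removing each walked
chain before choosing the next start; the simulators canonicalise their
truth chains with the same rule so recovery can be asserted exactly.
Cycles are an error, never silently broken: germline derivative
chromosomes are linear. Walking a chain from its other end yields the
reversed chain with all orientations flipped and each junction read in
the opposite direction (breakends exchanged); all junction signature
measurements are symmetric under that reversal.

## Junction signatures

**Microhomology** is the width of the interval of breakpoint shifts that
produce the identical junction sequence: the maximal k for which the
first k retained downstream bases equal the upstream reference
continuation, plus the symmetric upstream extension. Both flanks are
scanned over a **20 nt** window (germline junctions rarely exceed a few
nucleotides; 20 gives headroom), passed as equal-length strings with the
break at their midpoint; a brute-force shift-enumeration oracle verifies
the scan in the tests. The symmetric (two-sided) ambiguity range is a
declared definition, since breakpoint tables rarely state whether
one-sided or symmetric ranges were used.

**Insertions** are *templated* when a substring of length ≥ 20 nt — or
the full insertion, for insertions shorter than 20 nt — occurs exactly,
or reverse-complemented, within **500 bp** of either breakend. The
window is a declared default surfaced as a parameter; for random flanks
the false-templating probability of a 20-mer is bounded by ~2 kb·4⁻²⁰.

**Deletion** at a junction is the distance from each fused fragment end
to the nearest retained base of the adjacent reference segment, with a
gap flanked by both breakends (a reference-adjacent rejoin) counted once;
a balanced junction deletes nothing. Overlapping retained intervals
(duplications) contribute retained bases like any other fragment.

Summaries bin deletions as balanced / 1–9 / 10–99 / 100–999 /
1,000–9,999 / ≥ 10,000 nt, microhomology as 1 / 2–10 (plus a >10 bin so
the partition is exhaustive) and insertions as 1 / 2–19 / 20–99 / ≥ 100
nt; these half-open edges make the bins mutually exclusive and their
counts sum to the totals. Percentages are rounded half-up to integers,
as such tables are conventionally printed.

## Rearrangement statistics

All binomial tests are **exact one-sided tails** (cumulative sums of
point probabilities, via `scipy.stats.binom`; an independent brute-force
summation oracle checks them to 10⁻¹² for n ≤ 200). The direction is
chosen toward the observed deviation; at k exactly equal to n·p₀ the
lower tail is used. No normal approximation and no multiple-testing
correction are applied — cells report raw per-cell p-values.

* *Fragment distribution*: for origin chromosome o and derivative d,
  k = fragments of o placed on d, n = all fragments of o,
  p₀ = 1/#derivatives.
* *Orientation*: adjacent placements classify as tail-to-head
  (forward→forward), head-to-tail (reverse→reverse), tail-to-tail
  (forward→reverse) or head-to-head (reverse→forward); each class is
  tested with n = the derivative's junction count and p₀ = 1/4. The
  trial count is the junction count, not the fragment count — with k
  fragments a chain has k−1 fusions, and only that choice makes the
  class counts sum to n.
* *Fold-back enrichment* (the breakage-fusion-bridge screen):
  k = head-to-head + tail-to-tail, p₀ = 1/2, direction per the rule
  above.
* *Intragenic enrichment*: a junction is intragenic when either breakend
  lies inside any gene (inclusive bounds). The Monte Carlo test redraws
  the same number of junctions with both breakends uniform over the
  concatenated involved chromosomes (every base equally likely) and
  reports p = fraction of iterations whose intragenic count **strictly
  exceeds** the observed count, with no pseudocount — the minimum
  reportable p is 0 and is then printed as "p < 1/iterations". Draws
  use one seeded generator; results are bit-reproducible for a given
  (seed, iterations). Because the statistic is discrete and the
  inequality strict, the null p-value is uniform only up to discreteness;
  the calibration test therefore checks the mid-p variant
  (p + ½·P(tie)) against uniformity.

The intervaltree-backed point queries serve the general (possibly
overlapping) gene sets; the Monte Carlo inner loop instead vectorises
membership over merged intervals with numpy searchsorted, which is what
makes 1000 iterations on hundreds of junctions instantaneous.

## Mechanism decision table

The classifier turns narrative mechanism signatures into explicit,
testable criteria over a deterministic feature vector (involved
chromosome count; duplications, detected as overlapping placed intervals;
templated-insertion and 2–10 nt microhomology fractions; fraction of
junctions deleting < 1 kbp; fold-back and intragenic p-values; a
breakpoint-cluster dispersion statistic — the variance-to-mean ratio of
per-1-Mbp-window breakpoint counts on the involved chromosomes; terminal
loss, i.e. an involved chromosome whose first or last base is retained
nowhere):

| mechanism | criteria |
|---|---|
| BFB | fold-back p < α; terminal loss |
| chromothripsis | dispersion > 5; ≤ 3 chromosomes; no duplications |
| replicative (chromoanasynthesis/FoSTeS/MMBIR) | duplications or templated insertions; 2–10 nt microhomology fraction ≥ 0.2 |
| chromoplexy | intragenic p < α; deletion-< 1 kbp fraction ≥ 0.8; > 2 chromosomes |

with α = 0.05. Each mechanism scores satisfied − violated criteria; the
verdict is the argmax, ties reported as ties. The thresholds are
package constants surfaced in the module — a formalization chosen here,
not field-standard prescriptions. Chromoanasynthesis and generic
replicative error are merged into one category because their
junction-level signatures coincide (templated insertions and
microhomology can occur without detectable duplications).

## TAD intersection

Breakpoints are assigned by point containment after BED conversion; a
breakpoint increments **every** containing TAD, so nested or overlapping
domains are multi-assigned. Genes count in a TAD at ≥ 1 bp overlap. A
junction *bridges* TADs when its breakends share no containing TAD; one
end inside and one end outside all TADs counts as bridging, both ends
outside does not.

## Call-set benchmarking

A call represents a truth junction when both breakend positions are
within 100 kbp (default) of the junction's positions on the matching
chromosome pair; both pairings of call ends to junction ends are tried
and the better kept. A call near several junctions is assigned only to
the closest — minimal **sum** of the two end distances, ties broken by
junction id for determinism ("closest" needed a metric; the sum is the
declared one). Calls are not consumed: the benchmark counts detected
truth junctions, not one-to-one pairings. Orientation is ignored during
matching (distance only).

## Meiotic segregation

Only alternate/adjacent-I-style two-choice segregation is modelled: each
involved homolog pair contributes its normal or its derivative
chromosome; a gamete is balanced iff every rearrangement's chromosomes
travel homogeneously. With g independent rearrangements over c
chromosomes this gives 2^c gametes, 2^g balanced — the enumeration is
checked against this closed form for all configurations up to 10
chromosomes. 3:1 segregation and recombination within the multivalent
are out of scope, as is viability modelling of unbalanced gametes.

## The simulator: what it emulates, and what it does not

The default genome is 4 × 30 Mbp chromosomes with 60 non-overlapping
100-kbp genes each (20% genic fraction, the order of magnitude of coding
plus proximal regulatory sequence) and 1-Mbp TADs tiling each
chromosome. Sequence (uniform random nucleotides) is generated only
when a simulation needs it, on a smaller 2 × 2 Mbp genome.

* **Chromothripsis** — cuts confined to one random 2-Mbp window per
  chromosome (≤ 3 chromosomes, default 2, 40 breaks), fragments shuffled
  and dealt uniformly among the derivatives with uniform orientation.
  64% of cuts delete a log-uniform [1, 26 000] nt gap — the observed
  germline deletion frequency and range for junctions of this kind.
  Junctions additionally receive blunt-repair-style annotations
  (non-templated insertions with probability 0.35, otherwise 1–4 nt
  microhomology with probability 0.30), mirroring reported junction
  tables.
* **Chromoplexy** — cuts across ≥ 3 chromosomes (default 4, 60 breaks),
  each falling inside a random gene with probability 0.9 (else uniform);
  deletions absent or 1–100 nt (probability 0.5), so derivatives are
  largely balanced.
* **BFB** — per-chromatid cycles without sister-chromatid dynamics: each
  cycle breaks the chromatid, discards the acentric part and fuses the
  retained part to its own truncated inverted copy, adding exactly one
  fold-back junction and one duplicated segment per cycle. The break is
  drawn in the distal 5–30% of the mirrored trailing segment so that the
  surviving chromatid keeps its centromere-proximal bulk and deep cycle
  counts (25+) remain representable on a 30-Mbp chromosome. Orientation
  signature, terminal loss and duplications — the features the
  classifier tests — are unaffected by this restriction.
* **Chromoanasynthesis (replicative)** — all-forward chains over 2
  chromosomes with ≥ 21 nt deletions at every cut, so the planted
  features live in unretained sequence: junction microhomology (2–10 nt,
  probability 0.7 of non-insertion junctions) is written into the genome
  by overwriting the upstream continuation with the downstream start and
  forcing mismatches at both scan boundaries, so the analysis-side scan
  recovers exactly the planted length; insertions (probability 0.25) are
  templated with probability 0.5, copied — possibly reverse-complemented
  — from retained sequence within 500 bp of the upstream breakend;
  some fragments are duplicated (probability 0.1).

Technology call sets degrade a truth junction set with per-technology
sensitivity, Gaussian positional jitter and uniform false positives.
The four built-in profiles take their sensitivities from the observed
per-technology detection rates of a 132-junction germline CCR
(short-read 0.90, long-read 0.91, linked-read 0.66, optical 0.14) and
their call volumes from the corresponding genome-wide call counts.

Not emulated: read-level data (no FASTQ/BAM), reference repeat
structure (flanks are uniform random, so repeat-mediated false
microhomology is rarer than in real genomes), replication-timing or 3D
contact–informed breakpoint placement, and copy-number profiles. Tests
passing on the simulator therefore validate the pipeline's bookkeeping
and statistics, not caller performance on real sequencing artefacts.

## Problem sizes and determinism

The bundled analyses and the test suite run on the default simulator
conditions above (40–60 breaks per rearrangement, 200 seeded replicates
for walker-recovery and classifier-accuracy properties, 1000 Monte Carlo
iterations in the drivers, 300 in replicated property tests) — sizes
chosen so a full run completes in seconds on one CPU while keeping every
binomial count large enough for the statistics to be informative. Every
stochastic component takes an explicit seed and is bit-reproducible;
changing the seed changes the output (checked).

## Known limitations

* Junction annotations in the sequence-free simulators (chromothripsis,
  chromoplexy, BFB) are declared fields, not measurable from flanks.
* The deletion measure can attribute one reference gap to two different
  junctions when the two ends flanking that gap are fused into different
  partners; per-junction deletions then sum to more than the total
  deleted sequence. The simulators' truth bookkeeping uses the same
  convention, so recovery tests are consistent.
* The decision table is a formalization with declared thresholds; on
  rearrangements with weakly separated features it reports ties rather
  than forcing a verdict.
* Derivative naming after reconstruction follows the deterministic
  walk-start rule, which may name a chain after the chromosome of its
  lexicographically smallest terminal fragment rather than its
  centromere.
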