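import pytest

from ccrkit.model import Breakend, Fragment, Junction, Side
from ccrkit.simulate import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def genome():
    """Default synthetic genome: 4 x 30 Mbp chromosomes, 20% gene coverage,
    1 Mbp TAD tiling, no sequence."""
    return make_genome(GenomeSpec(), seed=1)


@pytest.fixture(scope="session")
def seq_genome():
    """Small sequence-bearing genome for nucleotide-level simulations."""
    return make_genome(
        GenomeSpec(
            n_chromosomes=2,
            chrom_length=2_000_000,
            genes_per_chrom=20,
            gene_length=20_000,
            with_sequences=True,
        ),
        seed=5,
    )


def make_chain(specs, prefix="J"):
    """Build a linear chain of fragments from (id, chrom, start, end) tuples,
    joined collinearly (tail-to-head) with explicit junction linkage.
    Returns (fragments, junctions)."""
    fragments = []
    junctions = []
    for i, (fid, chrom, start, end) in enumerate(specs):
        head = f"{prefix}{i}" if i > 0 else None
        tail = f"{prefix}{i + 1}" if i + 1 < len(specs) else None
        fragments.append(
            Fragment(fid, chrom, start, end, junction_head=head, junction_tail=tail)
        )
    for i in range(len(specs) - 1):
        up, down = fragments[i], fragments[i + 1]
        junctions.append(
            Junction(
                f"{prefix}{i + 1}",
                Breakend(up.chrom, up.end, Side.TAIL),
                Breakend(down.chrom, down.start, Side.HEAD),
            )
        )
    return fragments, junctions
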