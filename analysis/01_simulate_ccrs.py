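#!/usr/bin/env python
"""Generate the synthetic study cohort: one complex rearrangement per
formation mechanism.

Writes, under results/sim/<mechanism>/: the fragment table (the pipeline's
primary input), the confirmed-junction truth bedpe, gene and TAD BED
files, technology call-set VCFs degraded with the four built-in noise
profiles, and (for the replicative case) the genome FASTA.
"""

import argparse
import json
from pathlib import Path

from ccrkit.io import (
    write_bed,
    write_bedpe,
    write_fasta,
    write_fragment_table,
    write_vcf_bnd,
)
from ccrkit.simulate import (
    GenomeSpec,
    TECHNOLOGY_PROFILES,
    make_genome,
    make_noisy_callset,
    simulate,
)

MECHANISMS = ("chromothripsis", "chromoplexy", "bfb", "chromoanasynthesis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/sim"))
    args = parser.parse_args()

    genome = make_genome(GenomeSpec(), seed=args.seed)
    seq_genome = make_genome(
        GenomeSpec(n_chromosomes=2, chrom_length=2_000_000, genes_per_chrom=20,
                   gene_length=20_000, with_sequences=True),
        seed=args.seed + 1,
    )
    for mechanism in MECHANISMS:
        g = seq_genome if mechanism == "chromoanasynthesis" else genome
        truth = simulate(mechanism, g, seed=args.seed)
        outdir = args.out / mechanism
        outdir.mkdir(parents=True, exist_ok=True)
        write_fragment_table(truth.derivatives, outdir / "fragments.tsv")
        write_bedpe(truth.junctions, outdir / "truth.bedpe")
        write_bed(
            [(x.chrom, x.start, x.end, x.name) for x in truth.genome.genes],
            outdir / "genes.bed",
        )
        write_bed(
            [(t.chrom, t.start, t.end, t.id) for t in truth.genome.tads],
            outdir / "tads.bed",
        )
        (outdir / "genome.sizes").write_text(
            "".join(f"{c}\t{L}\n" for c, L in truth.genome.chromosomes)
        )
        if truth.genome.sequences is not None:
            write_fasta(truth.genome.sequences, outdir / "genome.fa")
        for name, profile in TECHNOLOGY_PROFILES.items():
            calls = make_noisy_callset(truth, profile, seed=args.seed)
            write_vcf_bnd(calls, outdir / f"calls.{name}.vcf",
                          truth.genome.chromosomes, source=name)
        meta = {
            "mechanism": mechanism,
            "seed": args.seed,
            "fragments": len(truth.fragments),
            "junctions": len(truth.junctions),
            "derivatives": len(truth.derivatives),
            "has_duplications": truth.has_duplications,
            "terminal_loss": truth.terminal_loss,
        }
        (outdir / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
        print(f"{mechanism}: {meta['fragments']} fragments, "
              f"{meta['junctions']} junctions, {meta['derivatives']} derivatives")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
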