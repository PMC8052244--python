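#!/usr/bin/env python
"""Intersect simulated breakpoints and junctions with TADs.

Counts breakpoints, junctions, TAD-bridging junctions and genes per TAD,
plus the global number of affected TADs, unassigned breakpoints and
bridging junctions.  Writes results/tad_report.<mechanism>.tsv (affected
TADs only) per simulated rearrangement.
"""

import argparse
from pathlib import Path

from ccrkit.io import read_fragment_table, read_genes, read_tads
from ccrkit.tads import build_tad_report

MECHANISMS = ("chromothripsis", "chromoplexy", "bfb", "chromoanasynthesis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for mechanism in MECHANISMS:
        simdir = args.sim / mechanism
        allow_overlap = mechanism in ("bfb", "chromoanasynthesis")
        _, junctions, _ = read_fragment_table(
            simdir / "fragments.tsv", allow_overlap=allow_overlap
        )
        tads = read_tads(simdir / "tads.bed")
        genes = read_genes(simdir / "genes.bed")
        report = build_tad_report(junctions, tads, genes)
        frame = report.to_frame()
        affected = frame[frame["breakpoints"] > 0]
        affected.to_csv(args.out / f"tad_report.{mechanism}.tsv", sep="\t", index=False)
        print(f"{mechanism}: {report.affected_tads} TADs affected, "
              f"{report.bridging_junctions}/{len(junctions)} junctions bridge TADs, "
              f"{report.unassigned_breakpoints} breakpoints outside all TADs")


if __name__ == "__main__":
    main()
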