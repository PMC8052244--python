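#!/usr/bin/env python
"""Benchmark the simulated technology call sets against the confirmed
junction truth set.

Applies the 100-kbp both-breakend rule with closest (minimal summed
distance) assignment to each technology's VCF and builds the single and
pairwise detection matrix (diagonal: per-technology detections; off
diagonal: union of the pair).  Writes results/benchmark.<mechanism>.tsv.
"""

import argparse
from pathlib import Path

from ccrkit.compare import match_calls, pairwise_union
from ccrkit.io import read_bedpe, read_vcf_bnd
from ccrkit.simulate import TECHNOLOGY_PROFILES

MECHANISMS = ("chromothripsis", "chromoplexy", "bfb", "chromoanasynthesis")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--max-dist", type=int, default=100_000)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for mechanism in MECHANISMS:
        simdir = args.sim / mechanism
        truth = read_bedpe(simdir / "truth.bedpe")
        results = {}
        for name in TECHNOLOGY_PROFILES:
            calls = read_vcf_bnd(simdir / f"calls.{name}.vcf", technology=name)
            results[name] = match_calls(calls, truth, max_dist=args.max_dist)
        matrix = pairwise_union(results)
        matrix.to_csv(args.out / f"benchmark.{mechanism}.tsv", sep="\t")
        rates = ", ".join(
            f"{name} {r.n_detected}/{len(truth)} ({r.n_calls} calls)"
            for name, r in results.items()
        )
        print(f"{mechanism}: {rates}")
        best_pair = max(
            ((a, b) for a in results for b in results if a < b),
            key=lambda p: matrix.loc[p[0], p[1]],
        )
        print(f"  best pairwise union: {best_pair[0]} + {best_pair[1]} = "
              f"{matrix.loc[best_pair[0], best_pair[1]]}/{len(truth)}")


if __name__ == "__main__":
    main()
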