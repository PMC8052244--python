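"""Synthetic-genome and mechanism-simulator properties."""

import numpy as np
import pytest

from ccrkit.model import CcrError, Orientation
from ccrkit.simulate import (
    GenomeSpec,
    TECHNOLOGY_PROFILES,
    TechnologyProfile,
    make_genome,
    make_noisy_callset,
    simulate,
    simulate_bfb,
    simulate_chromoanasynthesis,
    simulate_chromoplexy,
    simulate_chromothripsis,
)
from ccrkit.stats import count_intragenic, orientation_counts
from ccrkit.compare import match_calls


class TestGenome:
    def test_gene_coverage_arithmetic(self):
        spec = GenomeSpec(n_chromosomes=4, chrom_length=1_000_000, genes_per_chrom=50,
                          gene_length=10_000, tad_size=100_000)
        genome = make_genome(spec, seed=2)
        assert spec.gene_coverage == pytest.approx(0.5)
        for chrom, _ in genome.chromosomes:
            covered = sum(g.end - g.start + 1 for g in genome.genes if g.chrom == chrom)
            assert covered == 500_000

    def test_same_seed_is_identical(self):
        spec = GenomeSpec(n_chromosomes=2, chrom_length=500_000, with_sequences=True,
                          genes_per_chrom=5, gene_length=10_000)
        g1, g2 = make_genome(spec, seed=9), make_genome(spec, seed=9)
        assert g1.genes == g2.genes and g1.tads == g2.tads
        assert g1.sequences == g2.sequences

    def test_no_genes_means_no_intragenic_junctions(self, genome):
        spec = GenomeSpec(genes_per_chrom=0)
        empty = make_genome(spec, seed=3)
        truth = simulate_chromothripsis(empty, seed=4)
        assert count_intragenic(truth.junctions, empty.genes) == 0

    def test_infeasible_gene_density_rejected(self):
        with pytest.raises(CcrError, match="infeasible"):
            make_genome(GenomeSpec(chrom_length=100_000, genes_per_chrom=20, gene_length=10_000), 1)

    def test_tads_tile_each_chromosome(self):
        genome = make_genome(
            GenomeSpec(n_chromosomes=1, chrom_length=2_500_000,
                       genes_per_chrom=5, gene_length=10_000),
            seed=5,
        )
        spans = sorted((t.start, t.end) for t in genome.tads)
        assert spans[0][0] == 1 and spans[-1][1] == 2_500_000
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 == e1 + 1


class TestChromothripsis:
    def test_chain_arithmetic_single_chromosome(self, genome):
        truth = simulate_chromothripsis(genome, chroms=1, n_breaks=20, seed=6,
                                        deletion_prob=0.0)
        assert len(truth.fragments) == 21
        assert len(truth.junctions) == 20
        assert len(truth.derivatives) == 1
        assert all(j.deleted_nt == 0 for j in truth.junctions)

    def test_orientation_classes_are_roughly_uniform(self, genome):
        totals = np.zeros(4)
        for seed in range(15):
            truth = simulate_chromothripsis(genome, seed=seed)
            for der in truth.derivatives:
                c = orientation_counts(der)
                totals += [c.tail_to_head, c.head_to_tail, c.head_to_head, c.tail_to_tail]
        n = totals.sum()
        chi2 = float((((totals - n / 4) ** 2) / (n / 4)).sum())
        assert chi2 < 16.27  # chi-square 3 df, alpha = 0.001

    def test_fragments_tile_each_chromosome(self, genome):
        truth = simulate_chromothripsis(genome, seed=7)
        by_chrom = {}
        for f in truth.fragments:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            assert spans[0][0] == 1
            assert spans[-1][1] == genome.lengths[chrom]
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 > e1  # non-overlapping; gaps are the deletions

    def test_too_many_chromosomes_rejected(self, genome):
        with pytest.raises(CcrError, match="few"):
            simulate_chromothripsis(genome, chroms=4, seed=1)

    def test_window_capacity_guard(self, genome):
        with pytest.raises(CcrError):
            simulate_chromothripsis(genome, chroms=1, n_breaks=5000, seed=1,
                                    cluster_window=100_000)


class TestChromoplexy:
    def test_balanced_when_deletions_disabled(self, genome):
        truth = simulate_chromoplexy(genome, seed=8, deletion_prob=0.0)
        assert all(j.deleted_nt == 0 for j in truth.junctions)

    def test_requires_three_chromosomes(self, genome):
        with pytest.raises(CcrError, match="> 2"):
            simulate_chromoplexy(genome, chroms=2, seed=1)

    def test_intragenic_fraction_tracks_bias(self, genome):
        biased = simulate_chromoplexy(genome, seed=9, intragenic_bias=0.95)
        unbiased = simulate_chromoplexy(genome, seed=9, intragenic_bias=0.0)
        genes = genome.genes
        assert count_intragenic(biased.junctions, genes) > count_intragenic(
            unbiased.junctions, genes
        )


class TestBfb:
    def test_single_cycle_single_foldback(self, genome):
        truth = simulate_bfb(genome, n_cycles=1, seed=10)
        assert len(truth.junctions) == 1
        c = orientation_counts(truth.derivatives[0])
        assert c.head_to_head + c.tail_to_tail == 1

    def test_all_junctions_are_foldback(self, genome):
        truth = simulate_bfb(genome, n_cycles=10, seed=11)
        c = orientation_counts(truth.derivatives[0])
        assert c.head_to_head + c.tail_to_tail == c.n_junctions == len(truth.junctions)

    def test_flags(self, genome):
        truth = simulate_bfb(genome, seed=12)
        assert truth.terminal_loss and truth.has_duplications


class TestChromoanasynthesis:
    def test_requires_sequences(self, genome):
        with pytest.raises(CcrError, match="sequence"):
            simulate_chromoanasynthesis(genome, seed=1)

    def test_fixed_microhomology_planted_everywhere(self, seq_genome):
        truth = simulate_chromoanasynthesis(
            seq_genome, seed=13, microhomology_sizes=(4,), microhomology_prob=1.0,
            insertion_prob=0.0, duplication_prob=0.0,
        )
        assert all(j.microhomology_len == 4 for j in truth.junctions)

    def test_duplicated_fragments_are_flagged(self, seq_genome):
        truth = simulate_chromoanasynthesis(seq_genome, seed=14, duplication_prob=0.5)
        assert truth.has_duplications
        dup_ids = [f.id for f in truth.fragments if f.id.endswith(".d")]
        assert dup_ids


class TestNoisyCallsets:
    def test_perfect_profile_reproduces_truth(self, genome):
        truth = simulate_chromoplexy(genome, seed=15)
        profile = TechnologyProfile("perfect", 1.0, 0, 0.0)
        calls = make_noisy_callset(truth, profile, seed=1)
        assert [(c.end_a, c.end_b) for c in calls] == [
            (j.end_a, j.end_b) for j in truth.junctions
        ]
        assert match_calls(calls, truth.junctions).detection_rate() == 1.0

    def test_zero_sensitivity_is_empty(self, genome):
        truth = simulate_chromoplexy(genome, seed=16)
        profile = TechnologyProfile("none", 0.0, 0, 0.0)
        assert make_noisy_callset(truth, profile, seed=1) == []

    def test_mean_detection_matches_sensitivity(self, genome):
        truth = simulate_chromoplexy(genome, seed=17)
        n = len(truth.junctions)
        profile = TechnologyProfile("s", 0.9, 0, 0.0)
        detected = [
            len(make_noisy_callset(truth, profile, seed=s)) for s in range(60)
        ]
        se = np.sqrt(n * 0.9 * 0.1 / 60)
        assert abs(np.mean(detected) - 0.9 * n) < 5 * se

    def test_builtin_profiles_are_valid(self):
        for profile in TECHNOLOGY_PROFILES.values():
            assert 0 <= profile.sensitivity <= 1


class TestDeterminism:
    @pytest.mark.parametrize(
        "mechanism", ["chromothripsis", "chromoplexy", "bfb", "chromoanasynthesis"]
    )
    def test_same_seed_identical_different_seed_not(self, mechanism, genome, seq_genome):
        g = seq_genome if mechanism == "chromoanasynthesis" else genome
        t1 = simulate(mechanism, g, seed=20)
        t2 = simulate(mechanism, g, seed=20)
        t3 = simulate(mechanism, g, seed=21)
        key = lambda t: [
            (j.id, j.end_a, j.end_b, j.deleted_nt, j.microhomology_len, j.inserted_seq)
            for j in t.junctions
        ]
        assert key(t1) == key(t2)
        assert key(t1) != key(t3)

    def test_unknown_mechanism_rejected(self, genome):
        with pytest.raises(CcrError, match="unknown mechanism"):
            simulate("mystery", genome, seed=1)
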