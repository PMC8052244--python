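"""Exact binomial machinery, distribution/orientation tests, and the
Monte Carlo intragenic-enrichment test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from ccrkit.model import Breakend, Fragment, Junction, Side
from ccrkit.simulate import (
    GenomeSpec,
    make_genome,
    simulate_bfb,
    simulate_chromoplexy,
)
from ccrkit.stats import (
    OrientationCounts,
    count_intragenic,
    exact_binomial_one_sided,
    foldback_enrichment,
    fragment_distribution_test,
    monte_carlo_intragenic,
    orientation_counts,
    orientation_tests,
)
from ccrkit.walker import reconstruct_all
from ccrkit.model import Gene


def brute_force_tail(n, k, p0, direction):
    """Independent oracle: direct summation of binomial point masses."""
    ks = range(k, n + 1) if direction == "upper" else range(0, k + 1)
    return math.fsum(
        math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in ks
    )


class TestExactBinomial:
    def test_closed_forms(self):
        r = exact_binomial_one_sided(5, 0, 0.5)
        assert r.direction == "lower" and r.p_value == pytest.approx(0.03125)
        r = exact_binomial_one_sided(28, 28, 0.25)
        assert r.direction == "upper" and r.p_value == pytest.approx(0.25**28)

    def test_depleted_origin_example(self):
        # 4 of 36 fragments on one of four derivatives: lower tail 0.034
        r = exact_binomial_one_sided(36, 4, 0.25)
        assert r.direction == "lower"
        assert round(r.p_value, 3) == 0.034

    def test_brute_force_summation_example(self):
        r = exact_binomial_one_sided(28, 3, 0.25)
        assert r.p_value == pytest.approx(brute_force_tail(28, 3, 0.25, "lower"))
        assert round(r.p_value, 4) == 0.0551

    def test_tie_at_expectation_uses_lower_tail(self):
        r = exact_binomial_one_sided(20, 10, 0.5)
        assert r.direction == "lower" and r.p_value > 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            r = exact_binomial_one_sided(n, k, p0)
            assert abs(r.p_value - brute_force_tail(n, k, p0, r.direction)) < 1e-12

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_agreement_property(self, data):
        n = data.draw(st.integers(1, 200))
        k = data.draw(st.integers(0, n))
        p0 = data.draw(st.floats(0.01, 0.99, allow_nan=False))
        r = exact_binomial_one_sided(n, k, p0)
        assert abs(r.p_value - brute_force_tail(n, k, p0, r.direction)) < 1e-12
        assert r.direction == ("upper" if k > n * p0 else "lower")

    def test_upper_tail_monotone_in_k(self):
        values = [float(binom.sf(k - 1, 50, 0.3)) for k in range(51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            exact_binomial_one_sided(10, 11, 0.5)
        with pytest.raises(ValueError):
            exact_binomial_one_sided(10, 5, 1.0)


def _assigned_fragments(counts_per_derivative, origin="chr4"):
    """Fragments of one origin distributed over named derivatives, plus
    matching single-fragment 'derivative' stand-ins for the test."""
    from ccrkit.model import DerivativeChromosome, Orientation, PlacedFragment

    fragments, derivatives = [], []
    fid = 0
    for name, count in counts_per_derivative.items():
        chain = []
        for i in range(count):
            fid += 1
            frag = Fragment(f"F{fid}", origin, fid * 1000, fid * 1000 + 10)
            fragments.append(frag)
            chain.append(PlacedFragment(frag, Orientation.FORWARD, i))
        junctions = [
            Junction(
                f"{name}.J{i}",
                chain[i].fragment.breakend(Side.TAIL),
                chain[i + 1].fragment.breakend(Side.HEAD),
            )
            for i in range(len(chain) - 1)
        ]
        derivatives.append(DerivativeChromosome(name, chain, junctions))
    return fragments, derivatives


class TestFragmentDistribution:
    def test_case_scale_cells(self):
        # origin with 93 fragments: 45/13 on two of four derivatives
        fragments, derivatives = _assigned_fragments(
            {"der(4)": 45, "der(19)": 17, "der(21)": 13, "der(X)": 18}
        )
        m = fragment_distribution_test(fragments, derivatives)
        assert m.fraction("chr4", "der(4)") == pytest.approx(45 / 93, abs=0.005)
        assert round(math.log10(m.tests[("chr4", "der(4)")].p_value)) == -6
        assert round(m.tests[("chr4", "der(21)")].p_value, 3) == 0.007

    def test_all_on_one_derivative_closed_form(self):
        # derivatives without fragments of the origin are kept as k = 0 rows
        fragments, derivatives = _assigned_fragments(
            {"der(1)": 12, "der(2)": 0, "der(3)": 0, "der(4)": 0}
        )
        m = fragment_distribution_test(fragments, derivatives)
        r = m.tests[("chr4", "der(1)")]
        assert m.fraction("chr4", "der(1)") == 1.0
        assert r.p_value == pytest.approx(0.25**12)
        assert m.counts[("chr4", "der(2)")] == 0

    def test_row_sums_conserve_totals(self):
        fragments, derivatives = _assigned_fragments(
            {"der(1)": 7, "der(2)": 3, "der(3)": 2}
        )
        m = fragment_distribution_test(fragments, derivatives)
        assert m.origin_total("chr4") == 12
        assert sum(m.fraction("chr4", d) for d in m.derivatives) == pytest.approx(1.0)

    def test_null_calibration_of_cell_pvalues(self):
        # assign 12 fragments uniformly among 4 derivatives; the frequency of
        # p < 0.05 must match the exact discrete null expectation
        rng = np.random.default_rng(11)
        n, p0, alpha = 12, 0.25, 0.05
        expected = sum(
            float(binom.pmf(k, n, p0))
            for k in range(n + 1)
            if exact_binomial_one_sided(n, k, p0).p_value < alpha
        )
        reps = 2000
        hits = 0
        for _ in range(reps):
            k = int(rng.binomial(n, p0))
            if exact_binomial_one_sided(n, k, p0).p_value < alpha:
                hits += 1
        se = math.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 4 * se + 1e-9


class TestOrientation:
    def test_collinear_chain_is_all_tail_to_head(self):
        fragments, derivatives = _assigned_fragments({"der(1)": 3})
        c = orientation_counts(derivatives[0])
        assert c.as_dict() == {
            "tail_to_head": 2, "head_to_tail": 0, "head_to_head": 0, "tail_to_tail": 0,
        }

    def test_forward_then_reverse_is_tail_to_tail(self):
        from ccrkit.model import DerivativeChromosome, Orientation, PlacedFragment

        a = Fragment("A", "chr1", 1, 100)
        b = Fragment("B", "chr1", 201, 300)
        der = DerivativeChromosome(
            "d",
            [
                PlacedFragment(a, Orientation.FORWARD, 0),
                PlacedFragment(b, Orientation.REVERSE, 1),
            ],
            [Junction("J1", a.breakend(Side.TAIL), b.breakend(Side.TAIL))],
        )
        assert orientation_counts(der).tail_to_tail == 1

    def test_der19_tail_to_head_p_value(self):
        counts = OrientationCounts("der(19)", 3, 9, 8, 8)
        tests = orientation_tests(counts)
        r = tests["tail_to_head"]
        assert r.direction == "lower" and round(r.p_value, 2) == 0.06

    def test_symmetric_counts_use_lower_tail(self):
        counts = OrientationCounts("d", 7, 7, 7, 7)
        for r in orientation_tests(counts).values():
            assert r.direction == "lower" and r.p_value >= 0.5

    def test_extreme_count_closed_form(self):
        counts = OrientationCounts("d", 28, 0, 0, 0)
        assert orientation_tests(counts)["tail_to_head"].p_value == pytest.approx(
            0.25**28
        )

    def test_bfb_foldback_count_matches_simulator(self, genome):
        truth = simulate_bfb(genome, seed=21)
        c = orientation_counts(truth.derivatives[0])
        assert c.head_to_head + c.tail_to_tail == len(truth.junctions)


class TestFoldback:
    def test_all_foldback_closed_form(self):
        r = foldback_enrichment(OrientationCounts("d", 0, 0, 10, 10))
        assert r.direction == "upper" and r.p_value == pytest.approx(0.5**20)

    def test_balanced_counts_are_not_enriched(self):
        r = foldback_enrichment(OrientationCounts("d", 5, 5, 5, 5))
        assert r.direction == "lower" and r.p_value > 0.5

    def test_simulated_bfb_is_strongly_enriched(self, genome):
        low = 0
        for seed in range(20):
            truth = simulate_bfb(genome, n_cycles=25, seed=seed)
            r = foldback_enrichment(orientation_counts(truth.derivatives[0]))
            if r.p_value < 1e-6:
                low += 1
        assert low == 20  # 0.5^25 whenever >= 25 informative cycles ran


class TestIntragenic:
    def test_single_end_in_gene_counts(self):
        genes = [Gene("g", "chr1", 100, 200)]
        inside = Junction("J1", Breakend("chr1", 150, Side.TAIL), Breakend("chr2", 5000, Side.HEAD))
        outside = Junction("J2", Breakend("chr1", 500, Side.TAIL), Breakend("chr2", 5000, Side.HEAD))
        assert count_intragenic([inside], genes) == 1
        assert count_intragenic([outside], genes) == 0

    def test_expected_count_under_uniform_breakends(self):
        # genes covering fraction g: P(junction intragenic) = 1 - (1 - g)^2
        spec = GenomeSpec(n_chromosomes=2, chrom_length=1_000_000, genes_per_chrom=10, gene_length=25_000)
        genome = make_genome(spec, seed=3)
        g = spec.gene_coverage
        n, reps = 200, 30
        rng = np.random.default_rng(4)
        counts = []
        chroms = [c for c, _ in genome.chromosomes]
        for _ in range(reps):
            junctions = []
            for i in range(n):
                ends = []
                for _ in range(2):
                    chrom = chroms[int(rng.integers(0, 2))]
                    ends.append(Breakend(chrom, int(rng.integers(1, 1_000_001)), Side.TAIL))
                junctions.append(Junction(f"J{i}", ends[0], ends[1]))
            counts.append(count_intragenic(junctions, genome.genes))
        expected = n * (1 - (1 - g) ** 2)
        se = math.sqrt(n * (1 - (1 - g) ** 2) * (1 - g) ** 2 / reps)
        assert abs(np.mean(counts) - expected) < 5 * se

    def test_maximum_observed_count_gives_p_zero(self, genome):
        truth = simulate_chromoplexy(genome, seed=5)
        n = len(truth.junctions)
        r = monte_carlo_intragenic(
            truth.junctions, truth.genome.genes, truth.genome.lengths,
            iterations=200, seed=1, observed=n,
        )
        assert r.p_value == 0.0
        assert "p <" in r.formatted_p()

    def test_observed_zero_gives_p_near_one(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=1_000_000, genes_per_chrom=20, gene_length=25_000)
        genome = make_genome(spec, seed=6)  # 50% gene coverage
        junctions = [
            Junction(f"J{i}", Breakend("chr1", 10 + i, Side.TAIL), Breakend("chr1", 500_000 + i, Side.HEAD))
            for i in range(100)
        ]
        r = monte_carlo_intragenic(
            junctions, genome.genes, genome.lengths, iterations=300, seed=2, observed=0
        )
        assert r.p_value > 0.99

    def test_bit_reproducible_for_seed(self, genome):
        truth = simulate_chromoplexy(genome, seed=7)
        args = (truth.junctions, truth.genome.genes, truth.genome.lengths)
        r1 = monte_carlo_intragenic(*args, iterations=300, seed=9)
        r2 = monte_carlo_intragenic(*args, iterations=300, seed=9)
        assert r1.p_value == r2.p_value
        assert (r1.sim_counts == r2.sim_counts).all()
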