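"""Junction-signature operations: microhomology scanning, insertion
classification, deletion measurement and binned summaries."""

import numpy as np
import pytest

from ccrkit.model import Breakend, Fragment, Junction, Side
from ccrkit.signatures import (
    breakend_search_flanks,
    classify_insertion,
    junction_deletion,
    junction_flanks,
    microhomology_length,
    reverse_complement,
    summarize_signatures,
)
from ccrkit.simulate import simulate_chromoanasynthesis, simulate_chromothripsis


def brute_force_microhomology(left_ref: str, right_ref: str) -> int:
    """Independent oracle: count breakpoint shifts that yield the identical
    junction sequence; the ambiguous range is one less than that."""
    w = len(left_ref) // 2
    original = left_ref[:w] + right_ref[w:]
    valid = 0
    for s in range(-w, w + 1):
        if left_ref[: w + s] + right_ref[w + s :] == original:
            valid += 1
    return valid - 1


class TestMicrohomology:
    def test_constructed_two_nt_overlap(self):
        # junction read ...TTACGTAAC...: upstream ends TTAC with continuation
        # GT..., downstream starts GTAAC with precedent ...GT
        left = "CCCCCCCCCCCCCCCCTTAC" + "GTGGGGGGGGGGGGGGGGGG"
        right = "AAAAAAAAAAAAAAAAAAGT" + "GTAACTTTTTTTTTTTTTTT"
        # forward extension: right[20:22] == left[20:22] == "GT"
        assert microhomology_length(left, right) == 2

    def test_dissimilar_flanks_give_zero(self):
        left = "A" * 40
        right = "C" * 40
        assert microhomology_length(left, right) == 0

    def test_matches_brute_force_shift_oracle(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            left = "".join(rng.choice(bases, 40))
            right = "".join(rng.choice(bases, 40))
            assert microhomology_length(left, right) == brute_force_microhomology(
                left, right
            )

    def test_symmetric_under_segment_swap_with_revcomp(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            left = "".join(rng.choice(bases, 40))
            right = "".join(rng.choice(bases, 40))
            swapped_left = reverse_complement(right)
            swapped_right = reverse_complement(left)
            assert microhomology_length(left, right) == microhomology_length(
                swapped_left, swapped_right
            )

    def test_rejects_non_nucleotide_input(self):
        with pytest.raises(Exception, match="non-ACGTN"):
            microhomology_length("AX" * 20, "AC" * 20)

    def test_recovers_planted_lengths_from_simulated_sequence(self, seq_genome):
        truth = simulate_chromoanasynthesis(seq_genome, seed=10, duplication_prob=0.0)
        for j in truth.junctions:
            if j.inserted_seq:
                continue
            measured = microhomology_length(*junction_flanks(j, truth.genome))
            assert measured == truth.junction_truth[j.id]["microhomology"]


class TestInsertionClassification:
    def test_planted_match_is_templated(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        insertion = "".join(rng.choice(bases, 30))
        flank = "".join(rng.choice(bases, 100)) + insertion + "".join(rng.choice(bases, 100))
        assert classify_insertion(insertion, [flank]).is_templated

    def test_reverse_complement_match_is_templated(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        insertion = "".join(rng.choice(bases, 30))
        flank = "T" * 50 + reverse_complement(insertion) + "G" * 50
        result = classify_insertion(insertion, [flank])
        assert result.is_templated and result.reverse_complemented

    def test_random_insertion_is_non_templated(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            insertion = "".join(rng.choice(bases, 30))
            flanks = ["".join(rng.choice(bases, 500)) for _ in range(4)]
            assert not classify_insertion(insertion, flanks).is_templated

    def test_simulated_templated_insertions_classified(self, seq_genome):
        truth = simulate_chromoanasynthesis(
            seq_genome, seed=11, insertion_prob=1.0, templated_prob=1.0,
            microhomology_prob=0.0, duplication_prob=0.0,
        )
        inserted = [j for j in truth.junctions if j.inserted_seq]
        assert inserted
        for j in inserted:
            flanks = breakend_search_flanks(j, truth.genome)
            assert classify_insertion(j.inserted_seq, flanks).is_templated


class TestJunctionDeletion:
    def test_adjacent_fusion_is_balanced(self):
        frags = [Fragment("A", "chr4", 1, 100), Fragment("B", "chr4", 101, 200)]
        j = Junction("J1", Breakend("chr4", 100, Side.TAIL), Breakend("chr4", 101, Side.HEAD))
        assert junction_deletion(j, frags) == 0

    def test_shared_gap_counted_once(self):
        frags = [Fragment("A", "chr4", 1, 100), Fragment("B", "chr4", 151, 200)]
        j = Junction("J1", Breakend("chr4", 100, Side.TAIL), Breakend("chr4", 151, Side.HEAD))
        assert junction_deletion(j, frags) == 50

    def test_recovers_simulated_deletions(self, genome):
        truth = simulate_chromothripsis(genome, seed=12)
        for j in truth.junctions:
            assert junction_deletion(j, truth.fragments) == j.deleted_nt


def _junction(jid, deleted=0, mh=0, ins="", templated=False):
    return Junction(
        jid,
        Breakend("chr1", 100, Side.TAIL),
        Breakend("chr2", 100, Side.HEAD),
        inserted_seq=ins,
        microhomology_len=mh,
        deleted_nt=deleted,
        templated=templated,
    )


class TestSummary:
    def test_small_cohort_counts_and_percentages(self):
        # 3 balanced + deletions of 1 and 2 nt: 60% balanced, 40% < 10 nt
        junctions = [
            _junction("J1"), _junction("J2"), _junction("J3"),
            _junction("J4", deleted=1), _junction("J5", deleted=2),
        ]
        s = summarize_signatures(junctions)
        assert (s.balanced, s.percent("balanced")) == (3, 60)
        assert (s.del_lt10, s.percent("del_lt10")) == (2, 40)

    def test_empty_set_gives_all_zero(self):
        s = summarize_signatures([])
        assert s.n_junctions == 0 and s.balanced == 0 and s.percent("balanced") == 0

    def test_planted_bins_are_recovered(self):
        rng = np.random.default_rng(3)
        plan = {
            "balanced": (0, 30), "del_lt10": (5, 20), "del_lt100": (50, 25),
            "del_lt1000": (500, 18), "del_lt10000": (5000, 21), "del_gt10000": (50000, 18),
        }
        junctions = []
        for size, count in plan.values():
            for _ in range(count):
                junctions.append(_junction(f"J{len(junctions)}", deleted=size))
        order = rng.permutation(len(junctions))
        s = summarize_signatures([junctions[i] for i in order])
        for name, (_, count) in plan.items():
            assert getattr(s, name) == count
        assert s.n_junctions == 132

    def test_bins_partition_every_junction(self, genome):
        truth = simulate_chromothripsis(genome, seed=14)
        s = summarize_signatures(truth.junctions)
        deletion_bins = (
            s.balanced + s.del_lt10 + s.del_lt100 + s.del_lt1000
            + s.del_lt10000 + s.del_gt10000
        )
        assert deletion_bins == s.n_junctions
        assert s.mh_lt2 + s.mh_2_10 + s.mh_gt10 == s.mh_total
        assert s.ins_lt2 + s.ins_lt20 + s.ins_lt100 + s.ins_gt100 == s.ins_total

    def test_summary_invariant_under_reordering(self, genome):
        truth = simulate_chromothripsis(genome, seed=15)
        s1 = summarize_signatures(truth.junctions)
        s2 = summarize_signatures(list(reversed(truth.junctions)))
        assert s1 == s2
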