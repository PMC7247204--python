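"""Junction caller vs the brute-force placement-enumeration oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_ref
from oracle import enumerate_placements, oracle_canonical_start, oracle_mh_len
from spidel.caller import (
    NonIndelError,
    ResolutionError,
    call_deletion,
    call_from_descriptor,
    call_from_mutant_sequence,
    call_insertion,
    reverse_complement_call,
)
from spidel.io import parse_breakpoint_notation

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestCallDeletion:
    def test_published_microhomology_junction(self):
        # A reference reconstructed from the printed junction agca|GC|ccgt of a
        # 4-bp deletion with 2-bp homology: agca GC .. GC ccgt.
        ref = make_ref("AGCAGCTTGCCCGT")
        call = call_deletion(ref, 6, 10)  # delete TTGC
        assert (call.canonical_start, call.placement_count, call.mh_len) == (4, 3, 2)
        assert call.mh_seq == "GC"
        assert call.apply(ref) == "AGCAGCCCGT"
        assert enumerate_placements(ref.sequence, 6, 10) == [4, 5, 6]

    def test_blunt_junction_has_single_placement(self):
        # tgag|tcag junction with no shared flank bases
        ref = make_ref("TGAGCCTCAG")
        call = call_deletion(ref, 4, 6)
        assert (call.placement_count, call.mh_len, call.mh_seq) == (1, 0, "")

    def test_whole_reference_deletion(self):
        ref = make_ref("ACGTACGT")
        call = call_deletion(ref, 0, 8)
        assert (call.placement_count, call.mh_len) == (1, 0)

    def test_one_bp_deletion_in_run_flags_in_run(self):
        ref = make_ref("TTAAAATT")
        call = call_deletion(ref, 3, 4)
        assert call.in_run and call.placement_count == 4  # run length 4

    def test_one_bp_deletion_outside_run(self):
        ref = make_ref("TTAGCC")
        call = call_deletion(ref, 3, 4)
        assert not call.in_run and call.placement_count == 1

    def test_out_of_range_raises(self):
        ref = make_ref("ACGT")
        with pytest.raises(IndexError):
            call_deletion(ref, 2, 7)

    @pytest.mark.parametrize("size", [1, 2, 3, 4, 5, 6])
    def test_matches_oracle_on_random_sixty_mers(self, rng, size):
        # every (start, end) pair with size <= 6 on reproducible random 60-mers
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            ref = make_ref(seq)
            for start in range(0, 60 - size + 1):
                call = call_deletion(ref, start, start + size)
                placements = enumerate_placements(seq, start, start + size)
                assert call.placement_count == len(placements)
                assert call.canonical_start == min(placements)

    @given(seq=dna, data=st.data())
    @settings(derandomize=True, max_examples=200)
    def test_reconstruction_and_idempotence(self, seq, data):
        start = data.draw(st.integers(0, len(seq) - 1))
        end = data.draw(st.integers(start + 1, len(seq)))
        ref = make_ref(seq)
        call = call_deletion(ref, start, end)
        # every equivalent placement yields the identical mutant
        mutant = call.apply(ref)
        for s in enumerate_placements(seq, start, end):
            assert seq[:s] + seq[s + call.size:] == mutant
        # re-calling the canonical placement returns identical fields
        again = call_deletion(ref, call.canonical_start, call.end)
        assert again == call
        assert call.mh_len == oracle_mh_len(seq, start, end)
        # microhomology appears at both ends of the deleted segment
        assert seq[call.canonical_start: call.canonical_start + call.mh_len] == call.mh_seq
        assert seq[call.end: call.end + call.mh_len] == call.mh_seq

    @given(seq=dna, data=st.data())
    @settings(derandomize=True, max_examples=150)
    def test_reverse_complement_symmetry(self, seq, data):
        start = data.draw(st.integers(0, len(seq) - 1))
        end = data.draw(st.integers(start + 1, len(seq)))
        ref = make_ref(seq)
        call = call_deletion(ref, start, end)
        rc_call = reverse_complement_call(ref, call)
        assert rc_call.mh_len == call.mh_len
        assert rc_call.placement_count == call.placement_count


class TestCallInsertion:
    def test_run_insertion_left_aligned(self):
        ref = make_ref("TTAAAATT")
        call = call_insertion(ref, 5, "A")
        assert call.canonical_start == 2  # run starts at index 2
        assert call.placement_count == 5  # 4-run admits 5 insertion points
        assert call.apply(ref) == "TTAAAAATT"

    def test_non_run_insertion(self):
        ref = make_ref("ACGT")
        call = call_insertion(ref, 2, "T")
        assert call.apply(ref) == "ACTGT"


class TestCallFromMutantSequence:
    def test_unique_placement(self):
        ref = make_ref("AAACCCGGG")
        call = call_from_mutant_sequence(ref, "AAAGGG")
        assert (call.canonical_start, call.size) == (3, 3)

    def test_run_deletion_placements_match_enumeration(self):
        # Exactly two contiguous 2-bp windows of AAACCCGGG give AAACGGG
        ref = make_ref("AAACCCGGG")
        expected = [
            s
            for s in range(8)
            if ref.sequence[:s] + ref.sequence[s + 2:] == "AAACGGG"
        ]
        call = call_from_mutant_sequence(ref, "AAACGGG")
        assert expected == [3, 4]
        assert (call.size, call.placement_count, call.mh_seq) == (2, 2, "C")

    def test_identical_sequences_rejected(self):
        ref = make_ref("ACGTACGT")
        with pytest.raises(NonIndelError):
            call_from_mutant_sequence(ref, "ACGTACGT")

    def test_separated_changes_absorbed_into_one_indel(self):
        # two distant 1-bp deletions have no two-breakpoint representation;
        # the recovered event is the single spanning deletion + insertion
        ref = make_ref("AAACCCGGGTTTAAA")
        call = call_from_mutant_sequence(ref, "AACCCGGGTTAAA")
        assert call.size > len(call.inserted_seq) > 0
        assert call.apply(ref) == "AACCCGGGTTAAA"

    def test_deletion_with_junction_insertion(self):
        ref = make_ref("TTTTGCGCAAAA")
        call = call_from_mutant_sequence(ref, "TTTTAGAAAA")  # del GCGC, ins AG
        assert (call.size, call.inserted_seq) == (4, "AG")
        assert call.apply(ref) == "TTTTAGAAAA"

    def test_insertion_sharing_flank_bases_is_trimmed(self):
        # an inserted base identical to the adjacent deleted base is absorbed:
        # the minimal (maximally trimmed) representation is recovered
        ref = make_ref("TTTTGCGCAAAA")
        call = call_from_mutant_sequence(ref, "TTTTCCAAAA")
        assert (call.size, call.inserted_seq) == (3, "C")  # del GCG, ins C
        assert call.apply(ref) == "TTTTCCAAAA"

    def test_simulated_truth_recovered(self, rng):
        from spidel.simulate import SimulationConfig, _RefIndex, simulate_mutant, simulate_reference

        cfg = SimulationConfig(seed=7, ref_length=2000, junction_insertion_prob=0.3)
        ref = simulate_reference(cfg)
        index = _RefIndex(ref)
        params = {"slippage_1bp": 0.2, "other_1bp": 0.1, "dsb_deletion": 0.6,
                  "pure_insertion": 0.1, "complex": 0.0}
        for _ in range(100):
            mutant, _, truth = simulate_mutant(ref, cfg, rng, params, index)
            call = call_from_mutant_sequence(ref, mutant)
            assert call == truth


class TestCallFromDescriptor:
    def test_coordinate_placement_count_equals_span(self):
        # agca GC tt GC ccgt, printed as 5–7 -> 10–12 (span 3)
        ref = make_ref("AGCAGCTTGCCCGT")
        d = parse_breakpoint_notation("5–7 → 10–12")
        call = call_from_descriptor(ref, d)
        assert call.placement_count == d.span == 3
        assert call.mh_len == 2

    def test_context_run_deletion(self):
        ref = make_ref("GCGCAAAAAGCGC")
        d = parse_breakpoint_notation("5–9", "AAAAA→AAAA")
        call = call_from_descriptor(ref, d)
        assert (call.size, call.in_run, call.placement_count) == (1, True, 5)

    def test_context_non_run_deletion(self):
        ref = make_ref("GGTTATTGG")
        d = parse_breakpoint_notation("5", "ttAtt→tttt")
        call = call_from_descriptor(ref, d)
        assert (call.size, call.in_run) == (1, False)

    def test_ambiguous_context_raises(self):
        ref = make_ref("TTATTGGTTATT")
        d = parse_breakpoint_notation("3", "ttAtt→tttt")
        with pytest.raises(ResolutionError, match="2 times"):
            call_from_descriptor(ref, d)

    def test_context_insertion(self):
        ref = make_ref("GGCAACAGG")
        d = parse_breakpoint_notation("3–6", "aaca→aacTa")
        call = call_from_descriptor(ref, d)
        assert call.size == 0 and call.inserted_seq == "T"
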