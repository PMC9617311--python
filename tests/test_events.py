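"""Event calling: the duplication signature, validation, merging, the size formula."""

import numpy as np
import pytest

from tracedup import (
    Break,
    RunParameters,
    call_event,
    is_duplication_break,
    merge_breaks,
    validate_break,
)
from tracedup.pipeline import process_read

from conftest import make_trace

PARAMS = RunParameters()


def _dup_read(reference, start, length, window=60, insert=""):
    """A read centred on the junction of a tandem duplication of
    reference[start:start+length], optionally with bases inserted at the junction."""
    mutant = reference[: start + length] + insert + reference[start:]
    junction = start + length
    return mutant[junction - window : junction + window]


class TestDuplicationSignature:
    def test_worked_example_goes_back(self):
        trace = make_trace([3, 4, 5, None, None, 4, 5, 6, 7])
        assert is_duplication_break(trace, Break(3, 4))  # 5 + 2 - 1 > 4

    def test_adjacent_continuation_is_not_a_duplication(self):
        trace = make_trace([3, None, 4])
        assert not is_duplication_break(trace, Break(1, 1))  # 3 + 0 > 4 is false

    def test_edge_break_uncallable_not_an_exception(self):
        trace = make_trace([None, None, 4, 5])
        assert not is_duplication_break(trace, Break(0, 1))

    def test_exhaustive_grid_matches_direct_inequality(self):
        for left in range(10):
            for right in range(10):
                for g in range(1, 6):
                    entries = [left] + [None] * g + [right]
                    trace = make_trace(entries)
                    brk = Break(1, g)
                    assert is_duplication_break(trace, brk) == (left + g - 1 > right)


class TestValidateBreak:
    def test_consecutive_context_accepts(self):
        trace = make_trace([3, 4, 5, None, None, 4, 5, 6])
        assert validate_break(trace, Break(3, 4), delta=2)

    def test_non_consecutive_left_context_rejects(self):
        trace = make_trace([7, 3, 5, None, None, 4, 5, 6])
        assert not validate_break(trace, Break(3, 4), delta=2)

    def test_delta_zero_reduces_to_flank_presence(self):
        trace = make_trace([5, None, 4])
        assert validate_break(trace, Break(1, 1), delta=0)
        assert not validate_break(trace, Break(0, 0), delta=0)  # no left flank

    def test_insufficient_context_at_read_edge_rejects(self):
        trace = make_trace([5, None, None, 4, 5, 6])
        assert not validate_break(trace, Break(1, 2), delta=2)


class TestMergeBreaks:
    def test_distant_breaks_unchanged(self):
        trace = make_trace([0, None, 1, 2, 3, 4, None, 5])
        breaks = [Break(1, 1), Break(6, 6)]
        assert merge_breaks(breaks, trace, delta=2) == breaks

    def test_spurious_split_break_is_merged(self, random_ref, ref_index):
        """A chance in-reference k-mer inside a duplication break must not split
        the call: the two fragments would imply wild sizes, the merged break the
        true one."""
        # entries: left run ends at 50, stray resolved position 120 inside the
        # break, right run restarts at 31 (a 30 nt duplication signature)
        entries = (
            [48, 49, 50]
            + [None] * 4
            + [120]
            + [None] * 6
            + [31, 32, 33]
        )
        trace = make_trace(entries, k=12)
        breaks = [Break(3, 6), Break(8, 13)]
        merged = merge_breaks(breaks, trace, delta=2)
        assert merged == [Break(3, 13)]
        event = call_event(trace, merged[0], k=12)
        assert event.kind == "duplication" and event.size == 50 - 31 + 13 - 3 + 2

    def test_two_genuine_small_events_not_merged(self):
        # two 1 nt deletions separated by one present entry: the separate calls
        # (|d| = 1 each) are smaller than the merged call (|d| = 2), so no merge
        entries = [10, 11, None, 14, None, 17, 18]
        trace = make_trace(entries)
        breaks = [Break(2, 2), Break(4, 4)]
        assert merge_breaks(breaks, trace, delta=2) == breaks


class TestCallEvent:
    @pytest.mark.parametrize(
        "entries, brk, expected_size",
        [
            # clean duplication: break (3,4), flanks 5 and 4
            ([3, 4, 5, None, None, 4, 5, 6, 7], Break(3, 4), 4),
            # substitution near the breakpoint enlarges the break to (1,4),
            # shifts the left flank to 3; the size must not change
            ([3, None, None, None, None, 4, 5, 6, 7], Break(1, 4), 4),
            # junction overlap shortens the break to a single index
            ([4, 5, 6, None, 3, 4, 5], Break(3, 3), 5),
        ],
    )
    def test_worked_size_computations(self, entries, brk, expected_size):
        event = call_event(make_trace(entries), brk, k=3)
        assert event is not None
        assert event.kind == "duplication"
        assert event.size == expected_size

    def test_size_zero_remnant_yields_no_event(self):
        # flanks continue the diagonal across a 1-entry break: d = 0
        trace = make_trace([3, 4, None, 6])
        assert call_event(trace, Break(2, 2), k=3) is None

    def test_duplicated_sequence_recoverable(self, worked_index):
        trace = make_trace([3, 4, 5, None, None, 4, 5, 6, 7])
        event = call_event(trace, Break(3, 4), k=3)
        assert (event.ref_start, event.ref_end_exclusive) == (4, 8)
        assert worked_index.reference[event.ref_start : event.ref_end_exclusive] == "AGAT"

    def test_deletion_size_is_magnitude(self, random_ref, ref_index):
        deleted = random_ref[:150] + random_ref[158:]
        read = deleted[150 - 60 : 150 + 60]
        _, events = process_read("del", read, ref_index, PARAMS)
        assert [(e.kind, e.size) for e in events] == [("deletion", 8)]
        assert (events[0].ref_start, events[0].ref_end_exclusive) == (150, 158)


class TestPerReadPipeline:
    def test_wildtype_read_yields_nothing(self, random_ref, ref_index):
        _, events = process_read("wt", random_ref[30:150], ref_index, PARAMS)
        assert events == []

    def test_single_simulated_itd(self, random_ref, ref_index):
        read = _dup_read(random_ref, 140, 30)
        _, events = process_read("itd", read, ref_index, PARAMS)
        assert [(e.kind, e.size, e.ref_start) for e in events] == [
            ("duplication", 30, 140)
        ]

    def test_two_duplications_in_one_read(self, random_ref, ref_index):
        mutant = random_ref[:176] + random_ref[160:]  # 16 nt duplication
        mutant = mutant[:121] + mutant[100:]  # 21 nt duplication
        read = mutant[85:225]  # spans both junctions (121 and 197)
        _, events = process_read("double", read, ref_index, PARAMS)
        assert sorted((e.kind, e.size, e.ref_start) for e in events) == [
            ("duplication", 16, 160),
            ("duplication", 21, 100),
        ]

    def test_clean_case_break_width_equals_k(self, random_ref, ref_index):
        """Without junction insertion/overlap, j2 - j1 + 2 == k for the called break."""
        start, length = 140, 30
        assert random_ref[start] != random_ref[start + length]  # no junction overlap
        read = _dup_read(random_ref, start, length)
        _, events = process_read("clean", read, ref_index, PARAMS)
        (event,) = events
        j1, j2 = event.break_span
        assert j2 - j1 + 2 == ref_index.k
        assert event.size == event.left_flank_pos - event.right_flank_pos + ref_index.k

    @pytest.mark.parametrize("n_inserted", [1, 2, 3])
    def test_each_junction_insertion_adds_one(self, random_ref, ref_index, n_inserted):
        """Bases inserted at the junction grow the indel size one-for-one."""
        insert = "ACG"[:n_inserted]
        read = _dup_read(random_ref, 140, 30, insert=insert)
        _, events = process_read("ins", read, ref_index, PARAMS)
        assert len(events) == 1
        assert events[0].size == 30 + n_inserted

    def test_substitution_shift_invariance(self, random_ref, ref_index):
        """A substitution within k nt of the breakpoint must not change the size."""
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        clean = _dup_read(random_ref, 140, 30)
        for side in ("left", "right"):
            for offset in range(1, ref_index.k):
                bases = list(clean)
                pos = 60 - offset if side == "left" else 60 + offset - 1
                bases[pos] = sub[bases[pos]]
                _, events = process_read(f"{side}{offset}", "".join(bases), ref_index, PARAMS)
                dups = [e for e in events if e.kind == "duplication"]
                assert [e.size for e in dups] == [30], (side, offset)

    def test_determinism(self, random_ref, ref_index):
        rng = np.random.default_rng(13)
        reads = []
        mutant = random_ref[:170] + random_ref[140:]
        for i in range(40):
            hap = mutant if i % 3 == 0 else random_ref
            start = int(rng.integers(0, len(hap) - 120 + 1))
            reads.append((f"r{i}", hap[start : start + 120]))
        first = [process_read(rid, seq, ref_index, PARAMS)[1] for rid, seq in reads]
        second = [process_read(rid, seq, ref_index, PARAMS)[1] for rid, seq in reads]
        assert first == second
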