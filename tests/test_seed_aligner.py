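"""Seed search, ungapped extension rules, and the two alignment scores."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from isomirsea import (
    AlignmentParams,
    Alignment,
    MatureRecord,
    align_score,
    align_tag,
    align_tag_detailed,
    build_seed_index,
    extend_ungapped,
    find_seed_anchors,
    mirtag_diff,
)
from isomirsea.seed_aligner import REASON_MISMATCH_WINDOW, Rejection, SeedAnchor

from conftest import REF_SEQ, substitute


class TestScores:
    @pytest.mark.parametrize(
        "mir,aln,gaps,expected",
        [
            (22, 22, 0, 0.0),
            (26, 21, 0, pytest.approx(19.230769, abs=1e-5)),
            (26, 20, 0, pytest.approx(23.076923, abs=1e-5)),
        ],
    )
    def test_align_score(self, mir, aln, gaps, expected):
        assert align_score(mir, aln, gaps) == expected

    def test_align_score_rejects_zero_mir_size(self):
        with pytest.raises(ValueError):
            align_score(0, 10, 0)

    @pytest.mark.parametrize("mir,tag,expected", [(22, 22, 0), (26, 21, 5), (20, 24, -4)])
    def test_mirtag_diff_sign_convention(self, mir, tag, expected):
        assert mirtag_diff(mir, tag) == expected

    def test_score_decreases_as_span_grows(self):
        scores = [align_score(22, n, 0) for n in range(11, 23)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestFindSeedAnchors:
    def test_exact_tag_places_seed_at_mirna_position(self, mature, single_index, params):
        anchors = find_seed_anchors(mature.sequence, single_index, params)
        assert [a.seed_pos_in_tag for a in anchors] == [2]

    def test_5p_addition_shifts_anchor(self, mature, single_index, params):
        tag = "GG" + mature.sequence
        anchors = find_seed_anchors(tag, single_index, params)
        assert [a.seed_pos_in_tag for a in anchors] == [4]
        aln = extend_ungapped(tag, mature, anchors[0], params)
        assert isinstance(aln, Alignment) and aln.offset_5p == 2

    def test_lost_seed_nucleotide_means_no_anchor(self, mature, single_index, params):
        tag = mature.sequence[3:]  # seed nt 2 gone
        assert find_seed_anchors(tag, single_index, params) == []
        assert align_tag(tag, single_index, params) == []


class TestExtendUngapped:
    def test_identity_alignment(self, mature, params):
        aln = extend_ungapped(mature.sequence, mature, SeedAnchor(mature, 2), params)
        assert isinstance(aln, Alignment)
        assert aln.align_size == 22
        assert aln.mismatch_positions == ()
        assert aln.delta_3p == 0 and aln.overhang_3p == 0
        assert aln.align_score == 0.0 and aln.mirtag_diff == 0

    def test_two_close_mismatches_rejected_by_window(self, mature, params):
        tag = substitute(substitute(mature.sequence, 9), 15)  # distance 6 <= 10
        result = extend_ungapped(tag, mature, SeedAnchor(mature, 2), params)
        assert isinstance(result, Rejection)
        assert result.reason == REASON_MISMATCH_WINDOW

    def test_two_distant_mismatches_accepted(self, mature, params):
        tag = substitute(substitute(mature.sequence, 9), 21)  # distance 12 > 10
        aln = extend_ungapped(tag, mature, SeedAnchor(mature, 2), params)
        assert isinstance(aln, Alignment)
        assert aln.mismatch_positions == (9, 21)
        assert aln.identity_pct == pytest.approx(100 * 20 / 22, abs=1e-6)

    def test_third_mismatch_truncates_into_overhang(self, mature, params):
        # mismatches at 9, 20, and 22: extension stops before position 22
        tag = substitute(substitute(substitute(mature.sequence, 9), 20), 22)
        # 9 and 20 are 11 apart (> window); the third stops the extension
        aln = extend_ungapped(tag, mature, SeedAnchor(mature, 2), params)
        assert isinstance(aln, Alignment)
        assert aln.mismatch_positions == (9, 20)
        assert aln.mir_end == 21
        assert aln.overhang_3p == 1
        assert aln.delta_3p == 0  # tag still reaches the mature 3' end

    def test_mismatch_at_position_1_is_allowed_and_counted(self, mature, params):
        tag = substitute(mature.sequence, 1)
        aln = extend_ungapped(tag, mature, SeedAnchor(mature, 2), params)
        assert isinstance(aln, Alignment)
        assert aln.mismatch_positions == (1,)


class TestAlignTag:
    def test_family_sharing_yields_one_alignment_per_reference(self, make_index, params):
        a = MatureRecord("hsa-a", "hsa", REF_SEQ)
        b = MatureRecord("hsa-b", "hsa", substitute(REF_SEQ, 20))  # same seed, 3' variant
        idx = make_index(a, b)
        alns = align_tag(REF_SEQ, idx, params)
        assert sorted(x.mature_id for x in alns) == ["hsa-a", "hsa-b"]

    def test_no_seed_in_window_is_discarded(self, single_index, params):
        result = align_tag_detailed("T" * 22, single_index, params)
        assert result.alignments == []
        assert result.rejection_reason == "no_seed"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(rng_seed=st.integers(min_value=0, max_value=10**9))
    def test_seed_never_carries_a_mismatch(self, rng_seed):
        params = AlignmentParams()
        rng = random.Random(rng_seed)
        mat = MatureRecord("hsa-r", "hsa", "".join(rng.choice("ACGT") for _ in range(22)))
        idx = build_seed_index([mat], params)
        tag = list(mat.sequence)
        for _ in range(rng.randint(0, 5)):
            i = rng.randrange(len(tag))
            tag[i] = rng.choice("ACGT")
        for aln in align_tag("".join(tag), idx, params):
            assert not any(
                params.seed_start <= p <= params.seed_end
                for p in aln.mismatch_positions
            )
            assert aln.align_size >= params.min_align_len
            assert len(aln.mismatch_positions) <= params.max_mismatches

    def test_reverse_symmetry_of_identity(self, params):
        """Reversing both sequences preserves mismatch count of a full-span
        pairing: the coordinate labels flip but the paired columns do not."""
        rng = random.Random(5)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(22))
            mat = MatureRecord("hsa-r", "hsa", seq)
            tag = substitute(seq, rng.randint(8, 22), rng)
            aln = extend_ungapped(tag, mat, SeedAnchor(mat, 2), params)
            if not isinstance(aln, Alignment):
                continue
            n_fwd = sum(1 for a, b in zip(seq, tag) if a != b)
            n_rev = sum(1 for a, b in zip(seq[::-1], tag[::-1]) if a != b)
            assert n_fwd == n_rev == len(aln.mismatch_positions)
            mirrored = tuple(sorted(23 - p for p in aln.mismatch_positions))
            assert len(mirrored) == len(aln.mismatch_positions)
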