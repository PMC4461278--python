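import numpy as np
import pytest

from amperr.align import AlignmentResult
from amperr.io import AmpliconReference, QualityRead
from amperr.profile import (ErrorProfile, ExclusionPolicy, accumulate,
                            build_exclusion_mask, classify_transitions, rates,
                            run_lengths, substitution_matrix)


def _ref(seq, name="amp", mask=None):
    if mask is None:
        mask = build_exclusion_mask(seq)
    return AmpliconReference(name, seq, mask)


def _read(seq):
    return QualityRead("r", seq, np.full(len(seq), 38, np.uint8))


def _aln(ops, ref_name="amp", strand="+", ref_start=0):
    ref_span = sum(ops.count(c) for c in "MXD")
    return AlignmentResult("r", ref_name, strand, ref_start, ref_start + ref_span,
                           ops, 0, True)


class TestExclusionMask:
    def test_neutral_sequence_nothing_excluded(self):
        assert not build_exclusion_mask("ACGTACGTACGT").any()

    def test_homopolymer_run_of_four(self):
        mask = build_exclusion_mask("AAAATCG")
        assert mask.tolist() == [True] * 4 + [False] * 3

    def test_all_g_excluded_by_both_rules(self):
        assert build_exclusion_mask("G" * 10).all()

    def test_gc_rich_window(self):
        # 8 of 10 GC in the window, no run >= 4
        seq = "GCGGCAGCGT" + "ATATATATAT"
        mask = build_exclusion_mask(seq)
        assert mask[:10].all() and not mask[10:].any()

    def test_run_threshold_configurable(self):
        seq = "AAATCG"
        assert not build_exclusion_mask(seq).any()
        assert build_exclusion_mask(seq, ExclusionPolicy(homopolymer_min_run=3))[:3].all()

    def test_run_lengths(self):
        assert run_lengths("AACGGG").tolist() == [2, 2, 1, 3, 3, 3]


class TestAccumulate:
    def test_all_match_alignment(self):
        ref = _ref("ACGT" * 25)
        prof = accumulate(ErrorProfile(), _aln("M" * 100), ref, _read(ref.seq))
        assert prof.aligned_bases == 100 and prof.aligned_reads == 1
        assert prof.subst_bases == 0 and prof.indel_bases == 0
        assert prof.per_base_totals.sum() == 100

    def test_substitution_enters_matrix(self):
        ref = _ref("ACGT" * 25)
        read = "G" + ref.seq[1:]  # ref A read G at position 0
        prof = accumulate(ErrorProfile(), _aln("X" + "M" * 99), ref, _read(read))
        assert prof.subst_bases == 1
        assert prof.subst_matrix_counts[0, 2] == 1  # A -> G

    def test_excluded_substitution_counts_for_rate_not_matrix(self):
        ref = _ref("AAAA" + "TCGA" * 24)  # positions 0-3 excluded
        read = "T" + ref.seq[1:]
        prof = accumulate(ErrorProfile(), _aln("X" + "M" * 99), ref, _read(read))
        assert prof.subst_bases == 1
        assert prof.subst_matrix_counts.sum() == 0
        # excluded matches also stay out of the denominators
        assert prof.per_base_totals.sum() == 96

    def test_read_n_column_never_a_substitution(self):
        ref = _ref("ACGT" * 25)
        read = "N" + ref.seq[1:]
        prof = accumulate(ErrorProfile(), _aln("M" * 100), ref, _read(read))
        assert prof.subst_bases == 0 and prof.masked_cols == 1
        assert prof.aligned_bases == 100
        assert prof.per_base_totals.sum() == 99

    def test_indels_counted_in_bases(self):
        ref = _ref("ACGT" * 25)
        ops = "M" * 40 + "III" + "M" * 30 + "D" + "M" * 29
        read_seq = ref.seq[:40] + "AAA" + ref.seq[40:70] + ref.seq[71:]
        prof = accumulate(ErrorProfile(), _aln(ops), ref, _read(read_seq))
        assert prof.ins_bases == 3 and prof.ins_events == 1
        assert prof.del_bases == 1 and prof.del_events == 1
        assert prof.aligned_bases == 99

    def test_reference_span_mismatch_is_hard_error(self):
        ref = _ref("ACGT" * 25)
        bad = AlignmentResult("r", "amp", "+", 0, 50, "M" * 100, 0, True)
        with pytest.raises(ValueError, match="span"):
            accumulate(ErrorProfile(), bad, ref, _read(ref.seq))

    def test_per_amplicon_counters_sum_to_pooled(self):
        refs = [_ref("ACGT" * 25, "a1"), _ref("TTGCA" * 20, "a2")]
        prof = ErrorProfile()
        accumulate(prof, _aln("M" * 100, "a1"), refs[0], _read(refs[0].seq))
        accumulate(prof, _aln("X" + "M" * 99, "a2"), refs[1], _read("A" + refs[1].seq[1:]))
        for field in ("aligned_bases", "aligned_reads", "subst_bases", "ins_bases", "del_bases"):
            pooled = getattr(prof, field)
            assert pooled == sum(getattr(p, field) for p in prof.per_amplicon.values())


class TestRates:
    def test_textbook_arithmetic(self):
        prof = ErrorProfile(aligned_bases=1000, aligned_reads=10, subst_bases=5,
                            ins_bases=2, del_bases=0)
        r = rates(prof)
        assert r["subst_pct"] == pytest.approx(0.50)
        assert r["indel_pct"] == pytest.approx(0.20)
        assert r["subs_per_read"] == pytest.approx(0.5)

    def test_zero_reads_flagged_undefined(self):
        r = rates(ErrorProfile())
        assert r["defined"] is False
        assert r["subst_pct"] == 0.0 and r["indels_per_read"] == 0.0


class TestSubstitutionMatrix:
    def test_single_cell(self):
        prof = ErrorProfile()
        prof.per_base_totals[:] = [1000, 1, 1, 1]
        prof.subst_matrix_counts[0, 2] = 2
        matrix, totals, base_totals = substitution_matrix(prof)
        assert matrix[0, 2] == pytest.approx(0.20)
        assert totals[0] == pytest.approx(0.20)
        assert np.isnan(matrix[0, 0])

    def test_zero_substitutions_all_zero(self):
        prof = ErrorProfile()
        prof.per_base_totals[:] = 100
        matrix, totals, _ = substitution_matrix(prof)
        off = ~np.eye(4, dtype=bool)
        assert (matrix[off] == 0).all() and (totals == 0).all()

    def test_zero_denominator_row_undefined(self):
        prof = ErrorProfile()
        prof.per_base_totals[:] = [100, 0, 100, 100]
        matrix, totals, _ = substitution_matrix(prof)
        assert np.isnan(matrix[1]).all() and np.isnan(totals[1])

    def test_row_total_is_exact_offdiagonal_sum(self):
        rng = np.random.default_rng(6)
        prof = ErrorProfile()
        prof.per_base_totals[:] = rng.integers(500, 2000, 4)
        prof.subst_matrix_counts[:] = rng.integers(0, 30, (4, 4))
        np.fill_diagonal(prof.subst_matrix_counts, 0)
        matrix, totals, _ = substitution_matrix(prof)
        for i in range(4):
            expect = sum(matrix[i, j] for j in range(4) if j != i)
            assert totals[i] == pytest.approx(expect, abs=0)


class TestTransitions:
    def test_single_transition_entry(self):
        m = np.zeros((4, 4))
        m[0, 2] = 0.04  # A -> G
        out = classify_transitions(m)
        assert out["transition_rate"] == pytest.approx(0.01)
        assert out["transversion_rate"] == 0.0

    def test_uniform_matrix_equal_rates(self):
        m = np.full((4, 4), 0.05)
        np.fill_diagonal(m, np.nan)
        out = classify_transitions(m)
        assert out["transition_rate"] == pytest.approx(0.05)
        assert out["transversion_rate"] == pytest.approx(0.05)
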