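"""Conversion counting, editing profiles, indel frequency, QC filter."""

import numpy as np
import pytest

from bewindow.alignment import AmpliconAligner
from bewindow.quantify import (amplicon_qc_filter, build_conversion_matrix,
                               editing_profile, indel_frequency)
from bewindow.targets import to_amplicon_coord, reference_base, revcomp

Q38 = lambda n: np.full(n, 38, dtype=np.int16)


def aligned(target, seqs, quals=None):
    aligner = AmpliconAligner(target)
    out = []
    for i, s in enumerate(seqs):
        q = Q38(len(s)) if quals is None else quals[i]
        ar = aligner.align(s, q, f"r{i}")
        assert ar is not None
        out.append(ar)
    return out


def edit_at(target, positions):
    """Amplicon copy carrying the intended conversion at given positions."""
    seq = list(target.amplicon_seq)
    prod = target.product_base if target.protospacer_strand == "+" \
        else revcomp(target.product_base)
    for p in positions:
        seq[to_amplicon_coord(target, p)] = prod
    return "".join(seq)


class TestConversionMatrix:
    def test_clean_reads_all_reference(self, cbe_target):
        ars = aligned(cbe_target, [cbe_target.amplicon_seq] * 10)
        matrix = build_conversion_matrix(ars, cbe_target)
        assert matrix.total_reads == 10
        for p in range(1, 21):
            ref = reference_base(cbe_target, p)
            assert matrix.base_counts[p - 1, "ACGT".index(ref)] == 10
            assert matrix.masked[p - 1] == 0

    def test_constructed_counts_at_position_6(self, cbe_target):
        # position 6 reference is A on this target; use position 5 (C)
        edited = edit_at(cbe_target, [5])
        ars = aligned(cbe_target, [cbe_target.amplicon_seq] * 6 + [edited] * 4)
        matrix = build_conversion_matrix(ars, cbe_target)
        assert matrix.base_counts[4, "ACGT".index("C")] == 6
        assert matrix.base_counts[4, "ACGT".index("T")] == 4

    def test_low_quality_bases_masked(self, cbe_target):
        amp = cbe_target.amplicon_seq
        q = Q38(len(amp))
        q[to_amplicon_coord(cbe_target, 5)] = 20  # below -b 30 analog
        ars = aligned(cbe_target, [amp], [q])
        matrix = build_conversion_matrix(ars, cbe_target, min_base_qual=30)
        assert matrix.masked[4] == 1
        assert matrix.base_counts[4].sum() == 0

    def test_n_bases_always_masked(self, cbe_target):
        amp = list(cbe_target.amplicon_seq)
        amp[to_amplicon_coord(cbe_target, 5)] = "N"
        ars = aligned(cbe_target, ["".join(amp)])
        matrix = build_conversion_matrix(ars, cbe_target)
        assert matrix.masked[4] == 1

    def test_conservation_invariant(self, cbe_target):
        amp = cbe_target.amplicon_seq
        reads = [amp, amp[:40] + amp[42:], amp[10:95], edit_at(cbe_target, [4, 5])]
        matrix = build_conversion_matrix(aligned(cbe_target, reads), cbe_target)
        sums = matrix.base_counts.sum(axis=1) + matrix.deletions + matrix.masked
        assert (sums == matrix.total_reads).all()

    def test_partial_coverage_counts_as_masked(self, cbe_target):
        read = cbe_target.amplicon_seq[45:]  # misses protospacer 1..15
        matrix = build_conversion_matrix(aligned(cbe_target, [read]), cbe_target)
        assert matrix.masked[:15].sum() == 15

    def test_strand_invariance(self, cbe_target):
        """The same physical molecules on the flipped amplicon give the
        same protospacer-frame counts."""
        from bewindow.targets import AmpliconTarget
        flipped = AmpliconTarget("m", revcomp(cbe_target.amplicon_seq), 70,
                                 "-", "CBE", cbe_target.intended_positions)
        molecules = [cbe_target.amplicon_seq] * 3 + [edit_at(cbe_target, [4])] * 2
        m_plus = build_conversion_matrix(aligned(cbe_target, molecules), cbe_target)
        m_minus = build_conversion_matrix(
            aligned(flipped, [revcomp(s) for s in molecules]), flipped)
        assert (m_plus.base_counts == m_minus.base_counts).all()
        f_plus = editing_profile(m_plus, cbe_target).freqs
        f_minus = editing_profile(m_minus, flipped).freqs
        np.testing.assert_array_equal(f_plus, f_minus)


class TestEditingProfile:
    def test_simple_ratio(self, cbe_target):
        reads = [cbe_target.amplicon_seq] * 6 + [edit_at(cbe_target, [5])] * 4
        matrix = build_conversion_matrix(aligned(cbe_target, reads), cbe_target)
        prof = editing_profile(matrix, cbe_target)
        assert prof.freqs[4] == pytest.approx(0.4)

    def test_non_editable_positions_not_applicable(self, cbe_target):
        matrix = build_conversion_matrix(
            aligned(cbe_target, [cbe_target.amplicon_seq]), cbe_target)
        prof = editing_profile(matrix, cbe_target)
        editable = set(cbe_target.editable_positions())
        for p in range(1, 21):
            assert np.isnan(prof.freqs[p - 1]) == (p not in editable)

    def test_zero_denominator_undefined_not_zero(self, cbe_target):
        read = cbe_target.amplicon_seq[45:]  # position 1 uncovered
        matrix = build_conversion_matrix(aligned(cbe_target, [read]), cbe_target)
        prof = editing_profile(matrix, cbe_target)
        assert np.isnan(prof.freqs[0])
        assert prof.denominators[0] == 0


class TestIndelFrequency:
    def test_counting(self, cbe_target):
        amp = cbe_target.amplicon_seq
        with_del = amp[:40] + amp[42:]
        reads = [amp] * 97 + [with_del] * 3
        freq = indel_frequency(aligned(cbe_target, reads), cbe_target)
        assert freq == pytest.approx(0.03)

    def test_indel_outside_protospacer_excluded(self, cbe_target):
        amp = cbe_target.amplicon_seq
        outside = amp[:10] + amp[12:]  # deletion at offsets 10-11, protospacer at 30
        freq = indel_frequency(aligned(cbe_target, [amp, outside]), cbe_target)
        assert freq == 0.0

    def test_insertion_in_protospacer_counts(self, cbe_target):
        amp = cbe_target.amplicon_seq
        with_ins = amp[:40] + "TAT" + amp[40:]
        freq = indel_frequency(aligned(cbe_target, [amp, with_ins]), cbe_target)
        assert freq == pytest.approx(0.5)

    def test_no_reads_undefined(self, cbe_target):
        assert indel_frequency([], cbe_target) is None


class TestQcFilter:
    def test_threshold(self):
        retained, report = amplicon_qc_filter({"a": 900}, min_reads=1000)
        assert retained == [] and report[0]["sample"] == "a"

    def test_disabled_filter_retains_all(self):
        retained, report = amplicon_qc_filter({"a": 0, "b": 5}, min_reads=0)
        assert retained == ["a", "b"] and report == []

    def test_batch_counting(self):
        retained, report = amplicon_qc_filter(
            {"a": 500, "b": 1500, "c": 2000}, min_reads=1000)
        assert retained == ["b", "c"] and len(report) == 1
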