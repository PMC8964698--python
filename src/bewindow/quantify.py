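"""Per-position base counts, editing frequencies, and indel frequency.

This is the counting layer: accepted alignments are tallied into a
per-protospacer-position matrix of base observations (protospacer-strand
frame), with base calls below ``min_base_qual`` masked (the bam-readcount
``-b 30`` analog) and whole reads below an alignment-quality gate excluded
(the ``-q 20`` analog, realised as a minimum identity / score fraction for
single-amplicon data).  Editing frequencies use position-specific
denominators because masking varies by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import (AmpliconTarget, PROTOSPACER_LEN, to_amplicon_coord,
                      reference_base)

__all__ = [
    "ConversionMatrix",
    "EditingProfile",
    "build_conversion_matrix",
    "editing_profile",
    "indel_frequency",
    "amplicon_qc_filter",
]

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
_COMP_INDEX = np.array([_BASE_INDEX[b] for b in "TGCA"])  # complement permutation


@dataclass
class ConversionMatrix:
    """Counts of observed bases per protospacer position (1..20).

    ``base_counts[p-1, j]`` counts base ``"ACGT"[j]`` on the protospacer
    strand; ``deletions`` counts reads whose alignment deletes the position;
    ``masked`` counts low-quality, ambiguous, or non-covering observations.
    For every position, base counts + deletions + masked equal
    ``total_reads``.
    """

    target_name: str
    base_counts: np.ndarray  # (20, 4) int64
    deletions: np.ndarray    # (20,)
    masked: np.ndarray       # (20,)
    insertions: np.ndarray   # (20,) reads with an insertion anchored 3' of p
    total_reads: int
    indel_reads: int         # reads with any indel touching the protospacer

    def check_conservation(self):
        sums = self.base_counts.sum(axis=1) + self.deletions + self.masked
        if not np.all(sums == self.total_reads):
            raise AssertionError("per-position counts do not sum to total reads")

    def to_frame(self, target: AmpliconTarget) -> pd.DataFrame:
        """Long TSV-ready table: one row per protospacer position."""
        rows = []
        profile = editing_profile(self, target)
        for p in range(1, PROTOSPACER_LEN + 1):
            rows.append({
                "position": p,
                "ref_base": reference_base(target, p),
                **{b: int(self.base_counts[p - 1, _BASE_INDEX[b]]) for b in _BASE_ORDER},
                "del": int(self.deletions[p - 1]),
                "masked": int(self.masked[p - 1]),
                "insertion_adjacent": int(self.insertions[p - 1]),
                "denominator": int(profile.denominators[p - 1]),
                "freq": profile.freqs[p - 1],
            })
        return pd.DataFrame(rows)


@dataclass
class EditingProfile:
    """Per-position intended-conversion frequency for one sample.

    ``freqs[p-1]`` is NaN at positions whose reference base is not the
    editor substrate (not applicable) and at editable positions with a zero
    denominator (undefined).
    """

    editor: str
    freqs: np.ndarray         # (20,) float, NaN where undefined/not applicable
    denominators: np.ndarray  # (20,) int
    label: str = ""
    replicate: int = 0

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.freqs)


def _protospacer_offsets(target: AmpliconTarget) -> np.ndarray:
    return np.array([to_amplicon_coord(target, p)
                     for p in range(1, PROTOSPACER_LEN + 1)])


def build_conversion_matrix(alignments, target: AmpliconTarget,
                            min_base_qual: int = 30,
                            min_align_score_frac: float = 0.0) -> ConversionMatrix:
    """Tally accepted alignments into a :class:`ConversionMatrix`.

    ``min_base_qual`` masks individual base calls; ``min_align_score_frac``
    (fraction of the maximum attainable score, i.e. match * read length)
    excludes whole reads.  Ambiguous bases (N) are always masked.  All counts
    are reported in the protospacer-strand frame.
    """
    offs = _protospacer_offsets(target)
    footprint_lo, footprint_hi = int(offs.min()), int(offs.max())
    base_counts = np.zeros((PROTOSPACER_LEN, 4), dtype=np.int64)
    deletions = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    masked = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    insertions = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    total = 0
    indel_reads = 0

    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i

    for ar in alignments:
        if min_align_score_frac and ar.score < min_align_score_frac * 2.0 * len(ar.seq):
            continue
        total += 1
        read_arr = np.frombuffer(ar.seq.encode("ascii"), dtype=np.uint8)
        idx = ar.read_index_of[offs]
        covered = idx >= 0
        deleted = idx == -2
        b_idx = np.full(PROTOSPACER_LEN, -1, dtype=np.int8)
        b_idx[covered] = code[read_arr[idx[covered]]]
        qual_ok = np.zeros(PROTOSPACER_LEN, dtype=bool)
        qual_ok[covered] = ar.qual[idx[covered]] >= min_base_qual
        good = covered & qual_ok & (b_idx >= 0)
        if target.protospacer_strand == "-":
            b_idx[good] = _COMP_INDEX[b_idx[good]]
        np.add.at(base_counts, (np.flatnonzero(good), b_idx[good]), 1)
        deletions[deleted] += 1
        masked[~good & ~deleted] += 1

        has_indel = bool(deleted.any())
        for anchor, _length in ar.insertion_anchors:
            if footprint_lo <= anchor <= footprint_hi + 1:
                has_indel = True
                # attribute to the gap immediately 3' of p on the protospacer strand
                if target.protospacer_strand == "+":
                    p = anchor - target.protospacer_start  # insertion after position p
                else:
                    p = PROTOSPACER_LEN - (anchor - target.protospacer_start)
                if 1 <= p <= PROTOSPACER_LEN:
                    insertions[p - 1] += 1
        if has_indel:
            indel_reads += 1

    matrix = ConversionMatrix(target.name, base_counts, deletions, masked,
                              insertions, total, indel_reads)
    matrix.check_conservation()
    return matrix


def editing_profile(matrix: ConversionMatrix, target: AmpliconTarget,
                    label: str = "", replicate: int = 0) -> EditingProfile:
    """Intended-conversion frequency f(p) at each editable position.

    f(p) = product-base count / (total - masked - deletion-spanning), defined
    only where the reference base is the editor substrate and the denominator
    is positive.
    """
    freqs = np.full(PROTOSPACER_LEN, np.nan)
    denoms = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    prod_idx = _BASE_INDEX[target.product_base]
    for p in range(1, PROTOSPACER_LEN + 1):
        if reference_base(target, p) != target.substrate_base:
            continue
        denom = matrix.total_reads - matrix.masked[p - 1] - matrix.deletions[p - 1]
        denoms[p - 1] = denom
        if denom > 0:
            freqs[p - 1] = matrix.base_counts[p - 1, prod_idx] / denom
    return EditingProfile(target.editor, freqs, denoms, label, replicate)


def indel_frequency(alignments, target: AmpliconTarget):
    """Fraction of accepted reads with >= 1 inserted/deleted base in the protospacer.

    Returns ``None`` (undefined) when there are no accepted alignments.
    """
    offs = _protospacer_offsets(target)
    lo, hi = int(offs.min()), int(offs.max())
    total = 0
    with_indel = 0
    for ar in alignments:
        total += 1
        idx = ar.read_index_of[offs]
        hit = bool((idx == -2).any())
        if not hit:
            hit = any(lo <= anchor <= hi + 1 for anchor, _ in ar.insertion_anchors)
        with_indel += hit
    if total == 0:
        return None
    return with_indel / total


def amplicon_qc_filter(read_totals: dict, min_reads: int = 0):
    """Drop samples whose accepted-read total falls below ``min_reads``.

    Parameters
    ----------
    read_totals : dict
        Mapping of sample id -> accepted read count.

    Returns
    -------
    retained : list of sample ids
    report : list of dict
        One record per excluded sample with the reason.
    """
    retained, report = [], []
    for sample, n in read_totals.items():
        if n < min_reads:
            report.append({"sample": sample, "reads": int(n),
                           "reason": f"fewer than {min_reads} accepted reads"})
        else:
            retained.append(sample)
    return retained, report
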