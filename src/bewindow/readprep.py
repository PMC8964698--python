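"""Paired-end FASTQ parsing and quality-aware overlap merging.

Amplicon inserts are short enough that the two reads of a pair overlap; a
pair is combined into a single consensus read when the best ungapped overlap
is at least ``min_overlap`` (default 11) bases.  At overlap columns where the
reads agree the consensus quality is the higher of the two Phred scores
(capped at 41); where they disagree the higher-quality base wins and the
consensus quality is the difference of the two scores.  Pairs without a
qualifying overlap are flagged unmerged and excluded downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from itertools import zip_longest

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .targets import revcomp

__all__ = ["ReadPair", "ConsensusRead", "read_fastq_pairs", "merge_pair", "merge_pairs"]

QUAL_CAP = 41
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FastqParseError(ValueError):
    """Malformed FASTQ record or R1/R2 record-count mismatch."""


@dataclass
class ReadPair:
    """One read pair; qualities are integer Phred arrays."""

    read_id: str
    r1_seq: str
    r1_qual: np.ndarray
    r2_seq: str
    r2_qual: np.ndarray

    def __post_init__(self):
        for seq, qual, end in ((self.r1_seq, self.r1_qual, "R1"),
                               (self.r2_seq, self.r2_qual, "R2")):
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{self.read_id}/{end}: sequence and quality lengths differ"
                )
            if len(qual) and int(qual.min()) < 0:
                raise FastqParseError(f"{self.read_id}/{end}: negative Phred score")


@dataclass
class ConsensusRead:
    """Merged pair: sequence, per-base Phred, and overlap diagnostics."""

    read_id: str
    seq: str
    qual: np.ndarray
    overlap_len: int
    n_disagreements: int


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _qual_array(qual_str: str) -> np.ndarray:
    return (np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33)


def read_fastq_pairs(path_r1, path_r2):
    """Yield :class:`ReadPair` from two matched FASTQ files (plain or gzip)."""
    with _open_maybe_gzip(path_r1) as h1, _open_maybe_gzip(path_r2) as h2:
        it = zip_longest(FastqGeneralIterator(h1), FastqGeneralIterator(h2))
        for i, (rec1, rec2) in enumerate(it):
            if rec1 is None or rec2 is None:
                raise FastqParseError(
                    f"record {i}: R1/R2 files have different record counts"
                )
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            if id1.split()[0].rstrip("/12") != id2.split()[0].rstrip("/12"):
                raise FastqParseError(f"record {i}: read ids {id1!r} / {id2!r} differ")
            yield ReadPair(id1.split()[0], seq1.upper(), _qual_array(q1),
                           seq2.upper(), _qual_array(q2))


def _onehot(seq_arr: np.ndarray) -> np.ndarray:
    # (4, L) float32; N (or any non-ACGT) is all-zero and never matches
    return (seq_arr[None, :] == _BASES[:, None]).astype(np.float32)


def merge_pair(pair: ReadPair, min_overlap: int = 11,
               max_mismatch_frac: float = 0.1):
    """Merge one pair into a consensus read, or return ``None`` if unmergeable.

    R2 is reverse-complemented into R1 orientation, every relative offset with
    an overlap of at least ``min_overlap`` bases is scored ungapped
    (match - mismatch), and the best-scoring offset whose overlap mismatch
    fraction is at most ``max_mismatch_frac`` is merged.  Ties prefer the
    longer overlap, then the smaller absolute offset.
    """
    r1 = np.frombuffer(pair.r1_seq.encode("ascii"), dtype=np.uint8)
    r2 = np.frombuffer(revcomp(pair.r2_seq).encode("ascii"), dtype=np.uint8)
    q1 = pair.r1_qual
    q2 = pair.r2_qual[::-1]
    n1, n2 = len(r1), len(r2)
    if min(n1, n2) < min_overlap:
        return None

    x = _onehot(r1)
    y = _onehot(r2)
    # matches[i] for shift d = i - (n2 - 1): number of agreeing overlap columns
    matches = np.zeros(n1 + n2 - 1, dtype=np.float32)
    for c in range(4):
        matches += np.correlate(x[c], y[c], "full")
    shifts = np.arange(n1 + n2 - 1) - (n2 - 1)
    ov_start = np.maximum(shifts, 0)
    ov_end = np.minimum(n1, shifts + n2)
    ov_len = ov_end - ov_start
    mismatches = ov_len - matches
    score = matches - mismatches

    ok = (ov_len >= min_overlap) & (mismatches <= max_mismatch_frac * ov_len)
    if not ok.any():
        return None
    cand = np.flatnonzero(ok)
    # lexicographic: score desc, overlap desc, |shift| asc
    order = np.lexsort((np.abs(shifts[cand]), -ov_len[cand], -score[cand]))
    best = cand[order[0]]
    d = int(shifts[best])
    n_dis = int(round(float(mismatches[best])))
    ov = int(ov_len[best])

    off1 = -min(d, 0)
    off2 = d - min(d, 0)
    length = max(n1 + off1, n2 + off2)
    seq = np.zeros(length, dtype=np.uint8)
    qual = np.zeros(length, dtype=np.int16)
    seq[off1:off1 + n1] = r1
    qual[off1:off1 + n1] = q1
    only2 = np.ones(length, dtype=bool)
    only2[off1:off1 + n1] = False
    idx2 = np.arange(off2, off2 + n2)
    sel = only2[idx2]
    seq[idx2[sel]] = r2[sel]
    qual[idx2[sel]] = q2[sel]

    # overlap columns, in merged coordinates
    lo = max(off1, off2)
    hi = min(off1 + n1, off2 + n2)
    a1 = slice(lo - off1, hi - off1)
    a2 = slice(lo - off2, hi - off2)
    b1, b2 = r1[a1], r2[a2]
    qq1, qq2 = q1[a1], q2[a2]
    agree = b1 == b2
    cons_b = np.where(qq1 >= qq2, b1, b2)
    cons_b[agree] = b1[agree]
    cons_q = np.where(agree,
                      np.minimum(np.maximum(qq1, qq2), QUAL_CAP),
                      np.abs(qq1 - qq2))
    seq[lo:hi] = cons_b
    qual[lo:hi] = cons_q

    return ConsensusRead(pair.read_id, seq.tobytes().decode("ascii"),
                         qual, ov, n_dis)


def merge_pairs(pairs, min_overlap: int = 11, max_mismatch_frac: float = 0.1):
    """Merge a stream of pairs; yields ``(pair, consensus_or_None)``."""
    for pair in pairs:
        yield pair, merge_pair(pair, min_overlap, max_mismatch_frac)
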