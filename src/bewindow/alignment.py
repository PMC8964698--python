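"""Targeted alignment of consensus reads to a single amplicon reference.

Amplicon data are single-locus, so genome mapping is replaced by pairwise
alignment against the known reference: global in the read, with free end
gaps in the amplicon (the read may cover any sub-interval), affine gap
penalties, both orientations tried.  Scoring defaults follow BWA-MEM-like
conventions (match +2, mismatch -4, gap open -6, gap extend -1; a gap of
length k costs 6 + k) so indel calls stay comparable with mapper-based
pipelines.  Reads whose identity (matches / read length) falls below
``min_identity`` are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .targets import AmpliconTarget, revcomp

__all__ = ["AlignedRead", "AmpliconAligner", "align_to_amplicon", "write_sam"]

#: sentinel values in the amplicon-offset -> read-index map
NOT_COVERED = -1
DELETED = -2


@dataclass
class AlignedRead:
    """A consensus read aligned to its amplicon.

    ``read_index_of[o]`` gives the 0-based read index aligned to amplicon
    offset ``o``, ``DELETED`` (-2) inside read deletions, and ``NOT_COVERED``
    (-1) outside the read's footprint.  ``insertion_anchors`` holds, for each
    read insertion, the amplicon offset immediately 3' (forward strand) of
    the inserted bases together with the inserted length.
    """

    read_id: str
    seq: str
    qual: np.ndarray
    orientation: str
    score: float
    identity: float
    read_index_of: np.ndarray
    insertion_anchors: tuple
    n_matches: int


class AmpliconAligner:
    """Affine-gap aligner for one amplicon, with per-sequence result caching.

    Amplicon reads are highly duplicated, so alignments are cached by read
    sequence; qualities are attached per read afterwards.
    """

    def __init__(self, target: AmpliconTarget, match: float = 2.0,
                 mismatch: float = -4.0, gap_open: float = -6.0,
                 gap_extend: float = -1.0, min_identity: float = 0.7):
        self.target = target
        self.min_identity = min_identity
        self.scoring = dict(match=match, mismatch=mismatch,
                            gap_open=gap_open, gap_extend=gap_extend)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        # library convention: length-k gap costs open + (k-1)*extend;
        # ours: open + k*extend
        aligner.open_gap_score = gap_open + gap_extend
        aligner.extend_gap_score = gap_extend
        # free end gaps in the query row = unaligned amplicon overhang;
        # the read itself stays globally aligned
        try:
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older attribute name
            aligner.query_end_gap_score = 0.0
        self._aligner = aligner
        self._amp = np.frombuffer(target.amplicon_seq.encode("ascii"), dtype=np.uint8)
        self._cache = {}
        self.n_rejected = 0

    def _align_oriented(self, seq: str):
        alignments = self._aligner.align(self.target.amplicon_seq, seq)
        aln = alignments[0]
        t_blocks, q_blocks = aln.aligned
        n = len(self.target.amplicon_seq)
        index_of = np.full(n, NOT_COVERED, dtype=np.int32)
        insertions = []
        prev_t, prev_q = None, None
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            if prev_t is not None:
                if q0 > prev_q:  # insertion in read, anchored at t0
                    insertions.append((int(t0), int(q0 - prev_q)))
                if t0 > prev_t and prev_q > 0 and q0 < len(seq):
                    index_of[prev_t:t0] = DELETED
            index_of[t0:t1] = np.arange(q0, q1, dtype=np.int32)
            prev_t, prev_q = t1, q1
        read_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        covered = index_of >= 0
        n_matches = int((self._amp[covered] == read_arr[index_of[covered]]).sum())
        return float(alignments.score), index_of, tuple(insertions), n_matches

    def _align_seq(self, seq: str):
        """Cacheable part: orientation choice, score, coordinate map."""
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        amp = self.target.amplicon_seq
        rc = revcomp(seq)
        score_fwd = self._aligner.score(amp, seq)
        score_rev = self._aligner.score(amp, rc)
        if score_rev > score_fwd:
            orientation, used = "-", rc
        else:
            orientation, used = "+", seq
        score, index_of, insertions, n_matches = self._align_oriented(used)
        identity = n_matches / max(len(seq), 1)
        result = (orientation, score, identity, index_of, insertions, n_matches)
        self._cache[seq] = result
        return result

    def align(self, seq: str, qual: np.ndarray, read_id: str = ""):
        """Align one read; returns :class:`AlignedRead` or ``None`` (rejected)."""
        if not seq:
            return None
        orientation, score, identity, index_of, insertions, n_matches = \
            self._align_seq(seq)
        if identity < self.min_identity:
            self.n_rejected += 1
            return None
        if orientation == "-":
            seq = revcomp(seq)
            qual = qual[::-1]
        return AlignedRead(read_id, seq, qual, orientation, score, identity,
                           index_of, insertions, n_matches)


def align_to_amplicon(read, target: AmpliconTarget, *, match: float = 2.0,
                      mismatch: float = -4.0, gap_open: float = -6.0,
                      gap_extend: float = -1.0, min_identity: float = 0.7):
    """One-shot alignment of a :class:`~bewindow.readprep.ConsensusRead`.

    Convenience wrapper over :class:`AmpliconAligner` (which should be reused
    when aligning many reads against the same target).
    """
    aligner = AmpliconAligner(target, match, mismatch, gap_open, gap_extend,
                              min_identity)
    return aligner.align(read.seq, read.qual, read.read_id)


def _cigar(aligned: AlignedRead, read_len: int):
    """CIGAR operations (pysam codes) from the coordinate map."""
    index_of = aligned.read_index_of
    covered = np.flatnonzero(index_of >= 0)
    start = int(covered[0])
    end = int(covered[-1]) + 1
    ins_at = dict(aligned.insertion_anchors)
    ops = []

    def push(op, length):
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    first_read = int(index_of[start])
    push(4, first_read)  # leading soft clip (read bases before footprint)
    o = start
    while o < end:
        if o in ins_at:
            push(1, ins_at[o])
        if index_of[o] >= 0:
            push(0, 1)
        else:
            push(2, 1)
        o += 1
    if end in ins_at:
        push(1, ins_at[end])
    last_read = int(index_of[covered[-1]])
    push(4, read_len - last_read - 1)  # trailing soft clip
    return start, ops


def write_sam(aligned_reads, target: AmpliconTarget, path):
    """Serialize accepted alignments as SAM with the amplicon as reference."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": target.name, "LN": len(target.amplicon_seq)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned_reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = ar.read_id or "read"
            seg.query_sequence = ar.seq
            seg.query_qualities = [int(q) for q in ar.qual]
            seg.flag = 16 if ar.orientation == "-" else 0
            seg.reference_id = 0
            pos, ops = _cigar(ar, len(ar.seq))
            seg.reference_start = pos
            seg.cigartuples = ops
            seg.mapping_quality = 60
            seg.set_tag("AS", int(ar.score))
            out.write(seg)
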