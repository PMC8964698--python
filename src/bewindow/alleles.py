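"""Allele enumeration and perfect-edit classification.

A read's allele is its observed sequence over the quantification region
(protospacer positions 1-20 by default), on the protospacer strand, with
deletions written as ``-`` and insertions appended as ``@p+SEQ`` tags.
Classification:

``perfect``
    exactly the intended conversion at every intended position, nothing
    else — no other substitution and no indel in the region;
``unedited``
    reference sequence, no indel;
``indel_allele``
    any inserted or deleted base in the region (takes precedence);
``imperfect_edit``
    any other substitution pattern (bystander edits, missing intended
    edits, or non-intended products at intended positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import (AmpliconTarget, PROTOSPACER_LEN, to_amplicon_coord,
                      reference_base, revcomp)

__all__ = ["AlleleRecord", "AlleleTable", "call_alleles", "classify_allele",
           "perfect_edit_summary"]

CLASSES = ("perfect", "unedited", "imperfect_edit", "indel_allele")

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AlleleRecord:
    allele_seq: str
    count: int
    frequency: float
    classification: str
    edit_calls: tuple  # ((position, ref_base, observed_base), ...)


@dataclass
class AlleleTable:
    """Distinct alleles over the quantification region, most frequent first."""

    target_name: str
    region: tuple
    total_reads: int            # reads entering allele calling
    dropped_masked: int         # reads dropped for masked/uncovered region bases
    records: list
    other_count: int = 0        # reads in alleles below min_allele_count

    @property
    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASSES}
        for rec in self.records:
            counts[rec.classification] += rec.count
        return counts

    def _frac(self, num, denom):
        return num / denom if denom > 0 else None

    @property
    def perfect_of_total(self):
        return self._frac(self.class_counts["perfect"], self.total_reads)

    @property
    def edited_of_total(self):
        cc = self.class_counts
        edited = cc["perfect"] + cc["imperfect_edit"] + cc["indel_allele"]
        return self._frac(edited, self.total_reads)

    @property
    def perfect_of_edited(self):
        cc = self.class_counts
        edited = cc["perfect"] + cc["imperfect_edit"] + cc["indel_allele"]
        return self._frac(cc["perfect"], edited)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "allele": rec.allele_seq,
            "count": rec.count,
            "frequency": rec.frequency,
            "class": rec.classification,
            "edits": ";".join(f"{p}{r}>{o}" for p, r, o in rec.edit_calls),
        } for rec in self.records]
        return pd.DataFrame(rows)


def classify_allele(edit_calls, indel_flag: bool, target: AmpliconTarget) -> str:
    """Classify one allele from its substitution calls and indel status."""
    if indel_flag:
        return "indel_allele"
    calls = frozenset((int(p), r, o) for p, r, o in edit_calls)
    if not calls:
        return "unedited"
    intended = frozenset(
        (p, target.substrate_base, target.product_base)
        for p in sorted(target.intended_positions)
    )
    if intended and calls == intended:
        return "perfect"
    return "imperfect_edit"


def call_alleles(alignments, target: AmpliconTarget, region=(1, PROTOSPACER_LEN),
                 min_base_qual: int = 30, min_allele_count: int = 1) -> AlleleTable:
    """Aggregate accepted alignments into an :class:`AlleleTable`.

    Reads with any masked (low-quality, ambiguous, or uncovered) base inside
    the region are dropped from allele calling and counted separately;
    alleles seen fewer than ``min_allele_count`` times are pooled into an
    "other" bin (summary fractions are computed before pooling).
    """
    lo, hi = int(region[0]), int(region[1])
    if not (1 <= lo <= hi <= PROTOSPACER_LEN + 3):
        raise ValueError("allele region must lie within protospacer positions 1..23")
    positions = list(range(lo, hi + 1))
    offs = np.array([to_amplicon_coord(target, p) for p in positions])
    ref_bases = [reference_base(target, p) for p in positions]
    minus = target.protospacer_strand == "-"
    span_lo, span_hi = int(offs.min()), int(offs.max())

    counter = {}
    dropped = 0
    total = 0
    for ar in alignments:
        idx = ar.read_index_of[offs]
        if (idx == -1).any():
            dropped += 1
            continue
        chars = []
        calls = []
        masked = False
        for k, p in enumerate(positions):
            ri = idx[k]
            if ri == -2:
                chars.append("-")
                continue
            base = ar.seq[ri]
            if minus:
                base = base.translate(_COMP)
            if base not in "ACGT" or ar.qual[ri] < min_base_qual:
                masked = True
                break
            chars.append(base)
            if base != ref_bases[k]:
                calls.append((p, ref_bases[k], base))
        if masked:
            dropped += 1
            continue
        ins_tags = []
        has_del = bool((idx == -2).any())
        for anchor, length in ar.insertion_anchors:
            if span_lo <= anchor <= span_hi + 1:
                ins_tags.append((anchor, length))
        allele = "".join(chars)
        if ins_tags:
            allele += "".join(f"@{a}+{n}" for a, n in sorted(ins_tags))
        indel_flag = has_del or bool(ins_tags)
        key = (allele, tuple(calls), indel_flag)
        counter[key] = counter.get(key, 0) + 1
        total += 1

    records = []
    other = 0
    for (allele, calls, indel_flag), count in counter.items():
        cls = classify_allele(calls, indel_flag, target)
        if count < min_allele_count:
            other += count
            continue
        records.append(AlleleRecord(allele, count, count / total, cls, calls))
    records.sort(key=lambda r: (-r.count, r.allele_seq))
    table = AlleleTable(target.name, (lo, hi), total, dropped, records, other)
    return table


def perfect_edit_summary(control: AlleleTable, treated: AlleleTable,
                         freq_floor: float = 0.0) -> dict:
    """Compare perfect-allele fractions between conditions.

    Reports perfect-of-total and perfect-of-edited per condition, the fold
    change of perfect-of-total (treated / control), and the number of
    distinct imperfect genotypes above ``freq_floor`` in each condition.
    ``None`` marks undefined quantities (zero denominators).
    """
    if control.target_name != treated.target_name:
        raise ValueError("allele tables come from different targets")

    def n_imperfect(table):
        return sum(1 for rec in table.records
                   if rec.classification in ("imperfect_edit", "indel_allele")
                   and rec.frequency >= freq_floor)

    pc, pt = control.perfect_of_total, treated.perfect_of_total
    fold = None
    if pc is not None and pt is not None and pc > 0:
        fold = pt / pc
    return {
        "control": {
            "perfect_of_total": pc,
            "perfect_of_edited": control.perfect_of_edited,
            "edited_of_total": control.edited_of_total,
            "n_imperfect_genotypes": n_imperfect(control),
            "total_reads": control.total_reads,
        },
        "treated": {
            "perfect_of_total": pt,
            "perfect_of_edited": treated.perfect_of_edited,
            "edited_of_total": treated.edited_of_total,
            "n_imperfect_genotypes": n_imperfect(treated),
            "total_reads": treated.total_reads,
        },
        "perfect_of_total_fold": fold,
    }
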