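"""Amplicon/protospacer geometry and editing-window conventions.

All position-indexed statistics in this package are reported in protospacer
coordinates: positions 1-20 are the 20-nt protospacer read 5'->3' on the
protospacer (sgRNA-matching) strand, and the PAM trinucleotide occupies
positions 21-23.  Internally, amplicon offsets are 0-based on the forward
strand of the reference amplicon as sequenced; the functions here convert
between the two frames for either protospacer strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "AmpliconTarget",
    "WindowPartition",
    "window_partition",
    "to_amplicon_coord",
    "from_amplicon_coord",
    "reference_base",
    "revcomp",
    "PROTOSPACER_LEN",
    "DEFAULT_ON_TARGET",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROTOSPACER_LEN = 20
PAM_LEN = 3

#: Conventional on-target editing windows by editor class.  Canonical CBEs
#: edit cytidines efficiently at protospacer positions 4-8; ABE7.10 deaminates
#: adenines at positions 4-7.  Everything else in 1-20 is "out-of-window".
DEFAULT_ON_TARGET = {
    "CBE": frozenset(range(4, 9)),
    "ABE": frozenset(range(4, 8)),
}

#: Reference (substrate) and product base of the intended conversion, on the
#: protospacer strand: C->T for CBEs, A->G for ABEs.
EDITOR_SUBSTRATE = {"CBE": "C", "ABE": "A"}
EDITOR_PRODUCT = {"CBE": "T", "ABE": "G"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """Protospacer position outside the 1..23 frame."""


class InvalidWindowError(ValueError):
    """Window override contains positions outside 1..20."""


@dataclass(frozen=True)
class WindowPartition:
    """Partition of protospacer positions 1-20 into on-target / out-of-window."""

    on_target: frozenset
    out_of_window: frozenset

    def __post_init__(self):
        on = frozenset(self.on_target)
        out = frozenset(self.out_of_window)
        object.__setattr__(self, "on_target", on)
        object.__setattr__(self, "out_of_window", out)
        full = frozenset(range(1, PROTOSPACER_LEN + 1))
        if on | out != full or on & out:
            raise InvalidWindowError(
                "on_target and out_of_window must partition positions 1..20"
            )


def window_partition(editor: str, override=None) -> WindowPartition:
    """On-target / out-of-window partition for an editor class.

    Parameters
    ----------
    editor : {"CBE", "ABE"}
        CBE defaults to on-target positions 4-8, ABE to 4-7.
    override : iterable of int, optional
        Replaces the default on-target set (must be within 1..20).
    """
    if editor not in DEFAULT_ON_TARGET:
        raise ValueError(f"unknown editor {editor!r}; expected CBE or ABE")
    if override is not None:
        on = frozenset(int(p) for p in override)
        bad = [p for p in on if not 1 <= p <= PROTOSPACER_LEN]
        if bad:
            raise InvalidWindowError(f"override positions outside 1..20: {sorted(bad)}")
    else:
        on = DEFAULT_ON_TARGET[editor]
    out = frozenset(range(1, PROTOSPACER_LEN + 1)) - on
    return WindowPartition(on, out)


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon reference with its protospacer geometry.

    Parameters
    ----------
    name : str
        Sample-sheet identifier for the locus (e.g. ``FBN1``).
    amplicon_seq : str
        Reference amplicon on the forward strand as sequenced (A/C/G/T).
    protospacer_start : int
        0-based offset of the leftmost base of the 20-nt protospacer segment
        on ``amplicon_seq``'s forward strand (for either protospacer strand).
    protospacer_strand : {"+", "-"}
        Strand of the protospacer relative to ``amplicon_seq``.
    editor : {"CBE", "ABE"}
    intended_positions : frozenset of int
        Protospacer positions (1-based) carrying the intended edit.
    min_flank : int
        Required reference flank on each side of the protospacer.
    """

    name: str
    amplicon_seq: str
    protospacer_start: int
    protospacer_strand: str
    editor: str
    intended_positions: frozenset = field(default_factory=frozenset)
    min_flank: int = 10

    def __post_init__(self):
        object.__setattr__(self, "amplicon_seq", self.amplicon_seq.upper())
        object.__setattr__(
            self, "intended_positions", frozenset(int(p) for p in self.intended_positions)
        )
        seq = self.amplicon_seq
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: amplicon sequence must be A/C/G/T only")
        if self.protospacer_strand not in ("+", "-"):
            raise ValueError(f"{self.name}: protospacer_strand must be '+' or '-'")
        if self.editor not in EDITOR_SUBSTRATE:
            raise ValueError(f"{self.name}: editor must be CBE or ABE")
        span_lo = self.protospacer_start
        span_hi = self.protospacer_start + PROTOSPACER_LEN - 1
        offsets = [to_amplicon_coord(self, p) for p in range(1, PROTOSPACER_LEN + PAM_LEN + 1)]
        if min(offsets) < 0 or max(offsets) >= len(seq):
            raise ValueError(f"{self.name}: protospacer+PAM does not fit in the amplicon")
        if span_lo < self.min_flank or span_hi + self.min_flank >= len(seq):
            raise ValueError(
                f"{self.name}: protospacer needs >= {self.min_flank} nt flank on each side"
            )
        bad = [p for p in self.intended_positions if not 1 <= p <= PROTOSPACER_LEN]
        if bad:
            raise ValueError(f"{self.name}: intended positions outside 1..20: {sorted(bad)}")
        substrate = EDITOR_SUBSTRATE[self.editor]
        wrong = [p for p in self.intended_positions if reference_base(self, p) != substrate]
        if wrong:
            raise ValueError(
                f"{self.name}: intended positions {sorted(wrong)} do not hold "
                f"{substrate} on the protospacer strand ({self.editor})"
            )
        if self.pam_seq[1:] != "GG":
            warnings.warn(
                f"{self.name}: PAM {self.pam_seq} is not NGG; proceeding anyway",
                stacklevel=2,
            )

    @property
    def protospacer_seq(self) -> str:
        """20-nt protospacer on the protospacer strand."""
        return "".join(reference_base(self, p) for p in range(1, PROTOSPACER_LEN + 1))

    @property
    def pam_seq(self) -> str:
        """PAM trinucleotide (positions 21-23) on the protospacer strand."""
        return "".join(
            reference_base(self, p)
            for p in range(PROTOSPACER_LEN + 1, PROTOSPACER_LEN + PAM_LEN + 1)
        )

    @property
    def substrate_base(self) -> str:
        return EDITOR_SUBSTRATE[self.editor]

    @property
    def product_base(self) -> str:
        return EDITOR_PRODUCT[self.editor]

    def editable_positions(self):
        """Protospacer positions whose reference base is the editor substrate."""
        return tuple(
            p
            for p in range(1, PROTOSPACER_LEN + 1)
            if reference_base(self, p) == self.substrate_base
        )

    @classmethod
    def from_protospacer(cls, name, amplicon_seq, protospacer_seq, editor,
                         intended_positions=(), min_flank=10):
        """Locate a 20-nt protospacer on either strand of the amplicon.

        Raises if the protospacer is absent or occurs more than once over
        both strands (ambiguous geometry must be given explicitly).
        """
        amplicon_seq = amplicon_seq.upper()
        protospacer_seq = protospacer_seq.upper()
        if len(protospacer_seq) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be exactly 20 nt")
        hits = []
        fwd = amplicon_seq
        rc = revcomp(protospacer_seq)
        start = fwd.find(protospacer_seq)
        while start != -1:
            hits.append((start, "+"))
            start = fwd.find(protospacer_seq, start + 1)
        start = fwd.find(rc)
        while start != -1:
            hits.append((start, "-"))
            start = fwd.find(rc, start + 1)
        if not hits:
            raise ValueError(f"{name}: protospacer not found on either strand")
        if len(hits) > 1:
            raise ValueError(f"{name}: protospacer occurs {len(hits)} times; ambiguous")
        start, strand = hits[0]
        return cls(name, amplicon_seq, start, strand, editor,
                   frozenset(intended_positions), min_flank)


def to_amplicon_coord(target: AmpliconTarget, p: int) -> int:
    """0-based forward-strand amplicon offset of protospacer position ``p`` (1..23)."""
    if not 1 <= p <= PROTOSPACER_LEN + PAM_LEN:
        raise CoordinateError(f"protospacer position {p} outside 1..23")
    if target.protospacer_strand == "+":
        return target.protospacer_start + (p - 1)
    return target.protospacer_start + (PROTOSPACER_LEN - p)


def from_amplicon_coord(target: AmpliconTarget, offset: int):
    """Inverse of :func:`to_amplicon_coord`; ``None`` if outside positions 1..23."""
    if target.protospacer_strand == "+":
        p = offset - target.protospacer_start + 1
    else:
        p = PROTOSPACER_LEN - (offset - target.protospacer_start)
    return p if 1 <= p <= PROTOSPACER_LEN + PAM_LEN else None


def reference_base(target: AmpliconTarget, p: int) -> str:
    """Reference base at protospacer position ``p``, on the protospacer strand."""
    base = target.amplicon_seq[to_amplicon_coord(target, p)]
    if target.protospacer_strand == "-":
        base = base.translate(_COMPLEMENT)
    return base
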