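"""Built-in demonstration targets used by presets, docs, and tests.

Both amplicons are 120 nt with the protospacer at forward offset 30 on the
plus strand, an NGG PAM at positions 21-23, and >= 10 nt flanks, mirroring a
typical short amplicon-sequencing design around an edited site.
"""

from __future__ import annotations

from .targets import AmpliconTarget

# Protospacer CTGCCACCGTCATGCTACTG: cytidines at positions 1,4,5,7,8,11,15,18
DEMO_CBE_AMPLICON = (
    "GGAGTTTCCATCCCGTCAGCAAGGACAGTT"
    "CTGCCACCGTCATGCTACTG" "AGG"
    "TGTTTGACACCGAGCTTGACCTTGGACCTTAAAGGCTCTGCGTGGTAGATCTAAGTGAACGGTCTTG"
)

# Protospacer GATAAAAGCATCATGCAGTC: adenines at positions 2,4,5,6,7,10,13,17
DEMO_ABE_AMPLICON = (
    "CCCGGGGTAGGCAGAAACGGGACCAACTGA"
    "GATAAAAGCATCATGCAGTC" "TGG"
    "CTAAGTGACGATGCACCGCGTACGGGCTATGACGGAAAGCCTTACTTAGGGCATTCGGCGTACCGTG"
)


def demo_cbe_target(intended_positions=(4,)) -> AmpliconTarget:
    """A3A-like CBE demo target; intended edit defaults to the window C4."""
    return AmpliconTarget("demo_cbe", DEMO_CBE_AMPLICON, 30, "+", "CBE",
                          frozenset(intended_positions))


def demo_abe_target(intended_positions=(5,)) -> AmpliconTarget:
    """ABE7.10 demo target; intended edit defaults to the window A5."""
    return AmpliconTarget("demo_abe", DEMO_ABE_AMPLICON, 30, "+", "ABE",
                          frozenset(intended_positions))
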