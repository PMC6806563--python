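"""Small shared sequence primitives: strands, complements, IUPAC degeneracy."""

from __future__ import annotations

import enum

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: degeneracy sets of the 15 IUPAC nucleotide codes
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class Strand(enum.Enum):
    """Reference strand on which the editable base reads C."""

    PLUS = "+"
    MINUS = "-"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(COMPLEMENT)[::-1]
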