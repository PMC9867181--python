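"""IUPAC DNA alphabet: base sets, complements, and helpers."""

from __future__ import annotations

#: Concrete base set denoted by each IUPAC code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"

#: Full residue alphabet accepted in alignments (IUPAC codes plus gap).
ALPHABET: frozenset[str] = frozenset(IUPAC_SETS) | {GAP}

UNAMBIGUOUS: frozenset[str] = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def complement(seq: str) -> str:
    """IUPAC-aware complement (gap maps to gap)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return complement(seq)[::-1]


def is_unambiguous(seq: str) -> bool:
    """True iff every residue is one of A, C, G, T."""
    return all(c in UNAMBIGUOUS for c in seq)


def first_expansion(seq: str) -> str:
    """Deterministic concrete expansion of a degenerate sequence.

    Each ambiguity code is replaced by the alphabetically first base in its
    set (e.g. W -> A, Y -> C, N -> A).
    """
    return "".join(min(IUPAC_SETS[c]) for c in seq)
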