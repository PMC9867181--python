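"""Primer candidate enumeration and pairing inside diagnostic windows.

Candidates are designed on the target consensus so a single pair serves
every target population. Two melting temperatures are reported: the
Wallace rule 2(A+T)+4(G+C) (advisory above 14 nt) and a nearest-neighbor
estimate that is the ranking default.

Nearest-neighbor thermodynamics use the unified dinucleotide parameter set
(SantaLucia 1998: unified dH/dS with terminal initiation penalties and the
self-complementary symmetry correction), two-state Tm
``dH * 1000 / (dS + R ln(C_T / x)) - 273.15`` with x = 4 for
non-self-complementary duplexes, and the 16.6 log10([Na+]) monovalent-salt
adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from sscoi.alphabet import UNAMBIGUOUS, is_unambiguous, reverse_complement
from sscoi.diagnostic_scan import DiagnosticWindow, _consensus_base
from sscoi.seqio import LabeledAlignment

Strand = Literal["plus", "minus"]

#: Unified NN parameters: dinucleotide -> (dH kcal/mol, dS cal/(mol K)).
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

#: Initiation penalties per terminal base: (dH, dS).
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)
#: Symmetry correction for self-complementary duplexes: (dH, dS).
NN_SYMMETRY = (0.0, -1.4)

_GAS_CONSTANT = 1.987  # cal / (mol K)


def _require_unambiguous(sequence: str, what: str) -> None:
    if not sequence:
        raise ValueError(f"{what}: empty sequence")
    if not is_unambiguous(sequence):
        raise ValueError(f"{what}: ambiguity code present, metric undefined for {sequence!r}")


def gc_content(sequence: str) -> float:
    """(#G + #C) / length for unambiguous DNA."""
    _require_unambiguous(sequence, "gc_content")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def tm_wallace(sequence: str) -> float:
    """Wallace rule: 2(A+T) + 4(G+C), in degrees C."""
    _require_unambiguous(sequence, "tm_wallace")
    at = sequence.count("A") + sequence.count("T")
    gc = sequence.count("G") + sequence.count("C")
    return 2.0 * at + 4.0 * gc


def tm_nearest_neighbor(
    sequence: str, na_mM: float = 50.0, primer_nM: float = 500.0
) -> float:
    """Two-state nearest-neighbor melting temperature, in degrees C."""
    _require_unambiguous(sequence, "tm_nearest_neighbor")
    if len(sequence) < 8:
        raise ValueError("nearest-neighbor Tm requires length >= 8")
    dh = 0.0
    ds = 0.0
    for i in range(len(sequence) - 1):
        step_dh, step_ds = NN_PARAMS[sequence[i : i + 2]]
        dh += step_dh
        ds += step_ds
    for terminal in (sequence[0], sequence[-1]):
        init_dh, init_ds = NN_INIT_GC if terminal in "GC" else NN_INIT_AT
        dh += init_dh
        ds += init_ds
    self_complementary = sequence == reverse_complement(sequence)
    if self_complementary:
        dh += NN_SYMMETRY[0]
        ds += NN_SYMMETRY[1]
    x = 1.0 if self_complementary else 4.0
    c_total = primer_nM * 1e-9
    tm_kelvin = dh * 1000.0 / (ds + _GAS_CONSTANT * math.log(c_total / x))
    return tm_kelvin - 273.15 + 16.6 * math.log10(na_mM * 1e-3)


def max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for prev, cur in zip(sequence, sequence[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def has_3prime_self_complementarity(sequence: str, min_bp: int = 4) -> bool:
    """True if the 3'-terminal ``min_bp`` bases can anneal to the primer itself."""
    if len(sequence) < min_bp:
        return False
    return reverse_complement(sequence[-min_bp:]) in sequence


@dataclass(frozen=True)
class PrimerConstraints:
    """Candidate filters; defaults admit typical diagnostic primers
    (18-25 nt, GC 0.30-0.60)."""

    min_len: int = 18
    max_len: int = 25
    gc_min: float = 0.30
    gc_max: float = 0.60
    tm_min: float = 45.0  # Wallace scale
    tm_max: float = 70.0
    max_homopolymer: int = 4
    forbidden_3prime_self_comp: int = 4
    na_mM: float = 50.0
    primer_nM: float = 500.0


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer as synthesized (5'->3'); minus-strand candidates store the
    reverse complement of the reference slice they bind."""

    sequence: str
    strand: Strand
    start: int
    end: int
    gc: float
    tm_wallace: float
    tm_nn: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("candidate length must equal end - start")


def candidate_flags(sequence: str, constraints: PrimerConstraints) -> frozenset[str]:
    flags = set()
    if max_homopolymer_run(sequence) > constraints.max_homopolymer:
        flags.add("homopolymer")
    if has_3prime_self_complementarity(sequence, constraints.forbidden_3prime_self_comp):
        flags.add("self_complementary_3prime")
    return frozenset(flags)


def passes_constraints(sequence: str, constraints: PrimerConstraints) -> bool:
    if not (constraints.min_len <= len(sequence) <= constraints.max_len):
        return False
    if not is_unambiguous(sequence):
        return False
    if not (constraints.gc_min <= gc_content(sequence) <= constraints.gc_max):
        return False
    if not (constraints.tm_min <= tm_wallace(sequence) <= constraints.tm_max):
        return False
    return not candidate_flags(sequence, constraints)


def _target_consensus(alignment: LabeledAlignment, start: int, end: int) -> str:
    targets = alignment.targets()
    if not targets:
        raise ValueError("alignment has no target records")
    chars = []
    for c in range(start, end):
        cons = _consensus_base([rec.residues[c] for rec in targets])
        chars.append(cons or "N")
    return "".join(chars)


def _make_candidate(
    sequence: str, strand: Strand, start: int, end: int, constraints: PrimerConstraints
) -> PrimerCandidate:
    return PrimerCandidate(
        sequence=sequence,
        strand=strand,
        start=start,
        end=end,
        gc=gc_content(sequence),
        tm_wallace=tm_wallace(sequence),
        tm_nn=tm_nearest_neighbor(sequence, constraints.na_mM, constraints.primer_nM),
        flags=candidate_flags(sequence, constraints),
    )


def enumerate_candidates(
    alignment: LabeledAlignment,
    window: DiagnosticWindow,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[PrimerCandidate]:
    """Every plus- and minus-strand target-consensus subsequence of the
    window satisfying all constraints.

    Candidates depend only on the target consensus, so adding non-target
    sequences never changes the result.
    """
    if not (0 <= window.start < window.end <= alignment.n_columns):
        raise ValueError("window out of alignment bounds")
    consensus = _target_consensus(alignment, window.start, window.end)
    out: list[PrimerCandidate] = []
    width = window.end - window.start
    for length in range(constraints.min_len, constraints.max_len + 1):
        for offset in range(0, width - length + 1):
            slice_ = consensus[offset : offset + length]
            if any(c not in UNAMBIGUOUS for c in slice_):
                continue
            start = window.start + offset
            for strand, seq in (("plus", slice_), ("minus", reverse_complement(slice_))):
                if passes_constraints(seq, constraints):
                    out.append(_make_candidate(seq, strand, start, start + length, constraints))
    return out


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_size: int
    tm_difference: float

    def __post_init__(self) -> None:
        if self.forward.strand != "plus" or self.reverse.strand != "minus":
            raise ValueError("pair must be a plus-strand forward and a minus-strand reverse")
        if self.forward.end > self.reverse.start:
            raise ValueError("forward primer must bind upstream of the reverse binding site")


def make_pair(forward: PrimerCandidate, reverse: PrimerCandidate) -> PrimerPair:
    return PrimerPair(
        forward=forward,
        reverse=reverse,
        product_size=reverse.end - forward.start,
        tm_difference=abs(forward.tm_wallace - reverse.tm_wallace),
    )


def pair_candidates(
    forwards: Iterable[PrimerCandidate],
    reverses: Iterable[PrimerCandidate],
    product_range: tuple[int, int] = (100, 1500),
    max_tm_diff: float = 16.0,
) -> list[PrimerPair]:
    """All validly oriented cross pairs within the product-size range and Tm
    spread, sorted by Tm difference then product size (both ascending)."""
    lo, hi = product_range
    pairs: list[PrimerPair] = []
    for fwd in forwards:
        if fwd.strand != "plus":
            continue
        for rev in reverses:
            if rev.strand != "minus" or fwd.end > rev.start:
                continue
            product = rev.end - fwd.start
            tm_diff = abs(fwd.tm_wallace - rev.tm_wallace)
            if lo <= product <= hi and tm_diff <= max_tm_diff:
                pairs.append(make_pair(fwd, rev))
    pairs.sort(key=lambda p: (p.tm_difference, p.product_size))
    return pairs


def annealing_recommendation(
    pair: PrimerPair, below: float = 5.0, above: float = 3.0, scale: str = "wallace"
) -> tuple[float, float]:
    """Recommended annealing interval: [min primer Tm - below, min + above]."""
    if scale == "wallace":
        low_tm = min(pair.forward.tm_wallace, pair.reverse.tm_wallace)
    elif scale == "nn":
        low_tm = min(pair.forward.tm_nn, pair.reverse.tm_nn)
    else:
        raise ValueError(f"unknown Tm scale {scale!r}")
    return (low_tm - below, low_tm + above)


def pairs_report_tsv(pairs: Sequence[PrimerPair]) -> str:
    """Ranked pair report with 1-based inclusive coordinates."""
    lines = [
        "fwd_seq\tfwd_start\tfwd_end\tfwd_gc\tfwd_tm_wallace\tfwd_tm_nn\t"
        "rev_seq\trev_start\trev_end\trev_gc\trev_tm_wallace\trev_tm_nn\t"
        "product_size\ttm_difference\tannealing_lo\tannealing_hi"
    ]
    for p in pairs:
        lo, hi = annealing_recommendation(p)
        f, r = p.forward, p.reverse
        lines.append(
            f"{f.sequence}\t{f.start + 1}\t{f.end}\t{f.gc:.2f}\t{f.tm_wallace:.1f}\t{f.tm_nn:.1f}\t"
            f"{r.sequence}\t{r.start + 1}\t{r.end}\t{r.gc:.2f}\t{r.tm_wallace:.1f}\t{r.tm_nn:.1f}\t"
            f"{p.product_size}\t{p.tm_difference:.1f}\t{lo:.1f}\t{hi:.1f}"
        )
    return "\n".join(lines) + "\n"
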