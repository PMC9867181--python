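"""Simulated barcode panels with controlled divergence.

Generates labeled alignments emulating a diagnostic design problem: a
target clade with near-zero within-group p-distance and several non-target
species at configurable between-species divergence (default 0.06-0.08),
optionally with primer binding sites planted into the target sequences.
The substitution model is uniform (Jukes-Cantor-like), indel-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from sscoi.alphabet import first_expansion, reverse_complement
from sscoi.seqio import LabeledAlignment, Role, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, seed: Union[int, np.random.Generator]) -> str:
    rng = _as_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_sequence(
    sequence: str, p: float, seed: Union[int, np.random.Generator]
) -> str:
    """Substitute each site independently with probability ``p`` to a
    uniformly chosen *different* base. Deterministic for a fixed seed."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("substitution probability must be in [0, 1]")
    rng = _as_rng(seed)
    coded = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(coded)) < p
    if hit.any():
        idx = np.searchsorted(_BASES, coded[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        coded[hit] = _BASES[(idx + shift) % 4]
    return coded.tobytes().decode("ascii")


def plant_binding_sites(
    sequence: str,
    forward_primer: str,
    reverse_primer: str,
    fwd_pos: int,
    rev_pos: int,
) -> str:
    """Splice a forward primer site at ``fwd_pos`` and the reverse
    complement of the reverse primer at ``rev_pos``; length preserved.

    Degenerate primer letters are planted as their deterministic first
    expansion, so the binding model recovers both sites with 0 mismatches.
    """
    fwd = first_expansion(forward_primer)
    rev_site = reverse_complement(first_expansion(reverse_primer))
    if fwd_pos < 0:
        raise ValueError("fwd_pos must be non-negative")
    if rev_pos < fwd_pos + len(fwd):
        raise ValueError("reverse site overlaps the forward site")
    if rev_pos + len(rev_site) > len(sequence):
        raise ValueError(
            f"sequence too short: reverse site needs {rev_pos + len(rev_site)} bp, "
            f"have {len(sequence)}"
        )
    out = list(sequence)
    out[fwd_pos : fwd_pos + len(fwd)] = fwd
    out[rev_pos : rev_pos + len(rev_site)] = rev_site
    return "".join(out)


def _consensus_rate(between_p: float, within_p: float) -> float:
    """Consensus-level substitution rate giving an expected *individual*
    target-vs-nontarget p-distance of ``between_p``.

    Under the uniform model, two lineages mutated from a common ancestor at
    per-site rates qA and qB differ with probability
    ``qA + qB - (4/3) qA qB``; target individuals sit at ``within_p`` from
    the ancestor and non-target individuals compound the consensus rate
    with another ``within_p``. Inverting those two steps yields the rate
    the species consensus must be drawn at.
    """
    q_nontarget = (between_p - within_p) / (1.0 - (4.0 / 3.0) * within_p)
    rate = (q_nontarget - within_p) / (1.0 - (4.0 / 3.0) * within_p)
    if rate < 0.0:
        raise ValueError(
            "between_species_p too small relative to within_target_p "
            "to be realizable at the individual level"
        )
    return rate


@dataclass(frozen=True)
class PlantedSites:
    forward_primer: str
    reverse_primer: str
    fwd_pos: int
    rev_pos: int


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a simulated panel."""

    seed: int = 0
    fragment_length: int = 658
    n_target: int = 14
    target_name: str = "target taxon"
    nontarget_species: tuple[tuple[str, int], ...] = (
        ("relative_1", 3),
        ("relative_2", 3),
        ("relative_3", 3),
        ("relative_4", 3),
        ("relative_5", 3),
    )
    within_target_p: float = 0.005
    between_species_p: tuple[float, float] = (0.06, 0.08)
    planted_sites: Optional[PlantedSites] = None

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not (0.0 <= self.within_target_p < 1.0):
            raise ValueError("within_target_p must be in [0, 1)")
        lo, hi = self.between_species_p
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("between_species_p interval must be ordered within [0, 1)")


def simulate_panel(spec: PanelSpec) -> tuple[LabeledAlignment, dict]:
    """Simulate a labeled panel; returns the alignment and a truth record.

    One ancestral sequence is drawn uniformly and used as the target
    consensus; each non-target species' consensus is the ancestor mutated
    at a rate drawn from ``between_species_p``; individuals are their
    species consensus mutated at ``within_target_p``. Planted binding
    sites go into target sequences only. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = random_sequence(spec.fragment_length, rng)
    w = spec.within_target_p

    records: list[SequenceRecord] = []
    truth: dict = {
        "seed": spec.seed,
        "fragment_length": spec.fragment_length,
        "species_rates": {},
        "planted": None,
    }

    for i in range(spec.n_target):
        residues = mutate_sequence(ancestor, spec.within_target_p, rng)
        if spec.planted_sites is not None:
            ps = spec.planted_sites
            residues = plant_binding_sites(
                residues, ps.forward_primer, ps.reverse_primer, ps.fwd_pos, ps.rev_pos
            )
        records.append(
            SequenceRecord(
                id=f"target_{i + 1:02d}",
                residues=residues,
                species=spec.target_name,
                role=Role.TARGET,
            )
        )
    if spec.planted_sites is not None:
        ps = spec.planted_sites
        fwd_len = len(ps.forward_primer)
        rev_len = len(ps.reverse_primer)
        truth["planted"] = {
            "forward_window": [ps.fwd_pos, ps.fwd_pos + fwd_len],
            "reverse_window": [ps.rev_pos, ps.rev_pos + rev_len],
            "product_size": ps.rev_pos + rev_len - ps.fwd_pos,
        }

    for name, n_seqs in spec.nontarget_species:
        rate = float(rng.uniform(*spec.between_species_p))
        truth["species_rates"][name] = rate
        consensus = mutate_sequence(ancestor, _consensus_rate(rate, w), rng)
        for i in range(n_seqs):
            records.append(
                SequenceRecord(
                    id=f"{name}_{i + 1:02d}",
                    residues=mutate_sequence(consensus, spec.within_target_p, rng),
                    species=name,
                    role=Role.NON_TARGET,
                )
            )

    alignment = LabeledAlignment(records=tuple(records))

    from sscoi.phylo import distance_matrix

    dm = distance_matrix(alignment)
    roles = [r.role for r in alignment.records]
    t_idx = [i for i, r in enumerate(roles) if r is Role.TARGET]
    nt_idx = [i for i, r in enumerate(roles) if r is Role.NON_TARGET]
    within = [dm.d[i, j] for i in t_idx for j in t_idx if i < j]
    between = [dm.d[i, j] for i in t_idx for j in nt_idx]
    truth["realized_within_target_p"] = float(np.mean(within)) if within else 0.0
    truth["realized_target_vs_nontarget_p"] = float(np.mean(between)) if between else 0.0
    return alignment, truth
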