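"""Degenerate-aware in-silico PCR: primer binding-site search with a 3'
clamp rule, amplicon prediction, specificity/mixture panels, and virtual
gel rendering.

Detection is boolean and sequence-determined: a template "amplifies" iff
both primers find validly oriented binding sites within the product-size
cap. Concentration and cycle kinetics (wet-lab detection limits) are
deliberately outside the model.

Degenerate IUPAC codes in the primer are honored with base-set semantics
(a primer position matches a template base iff the template base's set is
contained in the primer position's set: primers are designed pools,
templates are observed data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from sscoi.alphabet import GAP, IUPAC_SETS, reverse_complement
from sscoi.seqio import SequenceRecord

#: DL2000 ladder rungs, top of gel first.
DL2000 = (2000, 1000, 750, 500, 250, 100)


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the IUPAC base sets intersect (N matches everything)."""
    if primer_base == GAP or template_base == GAP:
        raise ValueError("gap character is not a base")
    try:
        return bool(IUPAC_SETS[primer_base] & IUPAC_SETS[template_base])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC base: {exc.args[0]!r}") from None


def _binding_match(primer_base: str, template_base: str) -> bool:
    # template degeneracy counts as a mismatch unless every base it could
    # be is covered by the primer pool
    if primer_base == GAP or template_base == GAP:
        raise ValueError("gap character is not a base")
    return IUPAC_SETS[template_base] <= IUPAC_SETS[primer_base]


@dataclass(frozen=True)
class BindingConfig:
    max_mismatches: int = 2
    clamp_len: int = 3
    max_clamp_mismatches: int = 0
    max_product: int = 3000


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing location on the plus strand of a template."""

    template_id: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    mismatches: int
    clamp_mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches < self.clamp_mismatches or self.clamp_mismatches < 0:
            raise ValueError("mismatches >= clamp_mismatches >= 0 required")


def _scan_one_strand(
    template: str,
    primer: str,
    max_mismatches: int,
    clamp_len: int,
    max_clamp_mismatches: int,
):
    """Yield (offset, mismatches, clamp_mismatches) for primer laid 5'->3'
    along the given template string."""
    plen = len(primer)
    clamp_start = plen - min(clamp_len, plen)
    for offset in range(len(template) - plen + 1):
        mism = clamp_mism = 0
        ok = True
        for k in range(plen):
            if not _binding_match(primer[k], template[offset + k]):
                mism += 1
                if k >= clamp_start:
                    clamp_mism += 1
                    if clamp_mism > max_clamp_mismatches:
                        ok = False
                        break
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            yield offset, mism, clamp_mism


def find_binding_sites(
    template: str,
    primer: str,
    max_mismatches: int = 2,
    clamp_len: int = 3,
    max_clamp_mismatches: int = 0,
    template_id: str = "",
) -> list[BindingSite]:
    """All binding sites of a 5'->3' primer on both strands of a template.

    Minus-strand sites are found by matching against the reverse complement
    and mapping coordinates back to the plus strand. A primer longer than
    the template yields an empty list.
    """
    if GAP in template:
        raise ValueError("template must be unaligned (strip gaps first)")
    sites: list[BindingSite] = []
    tlen = len(template)
    for offset, mism, clamp in _scan_one_strand(
        template, primer, max_mismatches, clamp_len, max_clamp_mismatches
    ):
        sites.append(
            BindingSite(template_id, offset, offset + len(primer), "plus", mism, clamp)
        )
    rc = reverse_complement(template)
    for offset, mism, clamp in _scan_one_strand(
        rc, primer, max_mismatches, clamp_len, max_clamp_mismatches
    ):
        start = tlen - offset - len(primer)
        sites.append(
            BindingSite(template_id, start, start + len(primer), "minus", mism, clamp)
        )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_size: int

    def __post_init__(self) -> None:
        if self.forward_site.strand != "plus" or self.reverse_site.strand != "minus":
            raise ValueError("forward site must be plus strand, reverse site minus strand")
        if self.product_size != self.reverse_site.end - self.forward_site.start:
            raise ValueError("product_size must span forward start to reverse end")


def _primer_sequence(primer: Union[str, object]) -> str:
    return primer if isinstance(primer, str) else primer.sequence


def predict_amplicons(
    template: SequenceRecord,
    pair,
    config: BindingConfig = BindingConfig(),
) -> list[AmpliconPrediction]:
    """All amplicons a primer pair would produce from one template,
    sorted by product size.

    ``pair`` is a PrimerPair or any object with ``forward``/``reverse``
    members carrying 5'->3' sequences (plain string attributes accepted).
    Both orientations are considered: either primer may take the
    plus-strand role (so predictions are invariant under
    reverse-complementing the template); ``forward_site`` always names the
    plus-strand site and ``reverse_site`` the minus-strand site.
    """
    seq = template.ungapped()
    fwd = _primer_sequence(pair.forward)
    rev = _primer_sequence(pair.reverse)
    fwd_sites = find_binding_sites(
        seq, fwd, config.max_mismatches, config.clamp_len,
        config.max_clamp_mismatches, template.id,
    )
    rev_sites = find_binding_sites(
        seq, rev, config.max_mismatches, config.clamp_len,
        config.max_clamp_mismatches, template.id,
    )
    out = []
    seen: set[tuple[int, int, int, int]] = set()
    for plus_pool, minus_pool in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
        for f in plus_pool:
            if f.strand != "plus":
                continue
            for r in minus_pool:
                if r.strand != "minus" or f.end > r.start:
                    continue
                product = r.end - f.start
                key = (f.start, f.end, r.start, r.end)
                if product <= config.max_product and key not in seen:
                    seen.add(key)
                    out.append(AmpliconPrediction(template.id, f, r, product))
    out.sort(key=lambda a: (a.product_size, a.forward_site.start))
    return out


@dataclass(frozen=True)
class SimplePair:
    """Minimal forward/reverse primer holder for verification workflows."""

    forward: str
    reverse: str


@dataclass(frozen=True)
class GelLaneReport:
    lane_label: str
    band_sizes: tuple[int, ...]
    detected: bool

    def __post_init__(self) -> None:
        if self.detected != bool(self.band_sizes):
            raise ValueError("detected must mirror band presence")
        if list(self.band_sizes) != sorted(self.band_sizes, reverse=True):
            raise ValueError("band sizes must be sorted descending (top of gel first)")


NO_TEMPLATE_CONTROL = "no-template control"


def specificity_panel(
    templates: Sequence[SequenceRecord],
    pair,
    config: BindingConfig = BindingConfig(),
) -> list[GelLaneReport]:
    """One gel lane per template, input order preserved, plus a final
    no-template control lane (always undetected)."""
    lanes = []
    for rec in templates:
        sizes = tuple(
            sorted((a.product_size for a in predict_amplicons(rec, pair, config)), reverse=True)
        )
        lanes.append(GelLaneReport(rec.id, sizes, bool(sizes)))
    lanes.append(GelLaneReport(NO_TEMPLATE_CONTROL, (), False))
    return lanes


@dataclass(frozen=True)
class MixtureResult:
    ratio: tuple[int, int]
    detected: bool


def mixture_panel(
    target_templates: Sequence[SequenceRecord],
    background_templates: Sequence[SequenceRecord],
    ratios: Iterable[tuple[int, int]],
    pair,
    config: BindingConfig = BindingConfig(),
) -> list[MixtureResult]:
    """Target:background mixture series under sequence-determined detection.

    A mixture is detected iff the target is present at nonzero copy number
    and at least one target template amplifies; wet-lab detection limits
    are concentration effects outside this model.
    """
    target_amplifies = any(
        predict_amplicons(rec, pair, config) for rec in target_templates
    )
    out = []
    for target_copies, background_copies in ratios:
        if target_copies < 0 or background_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        out.append(
            MixtureResult(
                ratio=(target_copies, background_copies),
                detected=target_copies > 0 and target_amplifies,
            )
        )
    return out


def lanes_tsv(lanes: Sequence[GelLaneReport]) -> str:
    lines = ["lane\tdetected\tband_sizes"]
    for lane in lanes:
        bands = ",".join(str(b) for b in lane.band_sizes)
        lines.append(f"{lane.lane_label}\t{'yes' if lane.detected else 'no'}\t{bands}")
    return "\n".join(lines) + "\n"


def virtual_gel(
    lanes: Sequence[GelLaneReport], ladder: Sequence[int] = DL2000
) -> str:
    """Fixed-width text gel: ladder lane first, bands placed between the
    bracketing ladder rungs. Bands larger than the top rung are placed
    above it with a warning."""
    if list(ladder) != sorted(ladder, reverse=True) or len(set(ladder)) != len(ladder):
        raise ValueError("ladder must be strictly descending")

    # slot 0: above the top rung; slot 2k+1: rung k; slot 2k+2: between rung
    # k and k+1 (the last one doubles as "below the bottom rung")
    n_slots = 2 * len(ladder) + 2

    def slot_for(size: int) -> int:
        if size > ladder[0]:
            return 0
        for k, rung in enumerate(ladder):
            if size == rung:
                return 2 * k + 1
            if size > (ladder[k + 1] if k + 1 < len(ladder) else -1):
                return 2 * k + 2
        return n_slots - 1

    width = 9
    headers = ["ladder"] + [lane.lane_label[:width] for lane in lanes]
    rows: list[list[str]] = [["" for _ in range(len(lanes) + 1)] for _ in range(n_slots)]
    for k, rung in enumerate(ladder):
        rows[2 * k + 1][0] = f"{rung} ="
    for col, lane in enumerate(lanes, start=1):
        by_slot: dict[int, list[int]] = {}
        for band in lane.band_sizes:
            if band > ladder[0]:
                warnings.warn(
                    f"band {band} bp larger than top ladder rung {ladder[0]} bp",
                    stacklevel=2,
                )
            by_slot.setdefault(slot_for(band), []).append(band)
        for slot, bands in by_slot.items():
            rows[slot][col] = ",".join(str(b) for b in sorted(bands, reverse=True))

    out_lines = ["  ".join(h.ljust(width) for h in headers)]
    for row in rows:
        if any(cell for cell in row):
            cells = [row[0].ljust(width)] + [cell.rjust(width) for cell in row[1:]]
            out_lines.append("  ".join(cells))
    return "\n".join(out_lines) + "\n"
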