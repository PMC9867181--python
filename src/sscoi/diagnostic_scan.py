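"""Locate alignment regions conserved within the target taxon but divergent
against every non-target species — candidate real estate for
species-specific primers.

The divergence criterion is worst-case by design: a window qualifies only
if *every* non-target species' consensus differs from the target consensus
at enough columns, so a primer placed there can separate the target from
its closest relative, not just from the average relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sscoi.alphabet import UNAMBIGUOUS
from sscoi.seqio import LabeledAlignment

_BASES = "ACGT"  # alphabetical; consensus ties break in this order


@dataclass(frozen=True)
class SiteProfile:
    """Per-column conservation/divergence summaries of a labeled alignment.

    ``within_conservation[c]``: share of target sequences carrying the
    target-consensus base at column c (0 where the column is ineligible).
    ``min_nontarget_divergence[c]``: for the nearest non-target species, the
    share of its sequences differing from the target consensus.
    ``eligible[c]``: no gap/ambiguity in any target sequence at column c.
    ``species_differs[name][c]``: that species' consensus differs from the
    target consensus at column c.
    """

    n_columns: int
    within_conservation: np.ndarray
    min_nontarget_divergence: np.ndarray
    eligible: np.ndarray
    target_consensus: str
    species_differs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for vec in (self.within_conservation, self.min_nontarget_divergence, self.eligible):
            if len(vec) != self.n_columns:
                raise ValueError("profile vectors must have length n_columns")


def _consensus_base(column_chars: list[str]) -> str | None:
    """Most frequent unambiguous base; ties alphabetical; None if no A/C/G/T."""
    counts = {b: 0 for b in _BASES}
    for ch in column_chars:
        if ch in counts:
            counts[ch] += 1
    top = max(counts.values())
    if top == 0:
        return None
    # highest count wins; ties go to the alphabetically first base
    for b in _BASES:
        if counts[b] == top:
            return b
    return None


def site_profile(alignment: LabeledAlignment) -> SiteProfile:
    """Column-wise conservation/divergence profile.

    Target consensus per column is the most frequent unambiguous base among
    target sequences (ties broken alphabetically A<C<G<T). Requires at
    least one target and one non-target record.
    """
    targets = alignment.targets()
    if not targets:
        raise ValueError("alignment has no target records")
    species_groups = alignment.nontarget_species()
    if not species_groups:
        raise ValueError("alignment has no non-target records")

    n_cols = alignment.n_columns
    within = np.zeros(n_cols)
    eligible = np.zeros(n_cols, dtype=bool)
    consensus_chars: list[str] = []
    target_cols = [[rec.residues[c] for rec in targets] for c in range(n_cols)]

    for c in range(n_cols):
        chars = target_cols[c]
        cons = _consensus_base(chars)
        consensus_chars.append(cons or "N")
        col_eligible = all(ch in UNAMBIGUOUS for ch in chars)
        eligible[c] = col_eligible
        if col_eligible and cons is not None:
            within[c] = sum(1 for ch in chars if ch == cons) / len(chars)
        # ineligible columns report 0 conservation

    consensus = "".join(consensus_chars)
    species_differs: dict[str, np.ndarray] = {}
    divergence = np.full((len(species_groups), n_cols), np.nan)
    for s_idx, (name, recs) in enumerate(sorted(species_groups.items())):
        differs = np.zeros(n_cols, dtype=bool)
        for c in range(n_cols):
            chars = [rec.residues[c] for rec in recs]
            sp_cons = _consensus_base(chars)
            # no unambiguous base in this species: not usable as a
            # discriminating site (conservative)
            differs[c] = sp_cons is not None and sp_cons != consensus[c]
            divergence[s_idx, c] = sum(1 for ch in chars if ch != consensus[c]) / len(chars)
        species_differs[name] = differs

    return SiteProfile(
        n_columns=n_cols,
        within_conservation=within,
        min_nontarget_divergence=divergence.min(axis=0),
        eligible=eligible,
        target_consensus=consensus,
        species_differs=species_differs,
    )


@dataclass(frozen=True)
class DiagnosticWindow:
    """Half-open alignment interval suitable for species-specific primers."""

    start: int
    end: int
    mean_within_conservation: float
    min_discriminating_sites: int
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_stats(profile: SiteProfile, start: int, end: int) -> tuple[float, int]:
    mean_within = float(profile.within_conservation[start:end].mean())
    min_disc = min(
        int(diff[start:end].sum()) for diff in profile.species_differs.values()
    )
    return mean_within, min_disc


def find_diagnostic_windows(
    profile: SiteProfile,
    min_len: int = 18,
    min_within: float = 0.95,
    min_disc_sites: int = 2,
) -> list[DiagnosticWindow]:
    """Maximal diagnostic windows, sorted by score descending.

    Within each maximal run of eligible columns whose within-target
    conservation meets ``min_within``, every sub-window of length >=
    ``min_len`` whose worst-case (per non-target species) discriminating
    site count meets ``min_disc_sites`` is found; overlapping qualifying
    sub-windows are merged into maximal windows. Score is
    ``mean_within_conservation * min_discriminating_sites``.
    """
    if min_len < 15:
        raise ValueError("min_len must be >= 15 (shortest plausible primer footprint)")
    if not (0.0 <= min_within <= 1.0):
        raise ValueError("min_within must be in [0, 1]")
    if min_disc_sites < 0:
        raise ValueError("min_disc_sites must be >= 0")

    usable = profile.eligible & (profile.within_conservation >= min_within)
    n = profile.n_columns

    # maximal runs of usable columns
    runs: list[tuple[int, int]] = []
    c = 0
    while c < n:
        if usable[c]:
            start = c
            while c < n and usable[c]:
                c += 1
            runs.append((start, c))
        else:
            c += 1

    # The discriminating-site count is monotone under window growth, so any
    # window containing a qualifying sub-window also qualifies; the union of
    # all qualifying sub-windows of a run is therefore the run itself
    # whenever at least one sub-window qualifies (equivalently: the run is
    # long enough and itself meets the threshold).
    windows: list[DiagnosticWindow] = []
    for run_start, run_end in runs:
        if run_end - run_start < min_len:
            continue
        mean_within, min_disc = _window_stats(profile, run_start, run_end)
        if min_disc < min_disc_sites:
            continue
        windows.append(
            DiagnosticWindow(
                start=run_start,
                end=run_end,
                mean_within_conservation=mean_within,
                min_discriminating_sites=min_disc,
                score=mean_within * min_disc,
            )
        )
    windows.sort(key=lambda w: (-w.score, w.start))
    return windows


def windows_report_tsv(windows: list[DiagnosticWindow]) -> str:
    """Human-readable report with 1-based inclusive coordinates."""
    lines = ["start\tend\tlength\tmean_within_conservation\tmin_discriminating_sites\tscore"]
    for w in windows:
        lines.append(
            f"{w.start + 1}\t{w.end}\t{w.length}\t"
            f"{w.mean_within_conservation:.4f}\t{w.min_discriminating_sites}\t{w.score:.4f}"
        )
    return "\n".join(lines) + "\n"
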