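"""Barcode phylogenetics: p-distance matrices, neighbor-joining trees,
and nonparametric bootstrap support.

Distances are uncorrected p-distances (base differences per site). Sites
are comparable only where both residues are unambiguous A/C/G/T; gaps and
ambiguity codes are treated as missing data, never as matches or
mismatches. Pairwise deletion is the default; complete deletion first
drops every alignment column containing any gap or ambiguity in any
record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from sscoi.seqio import LabeledAlignment

DeletionMode = Literal["pairwise", "complete"]

_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def p_distance(
    a: str, b: str, deletion: DeletionMode = "pairwise"
) -> tuple[float, int]:
    """Proportion of differing sites between two equal-length sequences.

    A site is comparable iff both characters are in {A,C,G,T}. For a single
    pair the two deletion modes coincide (the "complete set" is the pair
    itself); the parameter exists for signature symmetry with
    :func:`distance_matrix`.

    Returns ``(distance, n_comparable)``. Zero comparable sites is an error:
    the distance is undefined, not 0.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths {len(a)} and {len(b)}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    xa, xb = _encode(a), _encode(b)
    comparable = np.isin(xa, _ACGT_BYTES) & np.isin(xb, _ACGT_BYTES)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable sites: p-distance undefined")
    mismatches = int(((xa != xb) & comparable).sum())
    return mismatches / n_comp, n_comp


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair comparable-site counts."""

    labels: tuple[str, ...]
    d: np.ndarray
    n_comparable: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n) or self.n_comparable.shape != (n, n):
            raise ValueError("matrix shapes must match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be exactly 0")
        # p-distances lie in [0, 1]; the [0, 1] bound is guaranteed by
        # distance_matrix(), while the type also carries general additive
        # distances (e.g. for tree reconstruction), so only non-negativity
        # is enforced here
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(
    alignment: LabeledAlignment, deletion: DeletionMode = "pairwise"
) -> DistanceMatrix:
    """All pairwise p-distances for an alignment.

    Complete deletion first drops every column containing any gap or
    ambiguity in any record, then computes mismatch fractions on the
    remaining columns.
    """
    coded = np.stack([_encode(r.residues) for r in alignment.records])
    unambiguous = np.isin(coded, _ACGT_BYTES)
    if deletion == "complete":
        keep = unambiguous.all(axis=0)
        coded = coded[:, keep]
        unambiguous = unambiguous[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    n = len(alignment.records)
    # broadcast over pairs; fine for panel-scale n
    comp = unambiguous[:, None, :] & unambiguous[None, :, :]
    diff = (coded[:, None, :] != coded[None, :, :]) & comp
    n_comp = comp.sum(axis=2)
    mism = diff.sum(axis=2)
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(n_comp[off_diag] == 0):
        i, j = np.argwhere((n_comp == 0) & off_diag)[0]
        raise ValueError(
            f"no comparable sites between {alignment.records[i].id!r} "
            f"and {alignment.records[j].id!r}: p-distance undefined"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(n_comp > 0, mism / np.maximum(n_comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        labels=tuple(alignment.ids), d=d, n_comparable=n_comp.astype(np.int64)
    )


@dataclass
class Edge:
    u: int
    v: int
    length: float
    support: Optional[int] = None


@dataclass
class UnrootedTree:
    """Unrooted tree: integer node ids, leaves carrying text labels,
    edges with branch lengths and optional integer-percent support."""

    leaf_labels: dict[int, str]
    edges: list[Edge] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def nodes(self) -> set[int]:
        out = set(self.leaf_labels)
        for e in self.edges:
            out.add(e.u)
            out.add(e.v)
        return out

    def adjacency(self) -> dict[int, list[tuple[int, float, Optional[int]]]]:
        adj: dict[int, list[tuple[int, float, Optional[int]]]] = {n: [] for n in self.nodes()}
        for e in self.edges:
            adj[e.u].append((e.v, e.length, e.support))
            adj[e.v].append((e.u, e.length, e.support))
        return adj

    def newick_root(self) -> int:
        internal = [n for n in self.nodes() if n not in self.leaf_labels]
        if not internal:
            raise ValueError("tree has no internal node to root the Newick rendering at")
        adj = self.adjacency()
        return max(internal, key=lambda n: (len(adj[n]), -n))

    def _leaves_below(self, child: int, parent: int, adj) -> frozenset[str]:
        stack, seen, labels = [(child, parent)], set(), []
        while stack:
            node, par = stack.pop()
            if node in self.leaf_labels:
                labels.append(self.leaf_labels[node])
            for nbr, _, _ in adj[node]:
                if nbr != par and (node, nbr) not in seen:
                    seen.add((node, nbr))
                    stack.append((nbr, node))
        return frozenset(labels)

    def bipartitions(self) -> dict[frozenset[str], int]:
        """Canonical leaf bipartition -> edge index, internal edges only.

        The canonical form is the side not containing the lexicographically
        smallest leaf label.
        """
        all_labels = frozenset(self.leaf_labels.values())
        anchor = min(all_labels)
        adj = self.adjacency()
        out: dict[frozenset[str], int] = {}
        for idx, e in enumerate(self.edges):
            if e.u in self.leaf_labels or e.v in self.leaf_labels:
                continue
            side = self._leaves_below(e.v, e.u, adj)
            if anchor in side:
                side = all_labels - side
            if 2 <= len(side) <= len(all_labels) - 2:
                out[side] = idx
        return out

    def leaf_path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        by_label = {lab: node for node, lab in self.leaf_labels.items()}
        start, goal = by_label[label_a], by_label[label_b]
        adj = self.adjacency()
        stack = [(start, None, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nbr, length, _ in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node, dist + length))
        raise ValueError(f"no path between {label_a!r} and {label_b!r}")


def nj_tree(matrix: DistanceMatrix) -> UnrootedTree:
    """Neighbor joining (Saitou–Nei agglomeration, Studier–Keppler Q).

    Ties in Q are broken by the lexicographically smallest active index
    pair. Negative branch lengths from the two-point formulas are clamped
    to 0 with the deficit moved to the sister edge. On an additive matrix
    the leaf-to-leaf path lengths reproduce the input distances.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 labels")

    labels = matrix.labels
    # dense working copy indexed by node id
    dist: dict[int, dict[int, float]] = {
        i: {j: float(matrix.d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    active = list(range(n))
    next_id = n
    tree = UnrootedTree(leaf_labels={i: labels[i] for i in range(n)})

    while len(active) > 3:
        r = len(active)
        row_sums = {i: sum(dist[i][k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[i][j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dist[i][j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = dist[i][j] - li
        if li < 0:
            lj, li = dist[i][j], 0.0
        elif lj < 0:
            li, lj = dist[i][j], 0.0
        u = next_id
        next_id += 1
        tree.edges.append(Edge(u, i, li))
        tree.edges.append(Edge(u, j, lj))
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i][k] + dist[j][k] - dist[i][j])
            dist[u][k] = duk
            dist[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    center = next_id
    for node, length in ((a, la), (b, lb), (c, lc)):
        tree.edges.append(Edge(center, node, max(0.0, length)))
    return tree


def bootstrap_support(
    alignment: LabeledAlignment,
    replicates: int,
    seed: int,
    deletion: DeletionMode = "pairwise",
) -> UnrootedTree:
    """NJ tree on the full alignment with bootstrap support on internal edges.

    Columns are resampled with replacement per replicate; support on each
    internal edge of the original-data tree is the percentage of replicate
    trees containing the same leaf bipartition. Replicates in which some
    pair has no comparable sites are skipped (with a warning) and excluded
    from the denominator. Deterministic for a fixed seed: replicate k uses
    the stream ``default_rng((seed, k))``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(distance_matrix(alignment, deletion))
    original_parts = tree.bipartitions()
    counts = {part: 0 for part in original_parts}
    n_cols = alignment.n_columns
    skipped = 0
    records = alignment.records
    used = 0
    for k in range(replicates):
        rng = np.random.default_rng((seed, k))
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = _resample_columns(records, cols)
        try:
            rep_matrix = distance_matrix(resampled, deletion)
        except ValueError:
            skipped += 1
            continue
        rep_parts = nj_tree(rep_matrix).bipartitions()
        used += 1
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    if skipped:
        warnings.warn(
            f"{skipped} of {replicates} bootstrap replicates skipped "
            "(undefined pairwise distance)",
            stacklevel=2,
        )
    denom = max(used, 1)
    for part, edge_idx in original_parts.items():
        tree.edges[edge_idx].support = round(100 * counts[part] / denom)
    return tree


def _resample_columns(records, cols: np.ndarray) -> LabeledAlignment:
    from dataclasses import replace

    coded = np.stack([_encode(r.residues) for r in records])
    resampled = coded[:, cols]
    new_records = tuple(
        replace(rec, residues=resampled[i].tobytes().decode("ascii"))
        for i, rec in enumerate(records)
    )
    return LabeledAlignment(records=new_records)


def align_overlap(a: str, b: str) -> tuple[str, str]:
    """Trim two unaligned sequences to their aligned overlap.

    Local pairwise alignment (gap-averse scoring, suited to indel-free
    protein-coding barcodes); returns the two equal-length sub-sequences
    restricted to columns where both are ungapped, ready for
    :func:`p_distance`.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -2
    best = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
    coords = best.coordinates
    sa, sb = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:  # aligned block
            sa.append(best.sequences[0][a0:a1])
            sb.append(best.sequences[1][b0:b1])
    return "".join(sa), "".join(sb)
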