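"""I/O for the formats the toolkit touches: FASTA, sample sheets, Newick,
and square distance-matrix TSVs, plus validated labeled alignments."""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

from Bio import SeqIO as _BioSeqIO

from sscoi.alphabet import ALPHABET

PathLike = Union[str, Path]


class Role(enum.Enum):
    """Membership of a record in the diagnostic design problem."""

    TARGET = "target"
    NON_TARGET = "non_target"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Role":
        normalized = text.strip().lower().replace("-", "_").replace(" ", "_")
        for member in cls:
            if member.value == normalized:
                return member
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(f"unknown role {text!r}; allowed roles: {allowed}")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA record: unique id, species label, role, and residues.

    Residues are canonical uppercase IUPAC DNA (U converted to T on ingest);
    gaps allowed.
    """

    id: str
    residues: str
    species: str = ""
    role: Role = Role.UNKNOWN
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, char in enumerate(self.residues):
            if char not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {char!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


def _normalize(raw: str) -> str:
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class LabeledAlignment:
    """Equal-length records, each carrying a species label and a role."""

    records: tuple[SequenceRecord, ...]
    n_columns: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            offenders = ", ".join(f"{r.id}={len(r)}" for r in self.records)
            raise ValueError(f"records have unequal lengths: {offenders}")
        object.__setattr__(self, "n_columns", lengths.pop())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def targets(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.role is Role.TARGET]

    def non_targets(self) -> list[SequenceRecord]:
        return [r for r in self.records if r.role is Role.NON_TARGET]

    def nontarget_species(self) -> dict[str, list[SequenceRecord]]:
        groups: dict[str, list[SequenceRecord]] = {}
        for rec in self.non_targets():
            groups.setdefault(rec.species, []).append(rec)
        return groups


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA file into validated records.

    The record id is the first whitespace-separated token of the header; the
    remainder is preserved as the description. Residues are uppercased and
    U is converted to T. Duplicate ids, empty sequences and non-IUPAC
    characters are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in _BioSeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise ValueError(f"duplicate id {bio_rec.id!r} in {path}")
        seen.add(bio_rec.id)
        desc = bio_rec.description
        if desc.startswith(bio_rec.id):
            desc = desc[len(bio_rec.id):].strip()
        records.append(
            SequenceRecord(
                id=bio_rec.id,
                residues=_normalize(str(bio_rec.seq)),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_sample_sheet(path: PathLike) -> dict[str, tuple[str, Role]]:
    """Read a TSV with header columns id, species, role.

    Role text is parsed case-insensitively into the Role enum; repeated ids
    and unknown role values are errors.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for required in ("id", "species", "role"):
            if required not in header:
                raise ValueError(f"sample sheet {path}: missing column {required!r}")
        mapping: dict[str, tuple[str, Role]] = {}
        for row in reader:
            rec_id = (row["id"] or "").strip()
            if not rec_id:
                raise ValueError(f"sample sheet {path}: empty id")
            if rec_id in mapping:
                raise ValueError(f"sample sheet {path}: id {rec_id!r} repeated")
            mapping[rec_id] = ((row["species"] or "").strip(), Role.parse(row["role"] or ""))
    return mapping


def write_sample_sheet(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("id\tspecies\trole\n")
        for rec in records:
            handle.write(f"{rec.id}\t{rec.species}\t{rec.role.value}\n")


def as_alignment(
    records: Iterable[SequenceRecord], labels: Mapping[str, tuple[str, Role]]
) -> LabeledAlignment:
    """Attach species/role labels to records and enforce alignment invariants."""
    labeled = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"unlabeled record {rec.id!r}: id missing from sample sheet")
        species, role = labels[rec.id]
        labeled.append(replace(rec, species=species, role=role))
    return LabeledAlignment(records=tuple(labeled))


def write_newick(tree) -> str:
    """Serialize an unrooted tree to Newick.

    Branch lengths to 6 decimals; integer-percent bootstrap support, when
    present, is written as the internal node label of the child node of the
    supported edge. Output round-trips through a standard Newick parser.
    """
    adjacency = tree.adjacency()

    def render(node: int, parent: int | None) -> str:
        children = [(nbr, length, support) for nbr, length, support in adjacency[node] if nbr != parent]
        if not children:
            return tree.leaf_labels[node]
        parts = []
        for child, length, support in children:
            sub = render(child, node)
            if support is not None and child not in tree.leaf_labels:
                sub += str(int(support))
            parts.append(f"{sub}:{length:.6f}")
        return "(" + ",".join(parts) + ")"

    root = tree.newick_root()
    return render(root, None) + ";"


def write_matrix_tsv(matrix) -> str:
    """Square TSV of a distance matrix, values at 2 decimals, diagonal 0.00."""
    out = io.StringIO()
    labels = list(matrix.labels)
    out.write("\t".join([""] + labels) + "\n")
    for i, label in enumerate(labels):
        cells = [label] + [f"{matrix.d[i, j]:.2f}" for j in range(len(labels))]
        out.write("\t".join(cells) + "\n")
    return out.getvalue()
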