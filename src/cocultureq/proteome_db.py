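"""Strain-tagged protein sequence databases.

A two-member co-culture is searched against a single merged FASTA
database containing the proteomes of both strains. Downstream stages
(strain assignment, normalization, shared-peptide analysis) need to know
which strain each accession belongs to, so every record read here is
tagged with a strain label and the merged database keeps an explicit
accession-to-strain map that can be written out as a sidecar table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard residues plus the ambiguity/rare codes tolerated at
#: parse time (their handling is decided by each consumer).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")

AMBIGUOUS_RESIDUES = frozenset("XBZ")


class UnknownAccessionError(KeyError):
    """Raised when an accession is not present in the database."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: accession, free-text description, sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"{self.accession}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeDatabase:
    """Ordered protein records with an accession -> strain label map."""

    records: list[ProteinRecord] = field(default_factory=list)
    strain_of_accession: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession: {rec.accession}")
            seen.add(rec.accession)
            if rec.accession not in self.strain_of_accession:
                raise ValueError(
                    f"accession {rec.accession} has no strain label"
                )

    @property
    def strain_labels(self) -> list[str]:
        """Strain labels in order of first appearance (one or two)."""
        out: list[str] = []
        for rec in self.records:
            label = self.strain_of_accession[rec.accession]
            if label not in out:
                out.append(label)
        return out

    def strain_of(self, accession: str) -> str:
        """Return the strain label of ``accession``.

        Raises :class:`UnknownAccessionError` for accessions not in the
        database, so callers can distinguish the failure from any valid
        strain label.
        """
        try:
            return self.strain_of_accession[accession]
        except KeyError:
            raise UnknownAccessionError(accession) from None

    def subset(self, strain_label: str) -> "ProteomeDatabase":
        """Records belonging to one strain, in database order."""
        recs = [
            r
            for r in self.records
            if self.strain_of_accession[r.accession] == strain_label
        ]
        return ProteomeDatabase(
            records=recs,
            strain_of_accession={r.accession: strain_label for r in recs},
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)


def read_fasta(path: str | Path, strain_label: str) -> ProteomeDatabase:
    """Read a FASTA file and tag every record with ``strain_label``.

    The accession is the header token before the first whitespace (the
    same token MaxQuant echoes in ``proteinGroups.txt``); the rest of
    the header line becomes the description. Sequences are upper-cased
    and validated against the allowed residue alphabet.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        description = entry.description[len(entry.id):].strip()
        sequence = str(entry.seq).upper().strip()
        records.append(ProteinRecord(accession, description, sequence))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return ProteomeDatabase(
        records=records,
        strain_of_accession={r.accession: strain_label for r in records},
    )


def write_fasta(db: ProteomeDatabase, path: str | Path, width: int = 60) -> None:
    """Write the database back to FASTA, wrapping sequence lines."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in db.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def build_merged_database(
    db_a: ProteomeDatabase, db_b: ProteomeDatabase
) -> ProteomeDatabase:
    """Concatenate two single-strain databases into the merged reference.

    Record order is preserved (all of ``db_a`` then all of ``db_b``); a
    protein cannot belong to two strains, so any accession present in
    both inputs is a hard error.
    """
    labels_a = set(db_a.strain_of_accession.values())
    labels_b = set(db_b.strain_of_accession.values())
    if labels_a & labels_b:
        raise ValueError(
            f"strain labels must be distinct, both use {labels_a & labels_b}"
        )
    overlap = set(db_a.strain_of_accession) & set(db_b.strain_of_accession)
    if overlap:
        raise ValueError(
            "accessions present in both databases: "
            + ", ".join(sorted(overlap))
        )
    return ProteomeDatabase(
        records=list(db_a.records) + list(db_b.records),
        strain_of_accession={
            **db_a.strain_of_accession,
            **db_b.strain_of_accession,
        },
    )


def write_strain_map(db: ProteomeDatabase, path: str | Path) -> None:
    """Write the accession -> strain table (tab-separated, with header)."""
    with open(path, "w") as fh:
        fh.write("accession\tstrain\n")
        for rec in db.records:
            fh.write(f"{rec.accession}\t{db.strain_of_accession[rec.accession]}\n")


def read_strain_map(path: str | Path) -> dict[str, str]:
    """Read a sidecar strain-map table written by :func:`write_strain_map`."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("accession"):
            raise ValueError(f"{path}: expected 'accession\\tstrain' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            acc, strain = parts
            if acc in mapping:
                raise ValueError(f"{path}: duplicate accession {acc}")
            mapping[acc] = strain
    return mapping
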