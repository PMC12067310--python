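"""In-silico tryptic digestion and shared-peptide analysis.

Peptides whose sequence occurs in both strains' proteomes cannot be
attributed to either organism and corrupt strain-resolved
quantification, so a co-culture design should be checked for them up
front. This module enumerates Trypsin/P peptides (cleavage after every
K or R, including before proline, matching the MaxQuant search setting)
and compares the distinct peptide sequence sets of the two strains,
both theoretically from FASTA and as observed in a MaxQuant
``peptides.txt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from cocultureq.proteome_db import ProteomeDatabase, UnknownAccessionError


class Peptide(NamedTuple):
    """A digestion product with 1-based inclusive coordinates."""

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int


@dataclass
class SharedPeptideReport:
    """Distinct-peptide overlap between the two strains."""

    strain_a: str
    strain_b: str
    n_distinct_a: int
    n_distinct_b: int
    n_shared: int
    shared_sequences: set[str] = field(default_factory=set)
    affected_accessions_a: set[str] = field(default_factory=set)
    affected_accessions_b: set[str] = field(default_factory=set)

    @property
    def fraction_shared_a(self) -> float:
        return self.n_shared / self.n_distinct_a if self.n_distinct_a else 0.0

    @property
    def fraction_shared_b(self) -> float:
        return self.n_shared / self.n_distinct_b if self.n_distinct_b else 0.0

    def summary_lines(self) -> list[str]:
        return [
            f"strain\tdistinct_peptides\tshared\tfraction_shared\taffected_proteins",
            f"{self.strain_a}\t{self.n_distinct_a}\t{self.n_shared}"
            f"\t{self.fraction_shared_a:.6f}\t{len(self.affected_accessions_a)}",
            f"{self.strain_b}\t{self.n_distinct_b}\t{self.n_shared}"
            f"\t{self.fraction_shared_b:.6f}\t{len(self.affected_accessions_b)}",
        ]


def _cleavage_sites(sequence: str) -> list[int]:
    # Trypsin/P: cut after every K or R, proline does not block.
    return [i + 1 for i, ch in enumerate(sequence) if ch in "KR"]


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 0,
    accession: str = "",
    rule: str = "trypsin/p",
) -> list[Peptide]:
    """Enumerate tryptic peptides of one protein.

    With ``missed_cleavages = m`` every peptide spanning 0..m internal
    cleavage sites is produced. ``rule="trypsin"`` applies classical
    trypsin (no cleavage before proline); the default Trypsin/P cleaves
    after every K/R.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 0 <= missed_cleavages <= 3:
        raise ValueError("missed_cleavages must be in 0..3")
    if rule not in ("trypsin/p", "trypsin"):
        raise ValueError(f"unknown digestion rule {rule!r}")
    sites = _cleavage_sites(sequence)
    if rule == "trypsin":
        sites = [s for s in sites if s == len(sequence) or sequence[s] != "P"]
    # boundaries delimit the fully-cleaved fragments
    bounds = [0] + [s for s in sites if s < len(sequence)] + [len(sequence)]
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for mc in range(missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(sequence[start:end], accession, start + 1, end, mc)
            )
    return peptides


def digest_database(
    db: ProteomeDatabase,
    min_len: int,
    max_len: int,
    missed_cleavages: int = 0,
    rule: str = "trypsin/p",
) -> dict[str, set[str]]:
    """Distinct retained peptide sequences per accession."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    out: dict[str, set[str]] = {}
    for rec in db:
        peps = digest_tryptic(rec.sequence, missed_cleavages, rec.accession, rule)
        out[rec.accession] = {
            p.sequence for p in peps if min_len <= len(p.sequence) <= max_len
        }
    return out


def theoretical_shared_peptides(
    db_a: ProteomeDatabase,
    db_b: ProteomeDatabase,
    min_len: int = 8,
    max_len: int = 25,
    missed_cleavages: int = 0,
    collapse_il: bool = False,
) -> SharedPeptideReport:
    """Overlap of theoretical tryptic peptides between two proteomes.

    Every protein of each database is digested, peptides outside the
    ``min_len..max_len`` residue window (default 8-25, the typical
    detectable size range) are discarded, and the distinct sequence sets
    are intersected by exact string equality. ``collapse_il=True``
    treats isoleucine and leucine as equivalent (isobaric residues a
    mass spectrometer cannot distinguish) for a conservative overlap
    estimate.
    """
    if len(db_a) == 0 or len(db_b) == 0:
        raise ValueError("both databases must be non-empty")

    def canon(s: str) -> str:
        return s.replace("I", "L") if collapse_il else s

    per_acc_a = digest_database(db_a, min_len, max_len, missed_cleavages)
    per_acc_b = digest_database(db_b, min_len, max_len, missed_cleavages)
    set_a = {canon(p) for peps in per_acc_a.values() for p in peps}
    set_b = {canon(p) for peps in per_acc_b.values() for p in peps}
    shared = set_a & set_b
    return SharedPeptideReport(
        strain_a=db_a.strain_labels[0],
        strain_b=db_b.strain_labels[0],
        n_distinct_a=len(set_a),
        n_distinct_b=len(set_b),
        n_shared=len(shared),
        shared_sequences=shared,
        affected_accessions_a={
            acc for acc, peps in per_acc_a.items()
            if any(canon(p) in shared for p in peps)
        },
        affected_accessions_b={
            acc for acc, peps in per_acc_b.items()
            if any(canon(p) in shared for p in peps)
        },
    )


def observed_shared_peptides(peptide_table, db: ProteomeDatabase) -> SharedPeptideReport:
    """Classify observed peptides from a MaxQuant peptides table by strain.

    Each peptide row maps to one or more accessions; a row whose
    accessions span both strains is counted as shared. Accessions absent
    from the merged database are a hard error (they indicate a
    database/search mismatch).
    """
    labels = db.strain_labels
    if len(labels) != 2:
        raise ValueError("observed shared-peptide analysis needs a merged 2-strain database")
    strain_a, strain_b = labels
    set_a: set[str] = set()
    set_b: set[str] = set()
    shared: set[str] = set()
    affected_a: set[str] = set()
    affected_b: set[str] = set()
    unknown: set[str] = set()
    for seq, accessions in peptide_table.iter_rows():
        strains = set()
        for acc in accessions:
            try:
                strains.add(db.strain_of(acc))
            except UnknownAccessionError:
                unknown.add(acc)
        if unknown:
            continue
        if strain_a in strains:
            set_a.add(seq)
        if strain_b in strains:
            set_b.add(seq)
        if strain_a in strains and strain_b in strains:
            shared.add(seq)
            affected_a.update(a for a in accessions if db.strain_of(a) == strain_a)
            affected_b.update(a for a in accessions if db.strain_of(a) == strain_b)
    if unknown:
        raise UnknownAccessionError(
            "accessions not in the merged database: " + ", ".join(sorted(unknown))
        )
    return SharedPeptideReport(
        strain_a=strain_a,
        strain_b=strain_b,
        n_distinct_a=len(set_a),
        n_distinct_b=len(set_b),
        n_shared=len(shared),
        shared_sequences=shared,
        affected_accessions_a=affected_a,
        affected_accessions_b=affected_b,
    )


def count_observable_peptides(sequence: str, min_len: int = 6, max_len: int = 30) -> int:
    """Number of distinct fully-cleaved tryptic peptides in a length window.

    This is the iBAQ divisor: intensity / observable-peptide count gives
    an absolute-abundance proxy. The default 6-30 residue window is the
    standard iBAQ convention.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    peps = digest_tryptic(sequence, missed_cleavages=0)
    return len({p.sequence for p in peps if min_len <= len(p.sequence) <= max_len})
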