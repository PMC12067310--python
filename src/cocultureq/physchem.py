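"""Physicochemical proteome profiling: pI, molecular weight, GRAVY.

Before committing to a co-culture proteomics experiment it is worth
checking whether the two proteomes differ systematically in properties
that bias protein extraction and peptide ionization: isoelectric point
(pI), molecular weight (MW) and hydrophobicity (grand average of
hydropathy, GRAVY). This module computes all three per protein and
summarizes their distributions per strain.

The numeric scales are explicit and overridable: pKa values default to
the EMBOSS set, hydropathy to Kyte-Doolittle, and masses to standard
average residue masses, so alternative published scales (e.g.
Bjellqvist pKa values) can be swapped in to reproduce other tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cocultureq.proteome_db import ProteomeDatabase

# Average (isotope-abundance-weighted) residue masses, Da.
_AVERAGE_RESIDUE_MASSES = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    # selenocysteine: rare but mass-defined
    "U": 150.0379,
}

# Kyte & Doolittle hydropathy index.
_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# EMBOSS pKa set. Keys "Nterm"/"Cterm" are the free termini.
_EMBOSS_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_EMBOSS_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

WATER_MASS = 18.0153


@dataclass(frozen=True)
class PhyschemScales:
    """The numeric tables behind MW, GRAVY and charge calculations."""

    residue_average_masses: dict[str, float] = field(
        default_factory=lambda: dict(_AVERAGE_RESIDUE_MASSES)
    )
    water_mass: float = WATER_MASS
    hydropathy: dict[str, float] = field(
        default_factory=lambda: dict(_KYTE_DOOLITTLE)
    )
    pka_positive: dict[str, float] = field(
        default_factory=lambda: dict(_EMBOSS_PKA_POSITIVE)
    )
    pka_negative: dict[str, float] = field(
        default_factory=lambda: dict(_EMBOSS_PKA_NEGATIVE)
    )

    def __post_init__(self) -> None:
        for table in (self.pka_positive, self.pka_negative):
            for group, pka in table.items():
                if not 0 < pka < 14:
                    raise ValueError(f"pKa of {group} out of (0, 14): {pka}")


DEFAULT_SCALES = PhyschemScales()


def compute_mw(
    sequence: str,
    scales: PhyschemScales = DEFAULT_SCALES,
    on_unknown: str = "error",
) -> float:
    """Molecular weight in Daltons: sum of residue masses plus one water.

    Residues without a mass entry (the ambiguity codes X, B, Z) raise an
    error unless ``on_unknown="skip"``, in which case they contribute
    zero mass and a warning is emitted.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"unknown policy {on_unknown!r}")
    masses = scales.residue_average_masses
    total = scales.water_mass
    skipped = 0
    for pos, ch in enumerate(sequence, start=1):
        m = masses.get(ch)
        if m is None:
            if on_unknown == "error":
                raise ValueError(
                    f"residue {ch!r} at position {pos} has no mass entry"
                )
            skipped += 1
            continue
        total += m
    if skipped:
        warnings.warn(
            f"{skipped} residue(s) without mass entries contributed 0 Da",
            stacklevel=2,
        )
    return total


def compute_gravy(sequence: str, scales: PhyschemScales = DEFAULT_SCALES) -> float:
    """Grand average of hydropathy: mean hydropathy over scored residues.

    Residues absent from the hydropathy table (X, B, Z, U) are excluded
    from the mean; a sequence with no scored residue is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    values = [scales.hydropathy[ch] for ch in sequence if ch in scales.hydropathy]
    if not values:
        raise ValueError("no residue in sequence has a hydropathy value")
    return float(np.mean(values))


def net_charge(
    sequence: str, ph: float, scales: PhyschemScales = DEFAULT_SCALES
) -> float:
    """Net charge at ``ph`` by Henderson-Hasselbalch summation.

    Exactly one free N-terminus and one free C-terminus are included;
    each positive group contributes ``1/(1+10^(pH-pKa))`` and each
    negative group ``-1/(1+10^(pKa-pH))``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 0 <= ph <= 14:
        raise ValueError(f"pH out of [0, 14]: {ph}")
    charge = 1.0 / (1.0 + 10.0 ** (ph - scales.pka_positive["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (scales.pka_negative["Cterm"] - ph))
    for ch in sequence:
        pka = scales.pka_positive.get(ch)
        if pka is not None:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
            continue
        pka = scales.pka_negative.get(ch)
        if pka is not None:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    return charge


def compute_pi(
    sequence: str,
    scales: PhyschemScales = DEFAULT_SCALES,
    tol: float = 0.001,
    max_iter: int = 50,
) -> float:
    """Theoretical isoelectric point by bisection on the net charge.

    ``net_charge`` is strictly decreasing in pH, so the zero crossing on
    [0, 14] is unique; bisection narrows the bracket until it is smaller
    than ``tol`` pH units. If the charge does not change sign on the
    bracket (possible for extreme compositions) the bracket end with the
    smaller absolute charge is returned.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(sequence, lo, scales)
    c_hi = net_charge(sequence, hi, scales)
    if c_lo <= 0:
        return lo
    if c_hi >= 0:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, scales) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def proteome_profile(
    db: ProteomeDatabase, scales: PhyschemScales = DEFAULT_SCALES
) -> pd.DataFrame:
    """Per-protein physicochemical profile of a (possibly merged) database.

    Returns one row per record with columns ``accession, strain, length,
    mw_da, pi, gravy``. A protein whose computation fails (e.g. an
    all-ambiguous sequence) is kept as a row with NaN values and the
    error text in an ``error`` column rather than aborting the profile.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    rows = []
    for rec in db:
        strain = db.strain_of_accession[rec.accession]
        row = {
            "accession": rec.accession,
            "strain": strain,
            "length": len(rec.sequence),
            "mw_da": np.nan,
            "pi": np.nan,
            "gravy": np.nan,
            "error": "",
        }
        try:
            row["mw_da"] = compute_mw(rec.sequence, scales, on_unknown="skip")
            row["pi"] = compute_pi(rec.sequence, scales)
            row["gravy"] = compute_gravy(rec.sequence, scales)
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-strain five-number summaries of length, MW, pI and GRAVY."""
    quantities = ["length", "mw_da", "pi", "gravy"]
    blocks = []
    for strain, grp in profile.groupby("strain", sort=False):
        for q in quantities:
            vals = grp[q].dropna()
            blocks.append(
                {
                    "strain": strain,
                    "quantity": q,
                    "n": len(vals),
                    "min": vals.min(),
                    "q25": vals.quantile(0.25),
                    "median": vals.median(),
                    "q75": vals.quantile(0.75),
                    "max": vals.max(),
                }
            )
    return pd.DataFrame(blocks)


def write_profile(
    profile: pd.DataFrame, path: str | Path, summary_path: str | Path | None = None
) -> None:
    """Write the profile (and optionally its summary) as tab-separated tables."""
    profile.to_csv(path, sep="\t", index=False, float_format="%.4f")
    if summary_path is not None:
        profile_summary(profile).to_csv(
            summary_path, sep="\t", index=False, float_format="%.4f"
        )
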