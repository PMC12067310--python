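"""Readers and writers for MaxQuant table dialects and the design file.

MaxQuant's ``proteinGroups.txt`` and ``peptides.txt`` are tab-separated
tables with per-sample intensity blocks (``LFQ intensity <label>``,
``iBAQ <label>``), ``+``/blank flag columns, and 0 encoding a missing
intensity. On read, zeros become explicit NaN so they can never leak
into strain totals or log transforms; on write they go back to 0 so the
output remains a valid MaxQuant-dialect file for downstream tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

LFQ_PREFIX = "LFQ intensity "
IBAQ_PREFIX = "iBAQ "
MAJORITY_COL = "Majority protein IDs"
PEPTIDES_COL = "Peptides"
UNIQUE_PEPTIDES_COL = "Unique peptides"
FLAG_COLS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}


@dataclass
class ProteinGroupTable:
    """Parsed protein groups: metadata, flags and intensity blocks.

    ``meta`` holds one row per protein group (majority accession string,
    peptide counts, boolean flags); ``lfq`` and the optional ``ibaq``
    are aligned protein-by-sample matrices with NaN for missing.
    """

    meta: pd.DataFrame
    lfq: pd.DataFrame
    ibaq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.lfq.index):
            raise ValueError("meta and lfq must share an index")
        if self.ibaq is not None:
            if not self.meta.index.equals(self.ibaq.index):
                raise ValueError("meta and ibaq must share an index")
            if list(self.ibaq.columns) != list(self.lfq.columns):
                raise ValueError("lfq and ibaq sample labels differ")
        if (self.lfq.to_numpy() < 0).any():
            raise ValueError("negative LFQ intensity")
        bad = self.meta[PEPTIDES_COL] < self.meta[UNIQUE_PEPTIDES_COL]
        if bad.any():
            raise ValueError(
                f"unique peptide count exceeds peptide count in {int(bad.sum())} rows"
            )

    @property
    def sample_labels(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def majority_accessions(self) -> pd.Series:
        return self.meta[MAJORITY_COL]

    def accession_lists(self) -> list[list[str]]:
        return [s.split(";") for s in self.meta[MAJORITY_COL]]

    def __len__(self) -> int:
        return len(self.meta)

    def take(self, mask_or_index) -> "ProteinGroupTable":
        """Row subset preserving alignment of all blocks."""
        meta = self.meta.loc[mask_or_index]
        return ProteinGroupTable(
            meta=meta,
            lfq=self.lfq.loc[meta.index],
            ibaq=None if self.ibaq is None else self.ibaq.loc[meta.index],
        )


@dataclass
class PeptideTable:
    """Parsed ``peptides.txt``: peptide sequence plus parent accessions."""

    df: pd.DataFrame  # columns: Sequence, Proteins

    def __len__(self) -> int:
        return len(self.df)

    def iter_rows(self) -> Iterator[tuple[str, list[str]]]:
        for seq, prot in zip(self.df["Sequence"], self.df["Proteins"]):
            accessions = [a for a in str(prot).split(";") if a]
            yield seq, accessions


@dataclass
class ExperimentalDesign:
    """Sample label -> condition -> replicate mapping."""

    df: pd.DataFrame  # columns: label, condition, replicate

    def __post_init__(self) -> None:
        df = self.df
        if df["label"].duplicated().any():
            dups = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate sample labels: {dups}")
        if df.empty:
            raise ValueError("design has no samples")
        for cond, grp in df.groupby("condition"):
            if grp["replicate"].duplicated().any():
                raise ValueError(f"duplicate replicate index within condition {cond}")

    @property
    def labels(self) -> list[str]:
        return list(self.df["label"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        sel = self.df[self.df["condition"] == condition]
        if sel.empty:
            raise ValueError(f"unknown condition {condition!r}")
        return list(sel["label"])

    def validate_against(self, sample_labels: list[str]) -> None:
        missing = [s for s in self.labels if s not in sample_labels]
        if missing:
            raise ValueError(
                f"design samples absent from the quant table: {missing}"
            )


def read_protein_groups(path: str | Path) -> ProteinGroupTable:
    """Parse a MaxQuant-dialect ``proteinGroups.txt``.

    Sample labels are discovered by stripping the ``LFQ intensity ``
    prefix; an iBAQ block is picked up when every sample has a matching
    ``iBAQ <label>`` column. Missing flag columns default to all-false
    with a warning so minimal tables remain readable.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if MAJORITY_COL not in raw.columns:
        raise ValueError(f"{path}: missing required column {MAJORITY_COL!r}")
    samples = [c[len(LFQ_PREFIX):] for c in raw.columns if c.startswith(LFQ_PREFIX)]
    if not samples:
        raise ValueError(f"{path}: no '{LFQ_PREFIX}<sample>' columns found")

    def numeric_block(prefix: str, labels: list[str]) -> pd.DataFrame:
        block = {}
        for s in labels:
            col = prefix + s
            try:
                block[s] = pd.to_numeric(raw[col])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}")
        df = pd.DataFrame(block, index=raw.index)
        return df.where(df > 0)  # 0 encodes missing

    lfq = numeric_block(LFQ_PREFIX, samples)
    ibaq = None
    if all(IBAQ_PREFIX + s in raw.columns for s in samples):
        ibaq = numeric_block(IBAQ_PREFIX, samples)

    meta = pd.DataFrame(index=raw.index)
    meta[MAJORITY_COL] = raw[MAJORITY_COL]
    if PEPTIDES_COL not in raw.columns:
        raise ValueError(f"{path}: missing required column {PEPTIDES_COL!r}")
    meta[PEPTIDES_COL] = pd.to_numeric(raw[PEPTIDES_COL]).astype(int)
    if UNIQUE_PEPTIDES_COL in raw.columns:
        meta[UNIQUE_PEPTIDES_COL] = pd.to_numeric(raw[UNIQUE_PEPTIDES_COL]).astype(int)
    else:
        warnings.warn(
            f"{path}: no {UNIQUE_PEPTIDES_COL!r} column; using {PEPTIDES_COL!r}",
            stacklevel=2,
        )
        meta[UNIQUE_PEPTIDES_COL] = meta[PEPTIDES_COL]
    for key, col in FLAG_COLS.items():
        if col in raw.columns:
            meta[key] = raw[col].str.strip() == "+"
        else:
            warnings.warn(f"{path}: no {col!r} column; assuming all rows pass", stacklevel=2)
            meta[key] = False
    return ProteinGroupTable(meta=meta, lfq=lfq, ibaq=ibaq)


def write_protein_groups(table: ProteinGroupTable, path: str | Path) -> None:
    """Write a table back to the MaxQuant dialect (missing -> 0).

    Intensities are written with 10 significant digits so normalized
    fractions round-trip; flags become ``+``/blank.
    """
    out = pd.DataFrame(index=table.meta.index)
    out[MAJORITY_COL] = table.meta[MAJORITY_COL]
    out[PEPTIDES_COL] = table.meta[PEPTIDES_COL]
    out[UNIQUE_PEPTIDES_COL] = table.meta[UNIQUE_PEPTIDES_COL]
    for s in table.sample_labels:
        out[LFQ_PREFIX + s] = table.lfq[s].fillna(0.0)
    if table.ibaq is not None:
        for s in table.sample_labels:
            out[IBAQ_PREFIX + s] = table.ibaq[s].fillna(0.0)
    for key, col in FLAG_COLS.items():
        out[col] = np.where(table.meta[key], "+", "")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peptides_table(path: str | Path) -> PeptideTable:
    """Parse a MaxQuant-dialect ``peptides.txt`` (Sequence + Proteins)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Sequence", "Proteins"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["Sequence"].str.len() == 0).any():
        raise ValueError(f"{path}: empty peptide sequence")
    return PeptideTable(df=df[["Sequence", "Proteins"]].copy())


def read_design(path: str | Path) -> ExperimentalDesign:
    """Read the experimental design (tab- or comma-separated).

    Column names are matched case-insensitively against
    ``label, condition, replicate``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("label", "condition", "replicate"):
            rename[col] = low
    df = df.rename(columns=rename)
    missing = {"label", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing design columns {sorted(missing)}")
    df = df[["label", "condition", "replicate"]].copy()
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    return ExperimentalDesign(df=df)


def write_design(design: ExperimentalDesign, path: str | Path) -> None:
    design.df.to_csv(path, sep="\t", index=False)
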