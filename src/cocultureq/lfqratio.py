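"""The core normalization: strain assignment and LFQRatio.

In a co-culture, a shift in the ratio of the two cell types between
conditions changes every protein's measured LFQ intensity even when
per-cell expression is constant, flooding a differential-expression
analysis with false positives. LFQRatio removes this compositional bias
by expressing each protein as a fraction of its own strain's total LFQ
signal in the same sample:

    normalized intensity = LFQ intensity / sum of LFQ intensities of
                           all proteins assigned to the same strain

The module also applies the standard pre-filters (decoys, contaminants,
site-only identifications, minimum peptide evidence) and computes the
per-strain iBAQ dynamic-range summary used to compare how deep each
proteome is sampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cocultureq.proteome_db import ProteomeDatabase
from cocultureq.quant_io import (
    MAJORITY_COL,
    PEPTIDES_COL,
    UNIQUE_PEPTIDES_COL,
    ProteinGroupTable,
)

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"


@dataclass
class StrainAssignment:
    """Per-group strain class: a strain label, 'ambiguous' or 'unknown'."""

    labels: pd.Series  # aligned to the table rows
    strain_labels: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def rows_of(self, strain: str) -> pd.Index:
        return self.labels.index[self.labels == strain]


@dataclass
class QuantMatrix:
    """Protein-group x sample matrix with explicit missingness.

    ``value_kind`` tracks the scale of the values: raw LFQ intensities,
    LFQRatio strain fractions, or log2-transformed values.
    """

    values: pd.DataFrame  # rows = groups, columns = samples, NaN = missing
    strain: pd.Series  # aligned to rows
    accession: pd.Series  # majority accession string, aligned to rows
    value_kind: str = "raw_lfq"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.strain.index):
            raise ValueError("values and strain must share an index")
        if not self.values.index.equals(self.accession.index):
            raise ValueError("values and accession must share an index")
        if self.value_kind not in ("raw_lfq", "strain_fraction", "log2"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def sample_labels(self) -> list[str]:
        return list(self.values.columns)

    def subset_strain(self, strain: str) -> "QuantMatrix":
        idx = self.strain.index[self.strain == strain]
        return QuantMatrix(
            values=self.values.loc[idx],
            strain=self.strain.loc[idx],
            accession=self.accession.loc[idx],
            value_kind=self.value_kind,
            scale=self.scale,
        )


@dataclass
class FilterLog:
    """How many rows each pre-filter removed."""

    n_input: int = 0
    n_reverse: int = 0
    n_contaminant: int = 0
    n_only_by_site: int = 0
    n_few_peptides: int = 0
    n_kept: int = 0


def filter_groups(
    table: ProteinGroupTable,
    min_peptides: int = 2,
    use_unique: bool = False,
    filter_log: FilterLog | None = None,
) -> ProteinGroupTable:
    """Apply the standard protein-group pre-filters.

    Removes reverse (decoy) hits, potential contaminants, groups
    identified only by a modification site, and groups supported by
    fewer than ``min_peptides`` peptides (``use_unique=True`` counts
    unique peptides only, the stricter variant used when comparing
    identified proteome sizes).
    """
    meta = table.meta
    count_col = UNIQUE_PEPTIDES_COL if use_unique else PEPTIDES_COL
    flag_any = meta["reverse"] | meta["contaminant"] | meta["only_by_site"]
    few = meta[count_col] < min_peptides
    keep = ~flag_any & ~few
    if filter_log is not None:
        filter_log.n_input = len(meta)
        filter_log.n_reverse = int(meta["reverse"].sum())
        filter_log.n_contaminant = int((meta["contaminant"] & ~meta["reverse"]).sum())
        filter_log.n_only_by_site = int(
            (meta["only_by_site"] & ~meta["reverse"] & ~meta["contaminant"]).sum()
        )
        filter_log.n_few_peptides = int((few & ~flag_any).sum())
        filter_log.n_kept = int(keep.sum())
    logger.info(
        "filter_groups: %d/%d rows kept (reverse=%d contaminant=%d "
        "only_by_site=%d <%d peptides=%d)",
        int(keep.sum()), len(meta), int(meta["reverse"].sum()),
        int(meta["contaminant"].sum()), int(meta["only_by_site"].sum()),
        min_peptides, int(few.sum()),
    )
    if not keep.any():
        raise ValueError(
            "all protein groups removed by filtering; review flag columns "
            f"and the min_peptides={min_peptides} threshold"
        )
    return table.take(keep)


def assign_strain_to_groups(
    table: ProteinGroupTable,
    db: ProteomeDatabase,
    allow_unknown: bool = False,
) -> StrainAssignment:
    """Map each protein group to a strain via its majority accessions.

    A group whose accessions all belong to one strain is assigned to it;
    accessions from both strains make the group 'ambiguous'. Accessions
    missing from the merged database are a hard error unless
    ``allow_unknown`` marks those groups 'unknown' instead.
    """
    classes = []
    offenders: set[str] = set()
    for accessions in table.accession_lists():
        strains = set()
        missing = False
        for acc in accessions:
            strain = db.strain_of_accession.get(acc)
            if strain is None:
                offenders.add(acc)
                missing = True
            else:
                strains.add(strain)
        if missing:
            classes.append(UNKNOWN)
        elif len(strains) == 1:
            classes.append(next(iter(strains)))
        else:
            classes.append(AMBIGUOUS)
    if offenders and not allow_unknown:
        raise KeyError(
            "accessions absent from the reference database: "
            + ", ".join(sorted(offenders))
        )
    labels = pd.Series(classes, index=table.meta.index, name="strain")
    assignment = StrainAssignment(labels=labels, strain_labels=db.strain_labels)
    logger.info("assign_strain_to_groups: %s", assignment.counts)
    return assignment


def lfqratio_normalize(
    table: ProteinGroupTable,
    assignment: StrainAssignment,
    scale: float = 1.0,
) -> QuantMatrix:
    """LFQRatio-normalize a filtered protein-group table.

    For every sample and strain, each protein's LFQ intensity is divided
    by the summed intensity of all proteins assigned to that strain in
    that sample (then multiplied by ``scale``). Ambiguous (cross-strain)
    groups are excluded from the totals and from the output, since their
    signal cannot be attributed to either organism. A strain with no
    quantified protein in some sample yields an all-missing block for
    that (strain, sample) with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    keep = assignment.labels.isin(assignment.strain_labels)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "lfqratio_normalize: excluding %d ambiguous/unknown groups", n_dropped
        )
    lfq = table.lfq.loc[keep[keep].index]
    strain = assignment.labels.loc[lfq.index]
    out = pd.DataFrame(np.nan, index=lfq.index, columns=lfq.columns)
    for g in assignment.strain_labels:
        rows = strain.index[strain == g]
        block = lfq.loc[rows]
        totals = block.sum(axis=0, skipna=True)  # NaN contributes 0
        for s in lfq.columns:
            total = totals[s]
            if total == 0 or np.isnan(total):
                warnings.warn(
                    f"no quantified {g} protein in sample {s}; block set missing",
                    stacklevel=2,
                )
                continue
            out.loc[rows, s] = block[s] / total * scale
    return QuantMatrix(
        values=out,
        strain=strain,
        accession=table.majority_accessions.loc[lfq.index],
        value_kind="strain_fraction",
        scale=scale,
    )


def raw_quant_matrix(
    table: ProteinGroupTable, assignment: StrainAssignment
) -> QuantMatrix:
    """Un-normalized LFQ matrix with the same row classes/exclusions."""
    keep = assignment.labels.isin(assignment.strain_labels)
    idx = keep[keep].index
    return QuantMatrix(
        values=table.lfq.loc[idx],
        strain=assignment.labels.loc[idx],
        accession=table.majority_accessions.loc[idx],
        value_kind="raw_lfq",
    )


def dynamic_range_summary(
    table: ProteinGroupTable, assignment: StrainAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain iBAQ dynamic range: rank vs log10 iBAQ.

    For each strain, proteins with a nonzero mean iBAQ intensity are
    ranked by descending abundance. Returns ``(series, summary)``: the
    rank/log10-iBAQ series for plotting abundance against protein
    number, and per-strain min/max/span statistics in log10 units.
    """
    if table.ibaq is None:
        raise ValueError(
            "no iBAQ columns in the protein-group table; enable iBAQ in the "
            "upstream search to use the dynamic-range assessment"
        )
    rows = []
    summaries = []
    for g in assignment.strain_labels:
        idx = assignment.rows_of(g)
        mean_ibaq = table.ibaq.loc[idx].mean(axis=1, skipna=True)
        mean_ibaq = mean_ibaq[mean_ibaq > 0].dropna()
        if mean_ibaq.empty:
            warnings.warn(f"strain {g}: no nonzero iBAQ values", stacklevel=2)
            continue
        log10 = np.log10(mean_ibaq.sort_values(ascending=False))
        for rank, (row, val) in enumerate(log10.items(), start=1):
            rows.append(
                {
                    "strain": g,
                    "rank": rank,
                    "accession": table.majority_accessions.loc[row],
                    "log10_ibaq": val,
                }
            )
        summaries.append(
            {
                "strain": g,
                "n_proteins": len(log10),
                "log10_min": float(log10.min()),
                "log10_max": float(log10.max()),
                "log10_span": float(log10.max() - log10.min()),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(summaries)
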