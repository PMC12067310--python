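"""Synthetic two-strain co-culture datasets with known ground truth.

The generative model mirrors what a co-culture measurement actually
convolves: measured protein intensity is proportional to (cells of the
strain in the sample) x (per-cell protein abundance). Each protein gets
a per-cell log2 abundance spanning a realistic dynamic range; each
condition fixes the strain-A : strain-B cell ratio; measured log2
intensity is per-cell abundance + log2(cell fraction) + Gaussian noise.
Low-intensity censoring (MNAR) and random dropout (MAR) remove values,
and the result is written in the MaxQuant table dialect together with
the FASTA databases, the experimental design and a truth table — so the
whole pipeline, from parsing through differential expression, can be
validated against known answers.

Strain proteomes are built from concatenated tryptic segments so that
digestion yields peptides in the detectable 8-25 residue window, and a
configurable fraction of strain-B proteins carries an exact copy of a
strain-A tryptic peptide to emulate cross-strain shared peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cocultureq.digestion import count_observable_peptides, digest_tryptic
from cocultureq.proteome_db import (
    ProteinRecord,
    ProteomeDatabase,
    build_merged_database,
    write_fasta,
    write_strain_map,
)
from cocultureq.quant_io import (
    FLAG_COLS,
    MAJORITY_COL,
    PEPTIDES_COL,
    UNIQUE_PEPTIDES_COL,
    ExperimentalDesign,
    ProteinGroupTable,
    write_design,
    write_protein_groups,
)

# interior residues of tryptic segments (no K/R, no ambiguity codes)
_SEGMENT_ALPHABET = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic co-culture.

    Defaults describe the headline scenario: two 1,000-protein
    proteomes, two conditions with the strain-A cell fraction shifting
    from 0.8 to 0.2 (a four-fold compositional swing), three replicates,
    log2 residual SD 0.3, a four-decade abundance range, 5% low-tail
    censoring plus 2% random dropout, and no truly changing proteins
    unless ``n_true_de`` is set.
    """

    n_proteins_a: int = 1000
    n_proteins_b: int = 1000
    protein_length_range: tuple[int, int] = (150, 450)
    conditions: list[tuple[str, float]] = field(
        default_factory=lambda: [("day0", 0.8), ("day4", 0.2)]
    )
    replicates: int = 3
    base_abundance_log10_range: tuple[float, float] = (6.0, 10.0)
    residual_sd: float = 0.3
    n_true_de: int = 0
    planted_lfc: float = 2.0
    mnar_quantile: float = 0.05
    mar_rate: float = 0.02
    shared_peptide_fraction: float = 0.05
    ibaq_peptide_window: tuple[int, int] = (6, 30)
    strain_a: str = "strainA"
    strain_b: str = "strainB"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        for name, r in self.conditions:
            if not 0 < r < 1:
                raise ValueError(f"condition {name}: cell fraction {r} not in (0, 1)")
        for frac in (self.mnar_quantile, self.mar_rate, self.shared_peptide_fraction):
            if not 0 <= frac < 1:
                raise ValueError(f"fraction {frac} not in [0, 1)")
        if not np.isfinite(self.planted_lfc):
            raise ValueError("planted_lfc must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    ``proteins``: per-protein strain, per-cell log2 abundance in the
    first condition, true-DE flag and true log2 fold change.
    ``samples``: per-sample condition and strain cell fractions.
    ``censored`` / ``dropped``: boolean protein x sample masks of
    MNAR-censored and MAR-dropped cells.
    """

    proteins: pd.DataFrame
    samples: pd.DataFrame
    censored: pd.DataFrame
    dropped: pd.DataFrame


def _random_protein(rng: np.random.Generator, target_len: int) -> str:
    parts: list[str] = []
    length = 0
    while length < target_len:
        seg_len = int(rng.integers(7, 25))  # peptide length 8..25 incl. K/R
        seg = "".join(rng.choice(_SEGMENT_ALPHABET, size=seg_len))
        term = "K" if rng.random() < 0.5 else "R"
        parts.append(seg + term)
        length += seg_len + 1
    return "".join(parts)


def _tryptic_window_peptides(seq: str, min_len: int = 8, max_len: int = 25) -> list[str]:
    return [
        p.sequence
        for p in digest_tryptic(seq)
        if min_len <= len(p.sequence) <= max_len
    ]


def simulate_proteomes(
    cfg: SyntheticConfig,
) -> tuple[ProteomeDatabase, ProteomeDatabase]:
    """Generate the two strain proteomes.

    A fraction ``shared_peptide_fraction`` of strain-B proteins receives
    one exact copy of a strain-A tryptic peptide, inserted at a cleavage
    boundary so it is a tryptic peptide of the strain-B protein too.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    lo, hi = cfg.protein_length_range

    def make_records(n: int, prefix: str) -> list[str]:
        return [_random_protein(rng, int(rng.integers(lo, hi + 1))) for _ in range(n)]

    seqs_a = make_records(cfg.n_proteins_a, "SA")
    seqs_b = make_records(cfg.n_proteins_b, "SB")

    n_planted = int(round(cfg.shared_peptide_fraction * cfg.n_proteins_b))
    planted_rows = rng.choice(cfg.n_proteins_b, size=n_planted, replace=False)
    for i in planted_rows:
        donor = seqs_a[int(rng.integers(cfg.n_proteins_a))]
        candidates = [p for p in _tryptic_window_peptides(donor) if p[-1] in "KR"]
        insert = candidates[int(rng.integers(len(candidates)))]
        seqs_b[i] = insert + seqs_b[i]  # tryptic peptide at the N-terminus

    def to_db(seqs: list[str], prefix: str, strain: str) -> ProteomeDatabase:
        records = [
            ProteinRecord(
                accession=f"{prefix}_{i + 1:05d}",
                description=f"synthetic {strain} protein {i + 1}",
                sequence=s,
            )
            for i, s in enumerate(seqs)
        ]
        return ProteomeDatabase(
            records=records,
            strain_of_accession={r.accession: strain for r in records},
        )

    return to_db(seqs_a, "SA", cfg.strain_a), to_db(seqs_b, "SB", cfg.strain_b)


def simulate_quant_table(
    cfg: SyntheticConfig,
    dbs: tuple[ProteomeDatabase, ProteomeDatabase],
) -> tuple[ProteinGroupTable, ExperimentalDesign, SyntheticTruth]:
    """Generate a MaxQuant-style protein-group table plus design + truth.

    Six rows that default filtering must remove are always injected:
    two reverse (decoy) hits, two potential contaminants and two
    single-peptide identifications, with MaxQuant-style ``REV__`` /
    ``CON__`` accession prefixes on the flagged rows.
    """
    rng = np.random.default_rng([cfg.seed, 22])
    db_a, db_b = dbs
    accs = [r.accession for r in db_a] + [r.accession for r in db_b]
    strains = [cfg.strain_a] * len(db_a) + [cfg.strain_b] * len(db_b)
    n = len(accs)
    log2_10 = np.log2(10.0)
    lo10, hi10 = cfg.base_abundance_log10_range
    base_log2 = rng.uniform(lo10 * log2_10, hi10 * log2_10, size=n)

    # plant true DE per strain, applied to every condition after the first
    true_lfc = np.zeros(n)
    for strain, offset, count in (
        (cfg.strain_a, 0, len(db_a)),
        (cfg.strain_b, len(db_a), len(db_b)),
    ):
        k = min(cfg.n_true_de, count)
        if k == 0:
            continue
        chosen = rng.choice(count, size=k, replace=False) + offset
        signs = rng.choice([-1.0, 1.0], size=k)
        true_lfc[chosen] = signs * cfg.planted_lfc

    samples, sample_rows = [], []
    for cond, frac_a in cfg.conditions:
        for rep in range(1, cfg.replicates + 1):
            label = f"{cond}_{rep}"
            samples.append((label, cond, rep, frac_a))
            sample_rows.append(
                {
                    "label": label,
                    "condition": cond,
                    "replicate": rep,
                    "fraction_a": frac_a,
                    "fraction_b": 1.0 - frac_a,
                }
            )

    strain_arr = np.array(strains)
    intensity = {}
    first_cond = cfg.conditions[0][0]
    for label, cond, rep, frac_a in samples:
        frac = np.where(strain_arr == cfg.strain_a, frac_a, 1.0 - frac_a)
        abund = base_log2 + (true_lfc if cond != first_cond else 0.0)
        measured = abund + np.log2(frac) + rng.normal(0.0, cfg.residual_sd, size=n)
        intensity[label] = 2.0 ** measured
    lfq = pd.DataFrame(intensity, index=pd.RangeIndex(n))

    # MNAR: censor the low-intensity tail per sample; MAR: random dropout
    censored = pd.DataFrame(False, index=lfq.index, columns=lfq.columns)
    dropped = pd.DataFrame(False, index=lfq.index, columns=lfq.columns)
    for col in lfq.columns:
        if cfg.mnar_quantile > 0:
            thresh = lfq[col].quantile(cfg.mnar_quantile)
            censored[col] = lfq[col] < thresh
        if cfg.mar_rate > 0:
            dropped[col] = rng.random(n) < cfg.mar_rate
    lfq = lfq.mask(censored | dropped)

    # iBAQ: intensity over the count of observable fully-tryptic peptides
    divisors = np.array(
        [
            max(1, count_observable_peptides(r.sequence, *cfg.ibaq_peptide_window))
            for r in list(db_a) + list(db_b)
        ],
        dtype=float,
    )
    ibaq = lfq.div(divisors, axis=0)

    peptide_counts = rng.integers(2, 31, size=n)
    unique_counts = np.array([rng.integers(2, c + 1) for c in peptide_counts])
    meta = pd.DataFrame(
        {
            MAJORITY_COL: accs,
            PEPTIDES_COL: peptide_counts,
            UNIQUE_PEPTIDES_COL: unique_counts,
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        },
        index=lfq.index,
    )

    # injected rows that default filtering must remove
    extra_meta = []
    extra_idx = []
    for i, (acc, flags, peps) in enumerate(
        [
            ("REV__SA_00001", {"reverse": True}, 5),
            ("REV__SB_00001", {"reverse": True}, 4),
            ("CON__P00001", {"contaminant": True}, 7),
            ("CON__P00002", {"contaminant": True}, 3),
            ("SA_ONEPEP", {}, 1),
            ("SB_ONEPEP", {}, 1),
        ]
    ):
        row = {
            MAJORITY_COL: acc,
            PEPTIDES_COL: peps,
            UNIQUE_PEPTIDES_COL: min(peps, 1) if peps == 1 else 2,
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        }
        row.update(flags)
        extra_meta.append(row)
        extra_idx.append(n + i)
    extra_meta = pd.DataFrame(extra_meta, index=extra_idx)
    extra_lfq = pd.DataFrame(
        rng.uniform(1e6, 1e8, size=(6, len(lfq.columns))),
        index=extra_idx,
        columns=lfq.columns,
    )
    extra_ibaq = extra_lfq / 10.0

    table = ProteinGroupTable(
        meta=pd.concat([meta, extra_meta]),
        lfq=pd.concat([lfq, extra_lfq]),
        ibaq=pd.concat([ibaq, extra_ibaq]),
    )
    design = ExperimentalDesign(
        df=pd.DataFrame(
            [(lab, cond, rep) for lab, cond, rep, _ in samples],
            columns=["label", "condition", "replicate"],
        )
    )
    truth = SyntheticTruth(
        proteins=pd.DataFrame(
            {
                "accession": accs,
                "strain": strains,
                "base_log2_abundance": base_log2,
                "true_de": true_lfc != 0,
                "true_lfc": true_lfc,
            },
            index=pd.RangeIndex(n),
        ),
        samples=pd.DataFrame(sample_rows),
        censored=censored,
        dropped=dropped,
    )
    return table, design, truth


def simulate_peptides_table(
    cfg: SyntheticConfig,
    dbs: tuple[ProteomeDatabase, ProteomeDatabase],
    peptides_per_protein: int = 3,
) -> pd.DataFrame:
    """An observed-peptides table consistent with the proteomes.

    Takes the first few window-sized tryptic peptides of each protein
    and maps every distinct sequence to all proteins of the merged
    database that contain it, so cross-strain planted peptides show up
    with accessions from both strains.
    """
    merged = build_merged_database(*dbs)
    owners: dict[str, list[str]] = {}
    chosen: dict[str, None] = {}
    for rec in merged:
        peps = _tryptic_window_peptides(rec.sequence)
        for p in peps:
            owners.setdefault(p, []).append(rec.accession)
        for p in peps[:peptides_per_protein]:
            chosen.setdefault(p)
    rows = [
        {"Sequence": p, "Proteins": ";".join(owners[p])} for p in chosen
    ]
    return pd.DataFrame(rows, columns=["Sequence", "Proteins"])


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write a complete dataset directory.

    Writes strainA.fasta, strainB.fasta, merged.fasta, map.tsv,
    proteinGroups.txt, peptides.txt, design.tsv and two truth tables.
    Byte-identical output for identical config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db_a, db_b = simulate_proteomes(cfg)
    merged = build_merged_database(db_a, db_b)
    table, design, truth = simulate_quant_table(cfg, (db_a, db_b))
    peptides = simulate_peptides_table(cfg, (db_a, db_b))

    paths = {
        "fasta_a": out / "strainA.fasta",
        "fasta_b": out / "strainB.fasta",
        "merged": out / "merged.fasta",
        "strain_map": out / "map.tsv",
        "protein_groups": out / "proteinGroups.txt",
        "peptides": out / "peptides.txt",
        "design": out / "design.tsv",
        "truth_proteins": out / "truth_proteins.tsv",
        "truth_samples": out / "truth_samples.tsv",
    }
    write_fasta(db_a, paths["fasta_a"])
    write_fasta(db_b, paths["fasta_b"])
    write_fasta(merged, paths["merged"])
    write_strain_map(merged, paths["strain_map"])
    write_protein_groups(table, paths["protein_groups"])
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    write_design(design, paths["design"])
    truth.proteins.to_csv(paths["truth_proteins"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    return paths
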