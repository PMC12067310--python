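"""Differential expression with moderated t-statistics.

Reimplements the LFQ-Analyst-style workflow applied to the normalized
co-culture data: log2 transform with consistency filtering, MNAR
("Perseus-type") imputation from a left-shifted Gaussian, protein-wise
two-group linear models with empirical-Bayes variance moderation (the
limma model), Benjamini-Hochberg FDR adjustment, and significance
calling at an adjusted-p / log2-fold-change double cutoff.

The empirical-Bayes step treats the per-protein sample variances
s_g^2 (d residual degrees of freedom each) as draws from a scaled-F
prior with hyperparameters (d0, s0^2) estimated by moment matching on
log s_g^2; posterior variances are the precision-weighted compromise
s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d) and the moderated t is the
ordinary t with s~_g in place of s_g, on d0 + d degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from cocultureq.lfqratio import QuantMatrix
from cocultureq.quant_io import ExperimentalDesign

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    """Thresholds and imputation settings for the DE workflow.

    ``impute_shift`` and ``impute_width`` are in units of each sample's
    observed standard deviation: missing values are drawn from
    Normal(mean - shift*sd, (width*sd)^2). The defaults (1.8, 0.3) are
    the Perseus convention for intensity-censored missingness.
    """

    p_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    imputation: str = "perseus"  # or "none"
    impute_shift: float = 1.8
    impute_width: float = 0.3
    min_valid_per_condition: int = 2
    fdr_method: str = "benjamini-hochberg"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be positive")
        if self.imputation not in ("perseus", "none"):
            raise ValueError(f"unknown imputation {self.imputation!r}")
        if self.fdr_method != "benjamini-hochberg":
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")


@dataclass
class DEResult:
    """Per-protein contrast estimates and significance calls."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    df_prior: float = np.nan
    s2_prior: float = np.nan
    config: DEConfig | None = None

    def volcano_table(self) -> pd.DataFrame:
        t = self.table
        out = pd.DataFrame(
            {
                "accession": t["accession"],
                "log2_fc": t["log2_fc"],
                "neg_log10_p": -np.log10(t["p_value"].clip(lower=1e-300)),
                "adj_p_value": t["adj_p_value"],
                "significant": t["significant"],
                "direction": t["direction"],
            }
        )
        return out


def prepare_matrix(
    qm: QuantMatrix, design: ExperimentalDesign, cfg: DEConfig | None = None
) -> QuantMatrix:
    """Log2-transform and drop inconsistently quantified proteins.

    A protein is kept only if it has at least ``min_valid_per_condition``
    non-missing values in at least one condition — proteins quantified
    sporadically across the design carry no usable signal even after
    imputation.
    """
    cfg = cfg or DEConfig()
    if qm.value_kind == "log2":
        raise ValueError("matrix is already log2-transformed")
    design.validate_against(qm.sample_labels)
    for cond in design.conditions:
        if len(design.samples_of(cond)) < 2:
            raise ValueError(
                f"condition {cond!r} has fewer than 2 samples; variance undefined"
            )
    values = qm.values[design.labels]
    values = values.where(values > 0)  # zeros are missing, never log2(0)
    log2 = np.log2(values)
    valid_ok = pd.Series(False, index=log2.index)
    for cond in design.conditions:
        cols = design.samples_of(cond)
        valid_ok |= log2[cols].notna().sum(axis=1) >= cfg.min_valid_per_condition
    n_dropped = int((~valid_ok).sum())
    if n_dropped:
        logger.info(
            "prepare_matrix: dropped %d/%d proteins with <%d valid values "
            "in every condition",
            n_dropped, len(log2), cfg.min_valid_per_condition,
        )
    idx = valid_ok[valid_ok].index
    return QuantMatrix(
        values=log2.loc[idx],
        strain=qm.strain.loc[idx],
        accession=qm.accession.loc[idx],
        value_kind="log2",
        scale=qm.scale,
    )


def impute_perseus(
    qm: QuantMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> QuantMatrix:
    """Replace missing log2 values by left-shifted Gaussian draws.

    For each sample column with observed mean mu and SD sigma, missing
    cells become independent draws from Normal(mu - shift*sigma,
    (width*sigma)^2): plausible values just below the detection limit.
    Columns with fewer than 3 observed values fall back to the
    matrix-wide mean and SD with a warning. Deterministic for a fixed
    seed.
    """
    if qm.value_kind != "log2":
        raise ValueError("Perseus imputation operates on log2 values")
    rng = np.random.default_rng(seed)
    values = qm.values.copy()
    all_obs = values.to_numpy().ravel()
    all_obs = all_obs[np.isfinite(all_obs)]
    for col in values.columns:
        obs = values[col].dropna()
        n_missing = len(values) - len(obs)
        if n_missing == 0:
            continue
        if len(obs) >= 3:
            mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        else:
            warnings.warn(
                f"sample {col}: only {len(obs)} observed values; imputing from "
                "matrix-wide mean/SD",
                stacklevel=2,
            )
            mu, sigma = float(all_obs.mean()), float(all_obs.std(ddof=1))
        draws = rng.normal(mu - shift * sigma, width * sigma, size=n_missing)
        mask = values[col].isna()
        values.loc[mask, col] = draws
    return QuantMatrix(
        values=values,
        strain=qm.strain,
        accession=qm.accession,
        value_kind="log2",
        scale=qm.scale,
    )


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 (trigamma is strictly decreasing)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    trigamma = lambda y: special.polygamma(1, y)
    lo, hi = 1.0, 1.0
    while trigamma(lo) < x:
        lo /= 2.0
        if lo < 1e-12:
            return lo
    while trigamma(hi) > x:
        hi *= 2.0
        if hi > 1e12:
            return hi
    return brentq(lambda y: trigamma(y) - x, lo, hi, xtol=tol)


def _fit_f_dist(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the sample variances.

    Returns (df_prior, s2_prior). When the excess variance of log s2 is
    non-positive the variances are no more dispersed than pure chi^2
    noise: the prior df is +inf and every variance shrinks fully to
    s2_prior.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("zero residual variance in all proteins; degenerate input")
    z = np.log(s2[ok])
    d2 = df_residual / 2.0
    e = z - special.digamma(d2) + np.log(d2)
    emean = float(np.mean(e))
    if len(e) < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    df_prior = 2.0 * _trigamma_inverse(evar)
    s2_prior = float(
        np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    )
    return df_prior, s2_prior


def moderated_ttest(
    qm: QuantMatrix,
    design: ExperimentalDesign,
    contrast: tuple[str, str],
    prior_df: float | None = None,
) -> DEResult:
    """Two-group moderated t-test per protein.

    ``contrast = (reference, treatment)``: the reported log2 fold change
    is mean(treatment) - mean(reference). ``prior_df`` overrides the
    estimated prior degrees of freedom (0 gives the ordinary pooled
    t-test; inf shrinks every variance to the prior).
    """
    cond_ref, cond_trt = contrast
    cols_ref = design.samples_of(cond_ref)
    cols_trt = design.samples_of(cond_trt)
    if len(cols_ref) < 2 or len(cols_trt) < 2:
        raise ValueError("each contrasted condition needs >= 2 samples")
    x = qm.values[cols_ref].to_numpy(dtype=float)
    y = qm.values[cols_trt].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError(
            "missing values present; impute first or use imputation='none' "
            "only on complete data"
        )
    n1, n2 = x.shape[1], y.shape[1]
    df_res = float(n1 + n2 - 2)
    lfc = y.mean(axis=1) - x.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_res

    if prior_df is None:
        df_prior, s2_prior = _fit_f_dist(s2, df_res)
    else:
        df_prior = float(prior_df)
        # prior variance still estimated from the data unless irrelevant
        if df_prior == 0:
            s2_prior = np.nan
        else:
            _, s2_prior = _fit_f_dist(s2, df_res)

    if df_prior == 0:
        s2_post = s2
        df_total = df_res
    elif np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        df_total = np.inf
    else:
        s2_post = (df_prior * s2_prior + df_res * s2) / (df_prior + df_res)
        df_total = df_prior + df_res

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "accession": qm.accession.to_numpy(),
            "strain": qm.strain.to_numpy(),
            "log2_fc": lfc,
            "t": t,
            "df_residual": df_res,
            "df_prior": df_prior,
            "s2": s2,
            "s2_posterior": s2_post,
            "p_value": p,
        },
        index=qm.values.index,
    )
    return DEResult(table=table, contrast=contrast, df_prior=df_prior, s2_prior=s2_prior)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, where
    p_(1) <= ... <= p_(m) is the sorted input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D collection of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_deps(res: DEResult, cfg: DEConfig | None = None) -> DEResult:
    """Adjust p-values and flag differentially expressed proteins.

    Significance requires adjusted p <= p_cutoff AND |log2 FC| >=
    lfc_cutoff (both comparisons inclusive). Direction is reported
    relative to the contrast: 'up' means enriched in the treatment
    condition.
    """
    cfg = cfg or DEConfig()
    table = res.table.copy()
    table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
    sig = (table["adj_p_value"] <= cfg.p_cutoff) & (
        table["log2_fc"].abs() >= cfg.lfc_cutoff
    )
    table["significant"] = sig
    table["direction"] = np.where(
        ~sig, "ns", np.where(table["log2_fc"] > 0, "up", "down")
    )
    return DEResult(
        table=table,
        contrast=res.contrast,
        df_prior=res.df_prior,
        s2_prior=res.s2_prior,
        config=cfg,
    )


def run_de(
    qm: QuantMatrix,
    design: ExperimentalDesign,
    contrast: tuple[str, str],
    cfg: DEConfig | None = None,
) -> DEResult:
    """Full DE workflow on one (typically strain-homogeneous) matrix.

    prepare (log2 + consistency filter) -> impute -> moderated t ->
    BH adjust -> call. With ``imputation='none'`` proteins with any
    remaining missing value in the contrasted samples are dropped
    (complete-case analysis).
    """
    cfg = cfg or DEConfig()
    log2 = prepare_matrix(qm, design, cfg)
    contrast_cols = design.samples_of(contrast[0]) + design.samples_of(contrast[1])
    missing_frac = log2.values[contrast_cols].isna().mean(axis=1)
    if cfg.imputation == "perseus":
        imputed = impute_perseus(log2, cfg.impute_shift, cfg.impute_width, cfg.seed)
    else:
        complete = log2.values[contrast_cols].notna().all(axis=1)
        idx = complete[complete].index
        imputed = QuantMatrix(
            values=log2.values.loc[idx],
            strain=log2.strain.loc[idx],
            accession=log2.accession.loc[idx],
            value_kind="log2",
            scale=log2.scale,
        )
        missing_frac = missing_frac.loc[idx]
    res = moderated_ttest(imputed, design, contrast)
    res.table["imputed_fraction"] = missing_frac.to_numpy()
    return call_deps(res, cfg)
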