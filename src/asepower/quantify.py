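"""Turn two-channel allele signals into per-transcript signed ASE levels.

The ASE level of a heterozygous SNP in a sample is the difference in
allele-1 fractions between cDNA and gDNA,

    a1_cDNA/(a1_cDNA + a2_cDNA) - a1_gDNA/(a1_gDNA + a2_gDNA),

oriented by phase so that a positive value always means "haplotype 1
over-expressed" within that sample, then averaged over the heterozygous
SNPs in the transcript body. A transcript is retained only if at least
``min_informative`` of its body SNPs are heterozygous in at least one
cohort sample (default 5, with 3 as the relaxed alternative).

Before ASE levels are formed, each sample-array's fractions are normalized
for intensity-dependent dye bias: a quadratic in log10 total intensity is
fitted to that array's heterozygous gDNA fractions (whose truth is 0.5) and
subtracted from every fraction on the array, gDNA and cDNA alike.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import AlleleSignals, Cohort, PhasedGenotypes, TranscriptASE

logger = logging.getLogger(__name__)

__all__ = [
    "allele_fraction",
    "fit_dye_bias",
    "normalize_fractions",
    "snp_ase_level",
    "orient_by_phase",
    "oriented_level_matrix",
    "transcript_ase",
    "region_sd_qc",
]


def allele_fraction(a1, a2):
    """Allele-1 fraction ``a1/(a1+a2)``; NaN (missing) where the total is 0.

    Accepts scalars or arrays; zero or non-finite totals yield NaN rather
    than a fabricated balanced value.
    """
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    total = a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = a1 / total
    out = np.where(np.isfinite(total) & (total > 0), frac, np.nan)
    return out.item() if out.ndim == 0 else out


def fit_dye_bias(fracs: np.ndarray, log_totals: np.ndarray) -> np.ndarray:
    """Least-squares quadratic fit of (fraction - 0.5) on log10 total intensity.

    Returns coefficients ``(c0, c1, c2)`` of ``c0 + c1*t + c2*t**2``.
    """
    ok = np.isfinite(fracs) & np.isfinite(log_totals)
    # polyfit returns highest degree first; reverse to (c0, c1, c2)
    return np.polyfit(log_totals[ok], fracs[ok] - 0.5, 2)[::-1]


def _eval_bias(coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    c0, c1, c2 = coeffs
    return c0 + c1 * t + c2 * t * t


def normalize_fractions(
    gdna: AlleleSignals,
    cdna: AlleleSignals,
    het_mask: np.ndarray,
    min_hets: int = 30,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-sample dye-bias correction of gDNA and cDNA allele fractions.

    For each sample-array the quadratic is fitted on the heterozygous gDNA
    observations only (their true fraction is 0.5, the one internal standard
    available) and the fitted curve is subtracted from every fraction of that
    sample, with clipping to [0, 1]. Arrays with fewer than ``min_hets``
    usable heterozygous observations are passed through uncorrected with a
    logged warning.

    Returns
    -------
    (gdna_fracs, cdna_fracs, fit_table)
        Corrected fraction matrices and a per-sample table of fitted
        coefficients (NaN rows where normalization was skipped).
    """
    fg = gdna.fractions()
    fc = cdna.fractions()
    tg = np.where(np.isfinite(fg), np.log10(gdna.totals()), np.nan)
    tc = np.where(np.isfinite(fc), np.log10(cdna.totals()), np.nan)
    n_samples = fg.shape[1]
    coeffs = np.full((n_samples, 3), np.nan)
    for j in range(n_samples):
        sel = het_mask[:, j] & np.isfinite(fg[:, j]) & np.isfinite(tg[:, j])
        if sel.sum() < min_hets:
            logger.warning(
                "sample %s: only %d het gDNA observations (<%d); "
                "dye-bias normalization skipped",
                gdna.samples[j], int(sel.sum()), min_hets,
            )
            continue
        c = fit_dye_bias(fg[sel, j], tg[sel, j])
        coeffs[j] = c
        fg[:, j] = np.clip(fg[:, j] - _eval_bias(c, tg[:, j]), 0.0, 1.0)
        fc[:, j] = np.clip(fc[:, j] - _eval_bias(c, tc[:, j]), 0.0, 1.0)
    fit_table = pd.DataFrame(coeffs, index=pd.Index(gdna.samples, name="sample"),
                             columns=["c0", "c1", "c2"])
    return fg, fc, fit_table


def snp_ase_level(cdna_frac, gdna_frac):
    """Difference in allele-1 fractions, cDNA minus gDNA (in [-1, 1])."""
    return np.asarray(cdna_frac, float) - np.asarray(gdna_frac, float)


def orient_by_phase(level, allele1_on_hap1):
    """Sign ASE levels so positive means haplotype 1 over-expressed.

    The raw level measures the excess of allele 1; if allele 1 sits on
    haplotype 2, the sign is flipped. Applying the flip twice returns the
    original level.
    """
    level = np.asarray(level, float)
    out = np.where(np.asarray(allele1_on_hap1, bool), level, -level)
    return out.item() if out.ndim == 0 else out


def oriented_level_matrix(
    cohort: Cohort,
    normalize: bool = True,
    min_hets: int = 30,
) -> np.ndarray:
    """Per-SNP oriented ASE levels for every (site, sample), NaN elsewhere.

    Levels are defined only at phased heterozygous calls with usable signal
    in both channels; unphased heterozygotes are dropped (their orientation
    is unknown). Computed on the full cohort; column subsets of the result
    equal what per-subset recomputation would give, because normalization is
    strictly per sample.
    """
    geno = cohort.genotypes
    het = geno.het_mask()
    if normalize:
        fg, fc, _ = normalize_fractions(cohort.gdna, cohort.cdna, het, min_hets)
    else:
        fg, fc = cohort.gdna.fractions(), cohort.cdna.fractions()
    levels = snp_ase_level(fc, fg)
    # allele 1 (ref, code 0) on haplotype 1 <=> hap1 carries the ref allele
    oriented = orient_by_phase(levels, geno.hap1 == 0)
    usable = het & geno.phased
    return np.where(usable, oriented, np.nan)


def _aggregate(levels: np.ndarray, aggregator: str) -> np.ndarray:
    # all-NaN columns (samples without a usable body het) legitimately yield NaN
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if aggregator == "mean":
            out = np.nanmean(levels, axis=0)
        elif aggregator == "median":
            out = np.nanmedian(levels, axis=0)
        else:
            raise ValueError(f"unknown aggregator {aggregator!r}")
    return out


def transcript_ase(
    cohort: Cohort,
    min_informative: int = 5,
    aggregator: str = "mean",
    normalize: bool = True,
    sample_idx: np.ndarray | None = None,
    levels: np.ndarray | None = None,
) -> TranscriptASE:
    """Aggregate oriented SNP-level ASE into a transcripts × samples matrix.

    Informative SNP = a body SNP heterozygous in at least one (subset)
    sample; transcripts below ``min_informative`` are dropped. Per sample,
    the value is the mean (or median) of that sample's oriented heterozygous
    body-SNP levels; samples with no usable body het are NaN.

    ``levels`` may carry a precomputed :func:`oriented_level_matrix` (full
    cohort; the sample subset is applied here) to avoid recomputation when
    scanning many subsets.
    """
    if levels is None:
        levels = oriented_level_matrix(cohort, normalize=normalize)
    geno = cohort.genotypes
    if sample_idx is None:
        sample_idx = np.arange(geno.n_samples)
    sample_idx = np.asarray(sample_idx)
    het = geno.het_mask()[:, sample_idx]
    sub_levels = levels[:, sample_idx]
    samples = [geno.samples[i] for i in sample_idx]

    rows = {}
    informative = {}
    for _, tx in cohort.transcripts.iterrows():
        body = cohort.body_site_indices(tx)
        n_informative = int(het[body].any(axis=1).sum()) if body.size else 0
        if n_informative < min_informative:
            continue
        informative[tx["transcript"]] = n_informative
        rows[tx["transcript"]] = _aggregate(sub_levels[body], aggregator)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    values.index.name = "transcript"
    return TranscriptASE(
        values=values,
        informative=pd.Series(informative, dtype=int, name="informative"),
        min_informative=min_informative,
    )


def region_sd_qc(
    cohort: Cohort,
    normalize: bool = True,
    levels: np.ndarray | None = None,
    min_informative: int = 5,
    flag_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(sample, transcript) SD of SNP-level ASE across the body, with flags.

    A cell's SD needs at least two heterozygous body SNPs (otherwise NaN).
    A transcript is flagged when more than ``flag_fraction`` of the samples
    with a defined SD have SD exceeding the absolute transcript ASE level
    of that sample — regions where noise dominates the signal.

    Returns ``(cell_sd, summary)``: the SD matrix and a per-transcript table
    with the exceeding fraction and flag.
    """
    if levels is None:
        levels = oriented_level_matrix(cohort, normalize=normalize)
    tase = transcript_ase(cohort, min_informative=min_informative,
                          normalize=normalize, levels=levels)
    sd_rows = {}
    summary_rows = []
    tx_table = cohort.transcripts.set_index("transcript")
    for tx_id in tase.values.index:
        body = cohort.body_site_indices(tx_table.loc[tx_id])
        block = levels[body]
        counts = np.isfinite(block).sum(axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(block, axis=0, ddof=1)
        sd = np.where(counts >= 2, sd, np.nan)
        sd_rows[tx_id] = sd
        mean_abs = np.abs(tase.values.loc[tx_id].to_numpy())
        defined = np.isfinite(sd) & np.isfinite(mean_abs)
        n_def = int(defined.sum())
        exceeding = int((sd[defined] > mean_abs[defined]).sum())
        frac = exceeding / n_def if n_def else np.nan
        summary_rows.append(
            {
                "transcript": tx_id,
                "n_samples_with_sd": n_def,
                "n_exceeding": exceeding,
                "frac_exceeding": frac,
                "flagged": bool(n_def and frac > flag_fraction),
            }
        )
    cell_sd = pd.DataFrame.from_dict(
        sd_rows, orient="index", columns=tase.values.columns
    )
    cell_sd.index.name = "transcript"
    summary = pd.DataFrame(summary_rows).set_index("transcript")
    return cell_sd, summary
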