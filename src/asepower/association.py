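"""Phase-aware ASE and covariate-adjusted GTE association scans over cis windows.

Both scans are ordinary least squares with a two-sided t-test on the SNP
term, run for every genotyped SNP inside a transcript's cis window
(transcript body plus ``flank`` bases on each side, 100 kb by default,
500 kb as the wide variant).

ASE scan: the response is the transcript's oriented ASE level; the SNP is
coded +1 for heterozygotes carrying the minor allele on haplotype 1, -1 for
heterozygotes carrying it on haplotype 2, and 0 for homozygotes (the
baseline group). Tests with any non-empty genotype group smaller than
``min_group`` (default 4) are skipped — small groups inflate the null.

GTE scan: the response is total expression; the SNP enters as minor-allele
dosage 0/1/2 with age and sex as covariates; groups below ``min_group``
(default 3) skip the test.

The hot path is a hand-vectorized closed-form OLS (batched normal
equations) because a scan evaluates tens of thousands of SNP-transcript
pairs; tests check it against a general-purpose OLS implementation.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, Cohort, TranscriptASE
from .quantify import oriented_level_matrix, transcript_ase

logger = logging.getLogger(__name__)

__all__ = [
    "CisWindow",
    "cis_window",
    "select_test_snps",
    "ase_groups",
    "ase_association",
    "gte_association",
    "run_scan",
]

RECORD_COLUMNS = [
    "snp", "chrom", "pos", "transcript", "method",
    "n_group1", "n_group2", "n_group3",
    "slope", "se", "p", "dist_tss", "dist_tts", "maf", "degenerate",
]


@dataclasses.dataclass(frozen=True)
class CisWindow:
    """Closed genomic interval scanned around one transcript."""

    transcript: str
    chrom: str
    lo: int
    hi: int
    flank: int


def cis_window(transcript_row: pd.Series, flank: int = 100_000) -> CisWindow:
    """Window = [start - flank, end + flank], clipped at the chromosome start."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start, end = int(transcript_row["start"]), int(transcript_row["end"])
    if start > end:
        raise ValueError("transcript start exceeds end")
    return CisWindow(
        transcript=str(transcript_row["transcript"]),
        chrom=str(transcript_row["chrom"]),
        lo=max(start - flank, 0),
        hi=end + flank,
        flank=flank,
    )


def select_test_snps(sites: pd.DataFrame, window: CisWindow) -> np.ndarray:
    """Indices of genotyped SNPs inside the closed window interval."""
    mask = (
        (sites["chrom"].to_numpy() == window.chrom)
        & (sites["pos"].to_numpy() >= window.lo)
        & (sites["pos"].to_numpy() <= window.hi)
    )
    return np.flatnonzero(mask)


def ase_groups(
    hap1: np.ndarray,
    hap2: np.ndarray,
    phased: np.ndarray,
    minor_is_alt,
) -> np.ndarray:
    """Code samples at a test SNP as +1 / 0 / -1 for the phase-grouped regression.

    +1: heterozygote with the minor allele on haplotype 1; -1: minor allele
    on haplotype 2; 0: homozygote (either). Missing calls and unphased
    heterozygotes are NaN (excluded from the test). Accepts a single site
    (1-D arrays) or a site × sample block (2-D with broadcastable
    ``minor_is_alt``).
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    minor_code = np.where(np.asarray(minor_is_alt), 1, 0)
    if hap1.ndim == 2:
        minor_code = np.asarray(minor_code).reshape(-1, 1)
    het = hap1 != hap2
    x = np.where(hap1 == minor_code, 1.0, -1.0)
    x = np.where(het, x, 0.0)
    x = np.where(hap1 == MISSING, np.nan, x)
    x = np.where(het & ~np.asarray(phased, bool), np.nan, x)
    return x


# ---------------------------------------------------------------------------
# closed-form OLS kernels
# ---------------------------------------------------------------------------

def _origin_ols_batch(y: np.ndarray, X: np.ndarray, valid: np.ndarray):
    """Slope, SE and two-sided p of y ~ x (through the origin) per row of X.

    ``y`` is (n,); ``X`` and ``valid`` are (S, n). Invalid entries are
    excluded per row. The origin model is what makes the phase-grouped test
    exactly invariant to per-sample haplotype relabeling (which negates a
    sample's response and coding together): slope, SSE and hence p depend
    only on the relabel-invariant products x*y, x*x, y*y. Homozygotes pin
    the zero baseline. Returns arrays of shape (S,) plus the used-n vector.
    """
    w = valid.astype(float)
    x0 = np.where(valid, X, 0.0)
    y0 = np.where(valid, y[None, :], 0.0)
    n = w.sum(axis=1)
    sxx = (x0 * x0).sum(axis=1)
    sxy = (x0 * y0).sum(axis=1)
    syy = (y0 * y0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        sse = np.maximum(syy - slope * sxy, 0.0)
        df = n - 1
        sigma2 = sse / np.maximum(df, 1)
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isfinite(t), p, np.nan)
        p = np.where(np.isinf(t), 0.0, p)  # exact fit: se == 0, slope != 0
    bad = (df < 1) | (sxx <= 0)
    slope = np.where(sxx > 0, slope, np.nan)
    se = np.where(bad, np.nan, se)
    p = np.where(bad, np.nan, p)
    return slope, se, p, n


def _multi_ols_batch(y: np.ndarray, D: np.ndarray, C: np.ndarray, valid: np.ndarray):
    """OLS of y on [C, d] per row d of D; t-test on the d coefficient.

    ``C`` (n, k) holds the shared covariate columns (including the
    intercept); ``D``/``valid`` are (S, n). Uses batched normal equations
    solved with a pseudoinverse (matching the conventional OLS treatment of
    rank-deficient designs).
    """
    w = valid.astype(float)
    d0 = np.where(valid, D, 0.0)
    y0 = np.where(valid, y[None, :], 0.0)
    k = C.shape[1]
    ctc = np.einsum("sn,nk,nl->skl", w, C, C)
    ctd = np.einsum("sn,nk->sk", w * d0, C)
    cty = np.einsum("sn,nk->sk", w * y0, C)
    dtd = (w * d0 * d0).sum(axis=1)
    dty = (w * d0 * y0).sum(axis=1)
    yty = (w * y0 * y0).sum(axis=1)
    S = D.shape[0]
    M = np.empty((S, k + 1, k + 1))
    M[:, :k, :k] = ctc
    M[:, :k, k] = ctd
    M[:, k, :k] = ctd
    M[:, k, k] = dtd
    rhs = np.concatenate([cty, dty[:, None]], axis=1)
    Minv = np.linalg.pinv(M, hermitian=True)
    beta = np.einsum("sij,sj->si", Minv, rhs)
    n = w.sum(axis=1)
    df = n - (k + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sse = np.maximum(yty - (beta * rhs).sum(axis=1), 0.0)
        sigma2 = sse / np.maximum(df, 1)
        se = np.sqrt(sigma2 * Minv[:, k, k])
        slope = beta[:, k]
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isfinite(t), p, np.nan)
        p = np.where(np.isinf(t), 0.0, p)
    bad = df < 1
    se = np.where(bad, np.nan, se)
    p = np.where(bad, np.nan, p)
    return slope, se, p, n


def _group_counts(x: np.ndarray, valid: np.ndarray, levels) -> np.ndarray:
    """Counts of each coding level per row, over valid entries: (S, len(levels))."""
    return np.stack(
        [((x == lv) & valid).sum(axis=1) for lv in levels], axis=1
    )


def _group_filter(counts: np.ndarray, min_group: int, require_all: bool) -> np.ndarray:
    nonempty = counts > 0
    ok_sizes = (counts >= min_group) | ~nonempty
    keep = ok_sizes.all(axis=1) & (nonempty.sum(axis=1) >= 2)
    if require_all:
        keep &= nonempty.all(axis=1)
    return keep


# ---------------------------------------------------------------------------
# single-test entry points
# ---------------------------------------------------------------------------

def ase_association(
    ase_values: np.ndarray,
    x: np.ndarray,
    min_group: int = 4,
    require_all_groups: bool = False,
) -> dict | None:
    """One phase-grouped ASE test: OLS of oriented ASE on the +1/0/-1 coding.

    Samples with missing ASE or coding are removed first. The regression
    runs through the origin: the homozygote group fixes the zero baseline and
    the test is exactly invariant to per-sample haplotype relabeling.
    Returns ``None`` when the group-size filter skips the test; otherwise a
    record dict with
    ``slope, se, p, n_group1/2/3`` (+1, 0, -1 counts) and a ``degenerate``
    flag (True with ``p`` NaN when the response has no variance).
    """
    y = np.asarray(ase_values, float)
    x = np.asarray(x, float)
    valid = (np.isfinite(y) & np.isfinite(x))[None, :]
    counts = _group_counts(x[None, :], valid, (1.0, 0.0, -1.0))
    if not _group_filter(counts, min_group, require_all_groups)[0]:
        return None
    slope, se, p, n = _origin_ols_batch(y, x[None, :], valid)
    return {
        "method": "ASE",
        "slope": slope[0], "se": se[0], "p": p[0], "n": int(n[0]),
        "n_group1": int(counts[0, 0]),
        "n_group2": int(counts[0, 1]),
        "n_group3": int(counts[0, 2]),
        "degenerate": bool(not np.isfinite(p[0])),
    }


def gte_association(
    expression: np.ndarray,
    dosage: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    min_group: int = 3,
) -> dict | None:
    """One GTE test: OLS of expression on dosage with age and sex covariates.

    Complete cases only; genotype classes {0, 1, 2} below ``min_group``
    skip the test. A covariate constant over the analyzed samples (e.g. sex
    in a single-sex subset) is dropped with a logged warning.
    """
    y = np.asarray(expression, float)
    d = np.asarray(dosage, float)
    age = np.asarray(age, float)
    sex = np.asarray(sex, float)
    valid = (np.isfinite(y) & np.isfinite(d) & np.isfinite(age) & np.isfinite(sex))
    counts = _group_counts(d[None, :], valid[None, :], (0.0, 1.0, 2.0))
    if not _group_filter(counts, min_group, False)[0]:
        return None
    cols = [np.ones_like(y)]
    for name, c in (("age", age), ("sex", sex)):
        if np.nanstd(np.where(valid, c, np.nan)) == 0:
            logger.warning("covariate %r constant over analyzed samples; dropped", name)
        else:
            cols.append(c)
    C = np.column_stack(cols)
    slope, se, p, n = _multi_ols_batch(y, d[None, :], C, valid[None, :])
    return {
        "method": "GTE",
        "slope": slope[0], "se": se[0], "p": p[0], "n": int(n[0]),
        "n_group1": int(counts[0, 0]),
        "n_group2": int(counts[0, 1]),
        "n_group3": int(counts[0, 2]),
        "degenerate": bool(not np.isfinite(p[0])),
    }


# ---------------------------------------------------------------------------
# full scans
# ---------------------------------------------------------------------------

def _distances(pos: np.ndarray, tx: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Signed, strand-oriented distances to TSS and TTS (upstream negative)."""
    start, end = int(tx["start"]), int(tx["end"])
    if tx["strand"] == "+":
        tss, tts = start, end - 1
        return pos - tss, pos - tts
    tss, tts = end - 1, start
    return tss - pos, tts - pos


def run_scan(
    cohort: Cohort,
    method: str,
    *,
    flank: int = 100_000,
    sample_idx: np.ndarray | None = None,
    genotype_order: np.ndarray | None = None,
    min_group: int | None = None,
    min_informative: int = 5,
    aggregator: str = "mean",
    normalize: bool = True,
    require_all_groups: bool = False,
    ase: TranscriptASE | None = None,
    levels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every (SNP, transcript) pair in cis and return the record table.

    Parameters
    ----------
    method
        ``"ase"`` or ``"gte"``.
    sample_idx
        Positional sample subset (down-sampling); default all samples.
    genotype_order
        Optional permutation of the (subset) samples applied to the genotype
        side only — the permutation-null device: phenotypes keep their
        owners, genotypes are relinked.
    min_group
        Group-size filter; defaults to 4 for ASE and 3 for GTE.
    ase, levels
        Precomputed transcript ASE matrix / oriented SNP-level matrix to
        reuse across permutations or subsets.

    Returns a DataFrame with one row per test passing the group filter,
    ordered by (transcript, position); ``maf`` is the empirical subset
    minor-allele frequency of the test SNP.
    """
    method = method.lower()
    if method not in ("ase", "gte"):
        raise ValueError(f"method must be 'ase' or 'gte', got {method!r}")
    if min_group is None:
        min_group = 4 if method == "ase" else 3
    geno = cohort.genotypes
    if sample_idx is None:
        sample_idx = np.arange(geno.n_samples)
    sample_idx = np.asarray(sample_idx)
    n = sample_idx.size

    # genotype-side arrays (optionally permuted relative to phenotypes)
    geno_cols = sample_idx if genotype_order is None else sample_idx[np.asarray(genotype_order)]
    hap1 = geno.hap1[:, geno_cols]
    hap2 = geno.hap2[:, geno_cols]
    phased = geno.phased[:, geno_cols]
    alt_freq_all = geno.alt_frequency(geno_cols)
    minor_is_alt_all = alt_freq_all <= 0.5
    maf_all = np.minimum(alt_freq_all, 1 - alt_freq_all)

    if method == "ase":
        if ase is None:
            ase = transcript_ase(
                cohort, min_informative=min_informative, aggregator=aggregator,
                normalize=normalize, sample_idx=sample_idx, levels=levels,
            )
        pheno = ase.values
        pheno_cols = {s: i for i, s in enumerate(pheno.columns)}
        sample_names = [geno.samples[i] for i in sample_idx]
        col_order = [pheno_cols[s] for s in sample_names]
    else:
        samples = [geno.samples[i] for i in sample_idx]
        expr = cohort.expression[samples]
        cov = cohort.covariates.loc[samples]
        age = cov["age"].to_numpy(float)
        sex = cov["sex"].to_numpy(float)
        cov_cols = [np.ones(n)]
        for name, c in (("age", age), ("sex", sex)):
            if np.std(c) == 0:
                logger.warning("covariate %r constant over subset; dropped", name)
            else:
                cov_cols.append(c)
        C = np.column_stack(cov_cols)

    sites = geno.sites
    records: list[pd.DataFrame] = []
    for _, tx in cohort.transcripts.iterrows():
        window = cis_window(tx, flank)
        site_idx = select_test_snps(sites, window)
        if site_idx.size == 0:
            continue
        if method == "ase":
            tx_id = tx["transcript"]
            if tx_id not in pheno.index:
                continue
            y = pheno.loc[tx_id].to_numpy(float)[col_order]
            x = ase_groups(
                hap1[site_idx], hap2[site_idx], phased[site_idx],
                minor_is_alt_all[site_idx],
            )
            valid = np.isfinite(y)[None, :] & np.isfinite(x)
            counts = _group_counts(x, valid, (1.0, 0.0, -1.0))
            keep = _group_filter(counts, min_group, require_all_groups)
            if not keep.any():
                continue
            x, valid, counts = x[keep], valid[keep], counts[keep]
            slope, se, p, _ = _origin_ols_batch(y, x, valid)
        else:
            tx_id = tx["transcript"]
            y = expr.loc[tx_id].to_numpy(float)
            g = (hap1[site_idx] + hap2[site_idx]).astype(float)
            g[hap1[site_idx] == MISSING] = np.nan
            # minor-allele dosage: flip where the ref allele is minor
            flip = ~minor_is_alt_all[site_idx]
            d = np.where(flip[:, None], 2.0 - g, g)
            valid = np.isfinite(y)[None, :] & np.isfinite(d)
            counts = _group_counts(d, valid, (0.0, 1.0, 2.0))
            keep = _group_filter(counts, min_group, False)
            if not keep.any():
                continue
            d, valid, counts = d[keep], valid[keep], counts[keep]
            slope, se, p, _ = _multi_ols_batch(y, d, C, valid)

        kept_sites = site_idx[keep]
        pos = sites["pos"].to_numpy()[kept_sites]
        dist_tss, dist_tts = _distances(pos, tx)
        records.append(pd.DataFrame({
            "snp": sites["snp"].to_numpy()[kept_sites],
            "chrom": sites["chrom"].to_numpy()[kept_sites],
            "pos": pos,
            "transcript": tx_id,
            "method": method.upper(),
            "n_group1": counts[:, 0],
            "n_group2": counts[:, 1],
            "n_group3": counts[:, 2],
            "slope": slope,
            "se": se,
            "p": p,
            "dist_tss": dist_tss,
            "dist_tts": dist_tts,
            "maf": maf_all[kept_sites],
            "degenerate": ~np.isfinite(p),
        }))

    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    out = out.sort_values(["transcript", "pos"], kind="stable", ignore_index=True)
    logger.info("%s scan: %d tests retained (flank=%d, n=%d)",
                method.upper(), len(out), flank, n)
    return out
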