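"""Power-comparison instruments: significance counting under down-sampling,
top-list overlap, MAF-binned detection curves and positional enrichment.

The three counting panels per (method, sample size, threshold) are: total
significant SNP-transcript associations; unique significant SNPs (keeping
only each SNP's strongest association); and transcripts with at least one
significant SNP. Their ratio between the ASE and GTE scans is the headline
power comparison. Down-sampled rows are medians over repeated random
subsets drawn without replacement.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .association import run_scan
from .containers import Cohort
from .correction import add_corrections
from .quantify import oriented_level_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "THRESHOLD_TYPES",
    "PowerSummary",
    "OverlapResult",
    "count_significant",
    "downsample_counts",
    "compare_power",
    "ase_gte_ratio",
    "toplist_overlap",
    "maf_power_curve",
    "positional_enrichment",
]

#: supported threshold types -> (column, cutoff)
THRESHOLD_TYPES = {
    "fdr_0.05": ("p_fdr", 0.05),
    "fdr_0.01": ("p_fdr", 0.01),
    "bonferroni_0.05": ("p_bonf", 0.05),
    "bonferroni_0.01": ("p_bonf", 0.01),
}

PANELS = ("associations", "snps", "transcripts")


@dataclasses.dataclass
class PowerSummary:
    """Tidy counting table: one row per (method, n, threshold, panel)."""

    table: pd.DataFrame

    def count(self, method: str, n: int, threshold: str, panel: str) -> float:
        t = self.table
        row = t[
            (t["method"] == method.upper())
            & (t["n"] == n)
            & (t["threshold"] == threshold)
            & (t["panel"] == panel)
        ]
        return float(row["count"].iloc[0]) if len(row) else float("nan")

    def ratio(self, n: int, threshold: str, panel: str) -> float:
        return ase_gte_ratio(
            self.count("ASE", n, threshold, panel),
            self.count("GTE", n, threshold, panel),
        )


@dataclasses.dataclass
class OverlapResult:
    """Top-list overlap between the two methods."""

    n_eligible: int
    k_gte: int
    k_ase: int
    n_overlap: int

    @property
    def overlap_percent(self) -> float:
        """|intersection| / k_gte x 100."""
        return 100.0 * self.n_overlap / self.k_gte if self.k_gte else float("nan")


def _best_per_snp(records: pd.DataFrame) -> pd.DataFrame:
    """Each SNP's minimum-p record; p-ties broken by smallest transcript id."""
    ordered = records.sort_values(
        ["snp", "p", "transcript"], kind="stable"
    )
    return ordered.drop_duplicates("snp", keep="first")


def count_significant(
    records: pd.DataFrame, threshold: str
) -> tuple[int, int, int]:
    """Counts of (associations, unique SNPs, transcripts) passing a threshold.

    ``records`` must carry the corrected columns from
    :func:`asepower.correction.add_corrections`.
    """
    if threshold not in THRESHOLD_TYPES:
        raise ValueError(
            f"unknown threshold type {threshold!r}; expected one of {sorted(THRESHOLD_TYPES)}"
        )
    col, cut = THRESHOLD_TYPES[threshold]
    if col not in records.columns:
        raise ValueError(f"records lack corrected column {col!r}; run add_corrections first")
    sig = records[records[col] <= cut]
    n_assoc = len(sig)
    best = _best_per_snp(records)
    n_snps = int((best[col] <= cut).sum())
    n_tx = sig["transcript"].nunique()
    return n_assoc, n_snps, n_tx


def _counts_all_thresholds(records: pd.DataFrame) -> dict[tuple[str, str], int]:
    out = {}
    for thr in THRESHOLD_TYPES:
        a, s, t = count_significant(records, thr)
        out[(thr, "associations")] = a
        out[(thr, "snps")] = s
        out[(thr, "transcripts")] = t
    return out


def downsample_counts(
    cohort: Cohort,
    method: str,
    n: int,
    n_runs: int = 10,
    seed: int = 0,
    *,
    flank: int = 100_000,
    levels: np.ndarray | None = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """Median significance counts over random subsets of size ``n``.

    Subsets are drawn without replacement and the full scan (including the
    informative-SNP filter and empirical MAFs) is re-run per subset; the
    post-filter test count of each run is its own correction denominator.
    ``n == cohort size`` degenerates to a single full-cohort run.
    Returns a tidy frame (method, n, threshold, panel, count).
    """
    N = cohort.n_samples
    if n > N:
        raise ValueError(f"subset size {n} exceeds cohort size {N}")
    rng = np.random.default_rng(seed)
    if n == N:
        runs = [np.arange(N)]
    else:
        runs = [rng.choice(N, n, replace=False) for _ in range(n_runs)]
    per_run: list[dict] = []
    for idx in runs:
        rec = run_scan(cohort, method, flank=flank, sample_idx=idx,
                       levels=levels, **scan_kwargs)
        rec = add_corrections(rec)
        per_run.append(_counts_all_thresholds(rec))
    rows = []
    for thr in THRESHOLD_TYPES:
        for panel in PANELS:
            vals = [r[(thr, panel)] for r in per_run]
            rows.append({
                "method": method.upper(), "n": n, "threshold": thr,
                "panel": panel, "count": float(np.median(vals)),
            })
    return pd.DataFrame(rows)


def compare_power(
    cohort: Cohort,
    sample_sizes: tuple[int, ...] = (50, 95, 188),
    n_runs: int = 10,
    seed: int = 0,
    *,
    flank: int = 100_000,
    **scan_kwargs,
) -> PowerSummary:
    """Counting table for both methods across sample sizes, with ratios.

    The oriented SNP-level ASE matrix is computed once (normalization is
    per-sample, so subsetting commutes with it) and reused across subsets.
    """
    levels = oriented_level_matrix(
        cohort, normalize=scan_kwargs.get("normalize", True)
    )
    parts = []
    for i, n in enumerate(sample_sizes):
        for j, method in enumerate(("ase", "gte")):
            lv = levels if method == "ase" else None
            parts.append(
                downsample_counts(
                    cohort, method, n, n_runs=n_runs,
                    seed=seed + 1000 * i + 100 * j, flank=flank,
                    levels=lv, **scan_kwargs,
                )
            )
    table = pd.concat(parts, ignore_index=True)
    return PowerSummary(table=table)


def ase_gte_ratio(ase_count: float, gte_count: float) -> float:
    """Ratio of ASE to GTE significance counts (inf when GTE finds none)."""
    if gte_count == 0:
        return float("inf") if ase_count > 0 else float("nan")
    return ase_count / gte_count


def toplist_overlap(
    ase_records: pd.DataFrame,
    gte_records: pd.DataFrame,
    k_ase: int,
    k_gte: int,
) -> OverlapResult:
    """Overlap between the two methods' top SNP lists.

    Eligibility is restricted to SNPs tested by both methods; within the
    eligible set each SNP is ranked by its best (minimum) p per method and
    the top ``k`` SNPs per method are intersected. The overlap percentage
    uses the GTE list size as denominator. Requested sizes exceeding the
    eligible set are capped with a warning.
    """
    eligible = np.intersect1d(
        ase_records["snp"].unique(), gte_records["snp"].unique()
    )
    n_eligible = eligible.size
    if min(k_ase, k_gte) < 1:
        raise ValueError("top-list sizes must be positive")
    if max(k_ase, k_gte) > n_eligible:
        logger.warning(
            "top-list size exceeds the %d eligible SNPs; capping", n_eligible
        )
        k_ase = min(k_ase, n_eligible)
        k_gte = min(k_gte, n_eligible)
    tops = {}
    for name, rec, k in (("ase", ase_records, k_ase), ("gte", gte_records, k_gte)):
        best = _best_per_snp(rec[rec["snp"].isin(eligible)])
        best = best.sort_values(["p", "snp"], kind="stable")
        tops[name] = set(best["snp"].head(k))
    n_overlap = len(tops["ase"] & tops["gte"])
    return OverlapResult(
        n_eligible=n_eligible, k_gte=k_gte, k_ase=k_ase, n_overlap=n_overlap
    )


def maf_power_curve(
    records: pd.DataFrame,
    threshold: str = "bonferroni_0.05",
    window: int = 5,
) -> pd.DataFrame:
    """Fraction of significant SNPs per 1% MAF bin, with a sliding average.

    Bin ``b`` covers MAF in ``[b/100, (b+1)/100)`` for b = 0..49; MAF
    exactly 0.5 falls in the last bin. SNP-level: each SNP counts once with
    its best association. Empty bins have NaN fraction and are skipped by
    the centered ``window``-bin moving average (truncated at the edges).
    """
    col, cut = THRESHOLD_TYPES[threshold]
    best = _best_per_snp(records)
    maf = best["maf"].to_numpy(float)
    sig = (best[col] <= cut).to_numpy()
    bins = np.minimum((maf * 100).astype(int), 49)
    tested = np.bincount(bins, minlength=50)
    significant = np.bincount(bins, weights=sig.astype(float), minlength=50).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tested > 0, significant / np.maximum(tested, 1), np.nan)
    smooth = np.full(50, np.nan)
    half = window // 2
    for b in range(50):
        seg = frac[max(0, b - half): b + half + 1]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            smooth[b] = seg.mean()
    return pd.DataFrame({
        "maf_bin": np.arange(50),
        "maf_lo": np.arange(50) / 100.0,
        "maf_hi": np.arange(1, 51) / 100.0,
        "tested": tested,
        "significant": significant,
        "fraction": frac,
        "sliding_fraction": smooth,
    })


def positional_enrichment(
    records: pd.DataFrame,
    threshold: str = "bonferroni_0.05",
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Tested/significant counts per 1 kb bin of distance to TSS and TTS.

    Distances are the strand-oriented signed values carried by the records
    (upstream negative). Returns a tidy frame with ``anchor`` in
    {"tss", "tts"}, the bin index (floor of distance / bin size), counts
    and the significant fraction.
    """
    col, cut = THRESHOLD_TYPES[threshold]
    sig = (records[col] <= cut).to_numpy()
    parts = []
    for anchor, column in (("tss", "dist_tss"), ("tts", "dist_tts")):
        d = records[column].to_numpy(float)
        bins = np.floor(d / bin_size).astype(int)
        grouped = pd.DataFrame({"bin": bins, "sig": sig}).groupby("bin")["sig"]
        tab = grouped.agg(tested="size", significant="sum").reset_index()
        tab["significant"] = tab["significant"].astype(int)
        tab["fraction"] = tab["significant"] / tab["tested"]
        tab.insert(0, "anchor", anchor)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)
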