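"""Readers and writers for the standard on-disk formats, plus genotype QC.

Formats: phased VCF 4.2 (``|`` separated GT, per-site ``MAF`` INFO field),
BED6 transcript models (0-based half-open, strand in column 6), and TSV
matrices (two columns per sample for the two allele channels; ``#``-prefixed
provenance header lines). VCF positions are 1-based on disk and converted
to the package's 0-based convention on read/write. Floats are written at 12
significant digits so write-then-read round-trips to working precision.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import MISSING, AlleleSignals, PhasedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_phased_vcf",
    "write_bed",
    "read_bed",
    "write_signals",
    "read_signals",
    "write_matrix",
    "read_matrix",
    "write_covariates",
    "read_covariates",
    "genotype_concordance",
]

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: PhasedGenotypes, path: str | Path) -> None:
    """Write phased genotypes as an uncompressed VCF 4.2 file.

    Positions are converted to 1-based; calls use ``|`` when phased, ``/``
    otherwise, and ``./.`` for missing. The empirical minor-allele frequency
    is stored in the ``MAF`` INFO field.
    """
    path = Path(path)
    maf = genotypes.minor_allele_freq()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,'
                 'Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        sites = genotypes.sites
        for i in range(genotypes.n_sites):
            row = sites.iloc[i]
            calls = []
            for j in range(genotypes.n_samples):
                a, b = genotypes.hap1[i, j], genotypes.hap2[i, j]
                if a == MISSING:
                    calls.append("./.")
                else:
                    sep = "|" if genotypes.phased[i, j] else "/"
                    calls.append(f"{a}{sep}{b}")
            maf_txt = "." if not np.isfinite(maf[i]) else f"{maf[i]:.6g}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['snp']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\tMAF={maf_txt}\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a VCF into a :class:`PhasedGenotypes` (biallelic SNPs only).

    Multi-allelic sites are skipped with a warning; ``./.`` calls become
    missing; ``0/1`` heterozygotes are kept but flagged unphased.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows, h1, h2, ph = [], [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"skipping non-biallelic site {rec.chrom}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            a1 = np.empty(len(samples), np.int8)
            a2 = np.empty(len(samples), np.int8)
            p = np.zeros(len(samples), bool)
            for j, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call["GT"]
                if alleles is None or None in alleles:
                    a1[j] = a2[j] = MISSING
                else:
                    a1[j], a2[j] = alleles
                    p[j] = call.phased
            rows.append({
                "snp": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos - 1,  # to 0-based
                "ref": rec.ref,
                "alt": rec.alts[0],
            })
            h1.append(a1)
            h2.append(a2)
            ph.append(p)
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    return PhasedGenotypes(
        sites=pd.DataFrame(rows),
        samples=samples,
        hap1=np.vstack(h1),
        hap2=np.vstack(h2),
        phased=np.vstack(ph),
    )


# ---------------------------------------------------------------------------
# BED transcripts
# ---------------------------------------------------------------------------

def write_bed(transcripts: pd.DataFrame, path: str | Path) -> None:
    """Write the transcript table as BED6 (0-based half-open)."""
    out = pd.DataFrame({
        "chrom": transcripts["chrom"],
        "start": transcripts["start"],
        "end": transcripts["end"],
        "name": transcripts["transcript"],
        "score": 0,
        "strand": transcripts["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file into the internal transcript table layout."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        comment="#",
    )
    return pd.DataFrame({
        "transcript": bed["name"].astype(str),
        "chrom": bed["chrom"].astype(str),
        "start": bed["start"].astype(int),
        "end": bed["end"].astype(int),
        "strand": bed["strand"].astype(str),
    })


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None) -> None:
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def write_signals(signals: AlleleSignals, path: str | Path,
                  provenance: dict | None = None) -> None:
    """Two-channel signal matrix as TSV: rows = SNPs, two columns per sample."""
    cols = {}
    for j, s in enumerate(signals.samples):
        cols[f"{s}.A1"] = signals.a1[:, j]
        cols[f"{s}.A2"] = signals.a2[:, j]
    df = pd.DataFrame(cols, index=pd.Index(signals.snps, name="snp"))
    _write_tsv(df, path, provenance)


def read_signals(path: str | Path) -> AlleleSignals:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    samples = []
    for c in df.columns:
        if c.endswith(".A1"):
            samples.append(c[:-3])
    a1 = np.column_stack([df[f"{s}.A1"].to_numpy(float) for s in samples])
    a2 = np.column_stack([df[f"{s}.A2"].to_numpy(float) for s in samples])
    return AlleleSignals(snps=pd.Index(df.index.astype(str)), samples=samples,
                         a1=a1, a2=a2)


def write_matrix(df: pd.DataFrame, path: str | Path,
                 provenance: dict | None = None) -> None:
    """Generic feature × sample matrix (expression, transcript ASE, ...)."""
    _write_tsv(df, path, provenance)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ---------------------------------------------------------------------------
# cross-platform genotype QC
# ---------------------------------------------------------------------------

def genotype_concordance(
    a: PhasedGenotypes, b: PhasedGenotypes
) -> tuple[float, float]:
    """Concordance between two genotype call sets (e.g. two array platforms).

    Shared samples and SNPs are intersected first; only calls present
    (non-missing) in both sets enter the denominator. Returns the per-call
    discordance rate and the fraction of SNPs with at least one discordant
    call.
    """
    snps = np.intersect1d(a.sites["snp"].to_numpy(), b.sites["snp"].to_numpy())
    samples = sorted(set(a.samples) & set(b.samples))
    if snps.size == 0 or len(samples) == 0:
        raise ValueError("no shared SNPs/samples between the two call sets")
    ia = pd.Index(a.sites["snp"]).get_indexer(snps)
    ib = pd.Index(b.sites["snp"]).get_indexer(snps)
    ja = [a.samples.index(s) for s in samples]
    jb = [b.samples.index(s) for s in samples]
    ga = a.genotypes()[np.ix_(ia, ja)]
    gb = b.genotypes()[np.ix_(ib, jb)]
    both = (ga != MISSING) & (gb != MISSING)
    n_calls = int(both.sum())
    if n_calls == 0:
        raise ValueError("no overlapping non-missing calls")
    disc = (ga != gb) & both
    per_call = disc.sum() / n_calls
    per_snp = (disc.any(axis=1)).mean()
    return float(per_call), float(per_snp)
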