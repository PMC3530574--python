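"""Core in-memory containers shared across the package.

Coordinate conventions: all positions are 0-based internally; transcript
intervals are half-open ``[start, end)`` as in BED. VCF input/output converts
to/from 1-based positions at the file boundary.

Allele coding: ``0`` is the reference (channel "allele 1") and ``1`` the
alternate allele. Missing genotype calls carry :data:`MISSING` in both
haplotype arrays.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing allele call in haplotype arrays
MISSING = -1

SITE_COLUMNS = ["snp", "chrom", "pos", "ref", "alt"]
TRANSCRIPT_COLUMNS = ["transcript", "chrom", "start", "end", "strand"]


@dataclasses.dataclass
class PhasedGenotypes:
    """Phased genotype calls for a cohort.

    Parameters
    ----------
    sites
        One row per variant with columns ``snp, chrom, pos, ref, alt``
        (0-based positions, sorted by chromosome then position).
    samples
        Sample identifiers, one per matrix column.
    hap1, hap2
        ``(n_sites, n_samples)`` int8 allele codes (0=ref, 1=alt,
        :data:`MISSING` for no-calls). The genotype is the allele sum.
    phased
        Boolean per-call flag; an unphased heterozygote has an arbitrary
        haplotype assignment and is excluded from phase-dependent analyses.
    """

    sites: pd.DataFrame
    samples: list[str]
    hap1: np.ndarray
    hap2: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"sites table lacks columns {missing}")
        shape = (len(self.sites), len(self.samples))
        for name in ("hap1", "hap2", "phased"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        miss1 = self.hap1 == MISSING
        miss2 = self.hap2 == MISSING
        if not np.array_equal(miss1, miss2):
            raise ValueError("missing calls must be missing on both haplotypes")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # -- derived views -----------------------------------------------------
    def genotypes(self) -> np.ndarray:
        """Alt-allele dosage in {0,1,2}, :data:`MISSING` where no-call."""
        g = self.hap1.astype(np.int8) + self.hap2.astype(np.int8)
        g[self.missing_mask()] = MISSING
        return g

    def missing_mask(self) -> np.ndarray:
        return self.hap1 == MISSING

    def het_mask(self) -> np.ndarray:
        """Called heterozygotes (phased or not)."""
        return (self.hap1 != self.hap2) & ~self.missing_mask()

    def alt_frequency(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Empirical alternate-allele frequency per site over called genotypes."""
        h1, h2 = self.hap1, self.hap2
        if sample_idx is not None:
            h1, h2 = h1[:, sample_idx], h2[:, sample_idx]
        called = h1 != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, h1, 0).sum(axis=1) + np.where(called, h2, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        f = self.alt_frequency(sample_idx)
        return np.minimum(f, 1.0 - f)

    def minor_is_alt(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """True where the alternate allele is the cohort minor allele.

        A site at exactly 0.5 counts the alternate allele as minor.
        """
        return self.alt_frequency(sample_idx) <= 0.5

    # -- manipulation ------------------------------------------------------
    def subset_samples(self, idx: Sequence[int]) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        return PhasedGenotypes(
            sites=self.sites,
            samples=[self.samples[i] for i in idx],
            hap1=self.hap1[:, idx],
            hap2=self.hap2[:, idx],
            phased=self.phased[:, idx],
        )

    def copy(self) -> "PhasedGenotypes":
        return PhasedGenotypes(
            sites=self.sites.copy(),
            samples=list(self.samples),
            hap1=self.hap1.copy(),
            hap2=self.hap2.copy(),
            phased=self.phased.copy(),
        )


@dataclasses.dataclass
class AlleleSignals:
    """Two-channel allele intensities (one matrix pair per assay: gDNA or cDNA).

    Rows align with a :class:`PhasedGenotypes.sites` table; NaN marks a SNP
    without a usable signal (e.g. untranscribed flank SNPs on the cDNA side).
    """

    snps: pd.Index
    samples: list[str]
    a1: np.ndarray  # allele-1 (ref channel) intensity, (n_sites, n_samples)
    a2: np.ndarray  # allele-2 (alt channel) intensity

    def __post_init__(self) -> None:
        shape = (len(self.snps), len(self.samples))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError("signal matrices do not match snps × samples")

    def totals(self) -> np.ndarray:
        return self.a1 + self.a2

    def fractions(self) -> np.ndarray:
        """Allele-1 fraction ``a1/(a1+a2)``; NaN where the total is not positive."""
        total = self.totals()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.a1 / total
        return np.where(np.isfinite(total) & (total > 0), frac, np.nan)

    def subset_samples(self, idx: Sequence[int]) -> "AlleleSignals":
        idx = np.asarray(idx)
        return AlleleSignals(
            snps=self.snps,
            samples=[self.samples[i] for i in idx],
            a1=self.a1[:, idx],
            a2=self.a2[:, idx],
        )


@dataclasses.dataclass
class TranscriptASE:
    """Per-sample, per-transcript signed ASE levels oriented to haplotype 1.

    ``values`` is transcripts × samples (NaN where a sample has no phased
    heterozygous SNP in the transcript body); ``informative`` counts, per
    transcript, the body SNPs heterozygous in at least one cohort sample.
    Only transcripts with ``informative >= min_informative`` are retained.
    """

    values: pd.DataFrame
    informative: pd.Series
    min_informative: int

    def __post_init__(self) -> None:
        finite = self.values.to_numpy()
        finite = finite[np.isfinite(finite)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("ASE levels must lie in [-1, 1]")


@dataclasses.dataclass
class CohortTruth:
    """Simulation ground truth.

    ``table`` has one row per transcript: ``transcript, causal_snp``
    (empty string for non-causal transcripts), ``ase_effect, gte_effect``
    (NaN for non-causal). ``hap1``/``hap2`` are the pre-switch-error,
    pre-missingness haplotypes, consistent with the emitted genotypes.
    """

    table: pd.DataFrame
    hap1: np.ndarray
    hap2: np.ndarray


@dataclasses.dataclass
class Cohort:
    """A complete dataset: everything both scans need, plus optional truth."""

    genotypes: PhasedGenotypes
    transcripts: pd.DataFrame  # TRANSCRIPT_COLUMNS, half-open 0-based
    gdna: AlleleSignals
    cdna: AlleleSignals
    expression: pd.DataFrame  # transcripts × samples
    covariates: pd.DataFrame  # index: sample; columns: age, sex
    truth: CohortTruth | None = None

    def __post_init__(self) -> None:
        samp = list(self.genotypes.samples)
        for name, other in (
            ("gdna", self.gdna.samples),
            ("cdna", self.cdna.samples),
            ("expression", list(self.expression.columns)),
            ("covariates", list(self.covariates.index)),
        ):
            if list(other) != samp:
                raise ValueError(f"sample identifiers of {name} disagree with genotypes")
        missing = [c for c in TRANSCRIPT_COLUMNS if c not in self.transcripts.columns]
        if missing:
            raise ValueError(f"transcript table lacks columns {missing}")

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    def body_site_indices(self, transcript_row: pd.Series) -> np.ndarray:
        """Indices of genotyped sites inside the transcript body [start, end)."""
        sites = self.genotypes.sites
        mask = (
            (sites["chrom"].to_numpy() == transcript_row["chrom"])
            & (sites["pos"].to_numpy() >= transcript_row["start"])
            & (sites["pos"].to_numpy() < transcript_row["end"])
        )
        return np.flatnonzero(mask)
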