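"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a two-platform monocyte cohort: phased
Hardy-Weinberg genotypes across a MAF spectrum, per-transcript two-channel
allele intensities for gDNA and cDNA, a normalized total-expression matrix,
and age/sex covariates. A configurable fraction of transcripts carries one
cis-regulatory SNP whose minor allele both unbalances allelic expression in
heterozygotes (``ase_effect``, an allelic-fraction shift) and shifts total
expression additively per allele (``gte_effect``, in units of the residual
expression SD).

Noise model: gDNA allele fractions are centred on the genotype-implied values
(0, 0.5, 1) with SD ``gdna_ratio_sd``; cDNA fractions carry the same
assay noise plus per-SNP regional RNA noise with SD ``rna_region_sd``. Both
channels are distorted by a quadratic intensity-dependent dye bias
``c0 + c1*t + c2*t^2`` in ``t = log10(total intensity)`` before emission,
which the quantification module's normalization step is expected to remove.

All transcripts are placed on one chromosome, spaced so that cis windows
never overlap; SNP genotypes are drawn independently (no linkage
disequilibrium beyond the single causal site, by design).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    AlleleSignals,
    Cohort,
    CohortTruth,
    PhasedGenotypes,
)

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "introduce_phasing_errors",
]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the emulated study design: 188 samples, 13 body SNPs
    per transcript (the typical informative-SNP count on a dense genotyping
    array), flank SNP density 0.2/kb over ±100 kb flanks (≈49 test SNPs per
    transcript window), gDNA allele-ratio noise SD 0.014 and per-region RNA
    allele-ratio noise SD 0.10.
    """

    n_samples: int = 188
    n_transcripts: int = 200
    snps_per_transcript: int = 13
    flank_snp_density: float = 0.2  # expected SNPs per kb of flanking sequence
    snp_flank: int = 100_000  # bp of flank on each side carrying test SNPs
    transcript_length: tuple[int, int] = (10_000, 50_000)
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal_fraction: float = 0.5
    ase_effect: float = 0.2  # allelic-fraction shift in causal heterozygotes
    gte_effect: float = 0.8  # additive per-allele expression shift (SD units)
    gdna_ratio_sd: float = 0.014
    rna_region_sd: float = 0.10
    dye_bias_coeffs: tuple[float, float, float] = (0.03, -0.01, 0.002)
    switch_error_rate: float = 0.0
    missing_rate: float = 0.01
    age_effect: float = 0.005  # expression shift per year of age
    sex_effect: float = 0.1  # expression shift for sex == 1
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be at least 1")
        if self.snps_per_transcript < 1:
            raise ValueError("snps_per_transcript must be at least 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ase_effect <= 0.5):
            raise ValueError("ase_effect must lie in [0, 0.5] (fraction shift)")
        for name in ("causal_fraction", "switch_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gdna_ratio_sd", "rna_region_sd", "expression_noise_sd",
                     "flank_snp_density"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number")
        if self.transcript_length[0] < 1 or self.transcript_length[0] > self.transcript_length[1]:
            raise ValueError("transcript_length must be a positive (lo, hi) pair")
        if self.snp_flank < 0:
            raise ValueError("snp_flank must be non-negative")


def simulate_genotypes(
    n_samples: int, maf: float, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw phased Hardy-Weinberg genotypes at a single site.

    Each of the two haplotypes carries the minor (alt) allele independently
    with probability ``maf``, so genotype classes occur at (p², 2pq, q²).

    Returns
    -------
    (hap1, hap2)
        int8 arrays of length ``n_samples`` with allele codes 0/1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if not np.isfinite(maf) or not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be a finite value in (0, 0.5], got {maf!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap1 = (rng.random(n_samples) < maf).astype(np.int8)
    hap2 = (rng.random(n_samples) < maf).astype(np.int8)
    return hap1, hap2


def introduce_phasing_errors(
    phased: PhasedGenotypes,
    switch_error_rate: float,
    seed: int | np.random.Generator = 0,
) -> PhasedGenotypes:
    """Flip the haplotype assignment of heterozygous calls at random.

    Each heterozygous call is independently flipped with probability
    ``switch_error_rate``; genotypes are unchanged by construction.
    """
    if not (0.0 <= switch_error_rate <= 1.0):
        raise ValueError(
            f"switch_error_rate must lie in [0, 1], got {switch_error_rate!r}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = phased.copy()
    if switch_error_rate == 0.0:
        return out
    flip = out.het_mask() & (rng.random(out.hap1.shape) < switch_error_rate)
    h1 = out.hap1[flip].copy()
    out.hap1[flip] = out.hap2[flip]
    out.hap2[flip] = h1
    return out


def _unique_positions(rng: np.random.Generator, lo: int, hi: int, k: int) -> np.ndarray:
    """k distinct integer positions in [lo, hi)."""
    span = hi - lo
    if k >= span:
        return np.arange(lo, hi)
    pos = np.unique(rng.integers(lo, hi, size=k))
    while pos.size < k:
        extra = rng.integers(lo, hi, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:k]


def _dye_bias(frac: np.ndarray, log_total: np.ndarray,
              coeffs: tuple[float, float, float]) -> np.ndarray:
    c0, c1, c2 = coeffs
    return np.clip(frac + c0 + c1 * log_total + c2 * log_total**2, 0.0, 1.0)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort with ground truth.

    The returned :class:`~asepower.containers.Cohort` carries phased
    genotypes (after optional switch errors and missingness), a BED-style
    transcript table, gDNA and cDNA allele-signal matrices, a normalized
    expression matrix, age/sex covariates and a :class:`CohortTruth` block.
    Identical config (including seed) gives byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_tx = cfg.n_transcripts
    flank = cfg.snp_flank
    spacing = 2 * flank + 150_000

    # -- transcript layout -------------------------------------------------
    lengths = rng.integers(cfg.transcript_length[0], cfg.transcript_length[1] + 1, n_tx)
    starts = flank + 50_000 + spacing * np.arange(n_tx)
    ends = starts + lengths
    strands = np.where(rng.random(n_tx) < 0.5, "+", "-")
    transcripts = pd.DataFrame(
        {
            "transcript": [f"tx{i:05d}" for i in range(n_tx)],
            "chrom": "chr1",
            "start": starts,
            "end": ends,
            "strand": strands,
        }
    )

    # -- SNP placement -----------------------------------------------------
    positions: list[np.ndarray] = []
    tx_of_site: list[np.ndarray] = []
    in_body: list[np.ndarray] = []
    for i in range(n_tx):
        body = _unique_positions(rng, starts[i], ends[i], cfg.snps_per_transcript)
        n_flank = rng.poisson(cfg.flank_snp_density * 2 * flank / 1000.0)
        offs = rng.integers(0, 2 * flank, size=n_flank) if n_flank else np.empty(0, int)
        fl = np.where(offs < flank, starts[i] - flank + offs, ends[i] + offs - flank)
        pos = np.concatenate([body, fl])
        body_flag = np.concatenate(
            [np.ones(body.size, bool), np.zeros(fl.size, bool)]
        )
        order = np.argsort(pos, kind="stable")
        positions.append(pos[order])
        in_body.append(body_flag[order])
        tx_of_site.append(np.full(pos.size, i))
    pos_all = np.concatenate(positions)
    body_all = np.concatenate(in_body)
    tx_all = np.concatenate(tx_of_site)
    n_sites = pos_all.size

    sites = pd.DataFrame(
        {
            "snp": [f"snp{i:06d}" for i in range(n_sites)],
            "chrom": "chr1",
            "pos": pos_all,
            "ref": "A",
            "alt": "G",
        }
    )

    # -- genotypes (alt allele = designed minor allele) ---------------------
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n_sites)
    hap1 = (rng.random((n_sites, n)) < maf[:, None]).astype(np.int8)
    hap2 = (rng.random((n_sites, n)) < maf[:, None]).astype(np.int8)
    true_hap1, true_hap2 = hap1.copy(), hap2.copy()
    geno_true = hap1 + hap2

    # -- causal assignment ---------------------------------------------------
    causal_tx = rng.random(n_tx) < cfg.causal_fraction
    causal_site = np.full(n_tx, -1)
    for i in np.flatnonzero(causal_tx):
        own = np.flatnonzero(tx_all == i)
        causal_site[i] = rng.choice(own)
    truth_table = pd.DataFrame(
        {
            "transcript": transcripts["transcript"],
            "causal_snp": [
                sites["snp"].iat[s] if s >= 0 else "" for s in causal_site
            ],
            "ase_effect": np.where(causal_tx, cfg.ase_effect, np.nan),
            "gte_effect": np.where(causal_tx, cfg.gte_effect, np.nan),
        }
    )

    # -- covariates and expression ------------------------------------------
    age = rng.uniform(18.0, 65.0, n)
    sex = rng.integers(0, 2, n)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex}, index=pd.Index([f"S{j:04d}" for j in range(n)], name="sample")
    )
    samples = list(covariates.index)

    baseline = rng.normal(0.0, 1.0, n_tx)
    expr = (
        baseline[:, None]
        + cfg.age_effect * (age - 41.5)[None, :]
        + cfg.sex_effect * sex[None, :]
        + rng.normal(0.0, cfg.expression_noise_sd, (n_tx, n))
    )
    for i in np.flatnonzero(causal_tx):
        expr[i] += cfg.gte_effect * geno_true[causal_site[i]]
    expression = pd.DataFrame(
        expr, index=transcripts["transcript"].to_numpy(), columns=samples
    )

    # -- true allele-1 (ref) fractions --------------------------------------
    # genotype-implied: 1 - g/2 (hom ref -> 1, het -> 0.5, hom alt -> 0)
    frac_g = 1.0 - geno_true / 2.0

    frac_c = frac_g.copy()
    e = cfg.ase_effect
    if e > 0:
        for i in np.flatnonzero(causal_tx):
            cs = causal_site[i]
            carriers = np.flatnonzero(true_hap1[cs] != true_hap2[cs])
            if carriers.size == 0:
                continue
            own = np.flatnonzero(tx_all == i)
            body_sites = own[body_all[own]]
            # over-expressed haplotype = the one carrying the alt (minor) allele
            hapstar_is_1 = true_hap1[cs, carriers] == 1
            sub1 = true_hap1[np.ix_(body_sites, carriers)]
            sub2 = true_hap2[np.ix_(body_sites, carriers)]
            het = sub1 != sub2
            # ref allele sits on the over-expressed haplotype?
            ref_on_star = np.where(hapstar_is_1[None, :], sub1 == 0, sub2 == 0)
            shift = np.where(ref_on_star, e, -e)
            block = frac_c[np.ix_(body_sites, carriers)]
            frac_c[np.ix_(body_sites, carriers)] = np.where(het, 0.5 + shift, block)

    # -- signal emission ----------------------------------------------------
    t_g = rng.normal(3.0, 0.25, (n_sites, n))
    obs_g = np.clip(frac_g + rng.normal(0.0, cfg.gdna_ratio_sd, (n_sites, n)), 0, 1)
    obs_g = _dye_bias(obs_g, t_g, cfg.dye_bias_coeffs)
    total_g = 10.0**t_g
    gdna = AlleleSignals(
        snps=pd.Index(sites["snp"]), samples=samples,
        a1=obs_g * total_g, a2=(1.0 - obs_g) * total_g,
    )

    t_c = rng.normal(3.0, 0.25, (n_sites, n))
    obs_c = np.clip(
        frac_c
        + rng.normal(0.0, cfg.gdna_ratio_sd, (n_sites, n))
        + rng.normal(0.0, cfg.rna_region_sd, (n_sites, n)),
        0, 1,
    )
    obs_c = _dye_bias(obs_c, t_c, cfg.dye_bias_coeffs)
    total_c = 10.0**t_c
    a1_c = obs_c * total_c
    a2_c = (1.0 - obs_c) * total_c
    # flank SNPs are untranscribed: no cDNA signal
    a1_c[~body_all, :] = np.nan
    a2_c[~body_all, :] = np.nan
    cdna = AlleleSignals(snps=pd.Index(sites["snp"]), samples=samples, a1=a1_c, a2=a2_c)

    # -- emitted genotype calls: switch errors, then missingness -------------
    phased = np.ones((n_sites, n), bool)
    genotypes = PhasedGenotypes(
        sites=sites, samples=samples, hap1=hap1, hap2=hap2, phased=phased
    )
    if cfg.switch_error_rate > 0:
        genotypes = introduce_phasing_errors(genotypes, cfg.switch_error_rate, rng)
    if cfg.missing_rate > 0:
        miss = rng.random((n_sites, n)) < cfg.missing_rate
        genotypes.hap1[miss] = MISSING
        genotypes.hap2[miss] = MISSING

    truth = CohortTruth(table=truth_table, hap1=true_hap1, hap2=true_hap2)
    return Cohort(
        genotypes=genotypes,
        transcripts=transcripts,
        gdna=gdna,
        cdna=cdna,
        expression=expression,
        covariates=covariates,
        truth=truth,
    )
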