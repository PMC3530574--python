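# Methods

## Statistical models

**ASE scan.** For each transcript, per-SNP ASE levels (cDNA allele-1
fraction minus gDNA allele-1 fraction at phased heterozygous calls) are
sign-oriented to each sample's haplotype 1 and averaged over the
heterozygous SNPs in the transcript body (arithmetic mean by default; a
median aggregator is available because both conventions appear in
practice). Each cis SNP is coded per sample as x = +1 (heterozygote,
minor allele on haplotype 1), −1 (minor allele on haplotype 2) or 0
(homozygote), and the transcript's ASE vector is regressed on x **through
the origin** with a two-sided t-test on the slope (df = n−1). The origin
model is deliberate: haplotype labels are arbitrary per sample, and
relabeling a sample negates its oriented ASE and its coding together — an
exact symmetry of the no-intercept regression only. It also encodes the
biological baseline: homozygotes at a cis-rSNP have no allelic imbalance,
so the expected ASE at x = 0 is 0. A per-sample haplotype relabel
therefore changes no p-value (the tests themselves are invariant; the
group-size filter counts +1/−1 membership, so a relabel can move a
borderline test across the filter).

**GTE scan.** Total expression is regressed on minor-allele dosage
(0/1/2) with age and sex as covariates, two-sided t-test on the dosage
slope. A covariate constant over the analyzed subset (e.g. sex in a
single-sex subset) is dropped with a warning. Minor alleles are defined
by the empirical frequency in the analyzed sample subset, not the
simulation truth — what a real analysis could compute.

**Cis windows and filters.** Test SNPs are all genotyped SNPs within the
closed interval [start − flank, end + flank] (flank 100 kb by default,
500 kb variant), clipped at the chromosome start. ASE-measuring SNPs are
restricted to the transcript body (cDNA signal requires transcription);
flank SNPs act as test SNPs only. A transcript enters the ASE analysis
only with ≥ `min_informative` (default 5, alternative 3) body SNPs that
are heterozygous in at least one cohort sample. A test is skipped unless
every non-empty genotype group has ≥ `min_group` values (4 for ASE, 3 for
GTE) and at least two groups are present; requiring *all three* groups is
available as a switch (off by default) but would discard low-MAF SNPs
whose rare homozygote class is absent.

**Multiple testing.** Bonferroni (p·m, capped at 1) and
Benjamini–Hochberg step-up ((m/i)·p over ascending ranks with a
running-minimum monotonicity pass; stable sort, so tied p receive equal
adjusted values). m is the post-filter test count of the scan at hand and
is recorded in every output header.

**Permutation null.** Sample identifiers are shuffled once per iteration
and applied to the genotype/phase side only; the ASE and expression
matrices are computed once and verified bit-identical afterwards (so
phasing and aggregation are untouched while the genotype–phenotype
linkage is broken). Pooled post-filter p-values are summarized by the KS
distance to uniform, the fraction below 0.05 and QQ quantiles.

## The synthetic cohort generator

The generator emulates a two-platform monocyte-style cohort measured with
two-channel genotyping arrays on gDNA and cDNA. Defaults are the study
conditions the package is tested under:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_samples` | 188 | ASE arm of the emulated design |
| `n_transcripts` | 200 | desk-scale; acceptance runs use 500 |
| `snps_per_transcript` | 13 | typical (median) informative SNPs per transcript on a dense array |
| `flank_snp_density` | 0.2/kb | reproduces ≈ 49 test SNPs per 100 kb-flank window, the genome-wide tests-per-transcript ratio |
| `maf_range` | (0.01, 0.5) | uniform MAF spectrum; genotypes drawn under HWE, haplotypes independent |
| `causal_fraction` | 0.5 | fraction of transcripts given one causal cis-rSNP, placed uniformly over body+flanks |
| `ase_effect` | 0.2 | allelic-fraction shift in causal heterozygotes (0.7/0.3 ≈ 2.3-fold allelic ratio) |
| `gte_effect` | 0.8 | additive per-allele expression shift in residual-SD units, matched a priori to the allelic effect's magnitude |
| `gdna_ratio_sd` | 0.014 | gDNA allele-ratio noise (array assay noise) |
| `rna_region_sd` | 0.10 | additional per-SNP RNA allele-ratio noise over a region |
| `dye_bias_coeffs` | (0.03, −0.01, 0.002) | quadratic intensity-dependent fraction distortion c₀+c₁t+c₂t², t = log₁₀ total signal |
| `switch_error_rate` | 0 | optional per-het phase flips (genotypes preserved) |
| `missing_rate` | 0.01 | MCAR no-calls, emulating posterior-probability exclusions |
| age, sex | U(18,65), Bernoulli(0.5) | small expression effects (0.005/yr, 0.1) exercise the covariate adjustment |

Expression is generated directly on a normalized scale (per-transcript
Gaussian baseline, unit residual SD), standing in for the variance
stabilization and quantile normalization a real array pipeline performs
upstream. A causal SNP's minor allele marks the over-expressed haplotype:
carriers' heterozygous body SNPs get cDNA fractions 0.5 ± `ase_effect`
(sign by which haplotype carries allele 1), and expression shifts by
`gte_effect` per minor allele. Signals are emitted as two-channel
intensities with log-normal totals; the dye bias distorts both channels'
fractions before emission and is what the quantification step's
normalization (per sample-array quadratic fit on heterozygous gDNA
fractions, whose truth is 0.5 — the one internal standard available)
must remove. Transcripts sit on one chromosome, spaced so cis windows
never overlap.

**What the generator does not model** — and hence what passing tests do
not show about real data: linkage disequilibrium (each SNP is drawn
independently, so "unique significant SNPs" are essentially causal SNPs,
whereas real counts are inflated by LD clusters), population structure,
alternative splicing, trans-acting variation shared across samples, and
read-count (RNA-seq) noise. GTE expression noise is homoscedastic
Gaussian, so the *unfiltered* GTE permutation null stays essentially
calibrated here; the small-group inflation the filters exist to remove is
reproduced on the ASE side, where it arises mechanistically from
heteroscedastic per-sample ASE precision (samples differ in the number of
heterozygous body SNPs averaged).

## Numerical choices

* Both regression kernels are closed-form batched normal equations
  (pseudoinverse for the covariate model); tests pin them to a
  general-purpose OLS implementation at 1e-10.
* Zero-total signals are missing observations, never 0 or 0.5. A test
  with zero residual variance and a nonzero slope reports p = 0 (exact
  fit); a constant-zero response is flagged `degenerate` with p = NaN and
  is excluded from correction denominators.
* Best-association-per-SNP ties break by smallest transcript id; record
  tables are ordered (transcript, position) — all outputs are
  deterministic given seeds, including the down-sampling subsets.
* MAF bins are [b%, (b+1)%) for b = 0..49 with MAF = 0.5 in the last
  bin; the 5-bin sliding average truncates at the edges and skips empty
  bins. Distances to TSS/TTS are signed and strand-oriented (upstream
  negative), 0-based internally; BED intervals are half-open, VCF
  positions 1-based on disk.
* Dye-bias normalization needs ≥ 30 heterozygous gDNA observations per
  array; below that the array passes through uncorrected with a warning.

## Problem sizes

The test suite and the acceptance script run the calibration study at
n = 100 samples × 200 transcripts × 100 permutations (≈ 10⁶ pooled null
tests per scan) and the power comparison on a 500-transcript cohort with
subsets of 50/95/188 samples, medians over 10 random subsets — sizes
chosen so the full suite completes in minutes on one CPU while keeping
every Monte-Carlo margin comfortable.

## Known limitations

The region-SD QC flags transcripts where most samples' within-region SD
exceeds their own |ASE|; under this generator a sample without true
imbalance always exceeds (its expected ASE is zero), so the flag fraction
tracks the homozygote fraction at the causal SNP and the QC is best read
as a *relative* discrimination between signal-dominated and
noise-dominated regions. Single-SNP causality also means top-list
overlap saturates quickly; with LD, real overlap percentages are lower
and sample-size dependent.
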