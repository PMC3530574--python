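# asepower

Comparing the power of **allele-specific expression (ASE) analysis** and
**eQTL-style genotype–expression (GTE) mapping** for identifying
*cis*-regulatory SNPs, on synthetic cohorts with known ground truth.

## The problem

A *cis*-regulatory SNP (rSNP) changes the expression of a nearby gene.
Two array-based strategies can find them in a genotyped cohort:

* **GTE (eQTL) mapping** regresses *total* expression across samples on
  SNP genotype: for SNP dosage *g* ∈ {0,1,2} minor alleles,

  &nbsp;&nbsp;&nbsp;&nbsp;*y*ᵢ = β₀ + β·*g*ᵢ + γ₁·ageᵢ + γ₂·sexᵢ + εᵢ,

  with a two-sided t-test on β. The signal must survive all
  between-sample variation in expression.

* **ASE analysis** measures the imbalance between a transcript's two
  parental alleles *within* each sample. At every heterozygous SNP the
  ASE level is the difference in allele fractions between cDNA and gDNA,

  &nbsp;&nbsp;&nbsp;&nbsp;A1꜀ᴰᴺᴬ/(A1꜀ᴰᴺᴬ+A2꜀ᴰᴺᴬ) − A1ɢᴰᴺᴬ/(A1ɢᴰᴺᴬ+A2ɢᴰᴺᴬ),

  phase-oriented so that positive means "haplotype 1 over-expressed",
  and averaged over the transcript body (kept only with ≥5 informative
  SNPs). Each cis SNP is then tested by regressing these levels on the
  phase coding *x* ∈ {+1, 0, −1} (heterozygotes split by which haplotype
  carries the minor allele; homozygotes are the zero baseline), through
  the origin so the test is invariant to arbitrary haplotype labels.

Because ASE cancels between-sample variation (trans effects, environment),
it needs far fewer samples than GTE for the same rSNP. This package
implements both scans over cis windows (transcript ±100 kb, 500 kb
variant), the group-size filters that keep the null honest (≥4 ASE / ≥3
GTE values per genotype group), Bonferroni and Benjamini–Hochberg step-up
control, permutation-null calibration by sample-identifier shuffling, and
the power-comparison instruments: significance counting under
down-sampling, top-list overlap, MAF-binned detection curves, and
TSS/TTS positional enrichment.

A synthetic-cohort generator drives everything: phased Hardy-Weinberg
genotypes over a MAF spectrum, causal SNPs injecting both an allelic
imbalance in heterozygotes and an additive expression shift, realistic
allele-ratio noise (gDNA SD 0.014, per-region RNA SD 0.10), a quadratic
intensity-dependent dye bias, age/sex confounding, missing calls and
optional phasing switch errors — so every stage has a parameter-recovery
and calibration test surface without any controlled-access data.

## Worked example

```bash
python examples/05_power_comparison.py
```

```
unique Bonferroni-0.05 significant SNPs (median over subsets):
  n=188: ASE    97  GTE    70  ratio   1.4
  n= 95: ASE    87  GTE    32  ratio   2.7
  n= 50: ASE    77  GTE     7  ratio  11.0
the ASE advantage grows as the cohort shrinks: within-sample allelic
ratios carry far less between-sample variance than total expression
top-list overlap: 60/60 of the GTE top SNPs are also in the ASE top list
(100% of 8993 SNPs eligible for both methods)
ASE detected fraction, MAF<15% vs >30%: 0.0116 vs 0.0088 (ASE stays
sensitive at low MAF)
```

On a 200-transcript cohort (half carrying a causal cis-rSNP) both scans
detect the shared signals at the full sample size, but down-sampling
collapses GTE power (70 → 7 unique significant SNPs from n=188 to n=50)
while ASE barely degrades (97 → 77); every top GTE hit is rediscovered by
ASE, and ASE keeps detecting low-MAF rSNPs where GTE cannot. The other
examples (`examples/01…06`) walk through simulation, quantification, the
scans, null calibration and the full YAML-configured pipeline.

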