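"""Compare the statistical power of ASE and GTE mapping under down-sampling.

Reproduces the three comparison instruments on one synthetic cohort:
significance counting at shrinking sample sizes (medians over random
subsets), the top-list overlap between the methods, and the MAF-binned
detection curves.
"""
import asepower as ap

cohort = ap.simulate_cohort(ap.SimulationConfig(n_transcripts=200, seed=5))

summary = ap.compare_power(cohort, sample_sizes=(50, 95, 188), n_runs=5, seed=5)
print("unique Bonferroni-0.05 significant SNPs (median over subsets):")
for n in (188, 95, 50):
    ase = summary.count("ASE", n, "bonferroni_0.05", "snps")
    gte = summary.count("GTE", n, "bonferroni_0.05", "snps")
    print(f"  n={n:3d}: ASE {ase:5.0f}  GTE {gte:5.0f}  "
          f"ratio {summary.ratio(n, 'bonferroni_0.05', 'snps'):5.1f}")
print("the ASE advantage grows as the cohort shrinks: within-sample allelic "
      "ratios carry far less between-sample variance than total expression")

ase_rec = ap.add_corrections(ap.run_scan(cohort, "ase"))
gte_rec = ap.add_corrections(ap.run_scan(cohort, "gte"))
ov = ap.toplist_overlap(ase_rec, gte_rec, k_ase=200, k_gte=60)
print(f"top-list overlap: {ov.n_overlap}/{ov.k_gte} of the GTE top SNPs are "
      f"also in the ASE top list ({ov.overlap_percent:.0f}% of {ov.n_eligible} "
      "SNPs eligible for both methods)")

curve = ap.maf_power_curve(ase_rec)
low = curve.loc[0:14, "fraction"].mean()
high = curve.loc[30:49, "fraction"].mean()
print(f"ASE detected fraction, MAF<15% vs >30%: {low:.4f} vs {high:.4f} "
      "(ASE stays sensitive at low MAF)")
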