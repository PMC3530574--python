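"""Association scans: windows, coding, group filters, OLS correctness."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import asepower as ap
from asepower.association import cis_window, select_test_snps


def _tx(start, end, chrom="chr1", strand="+", name="txA"):
    return pd.Series(
        {"transcript": name, "chrom": chrom, "start": start, "end": end,
         "strand": strand}
    )


class TestCisWindow:
    def test_window_arithmetic(self):
        w = cis_window(_tx(200_000, 210_000), flank=100_000)
        assert (w.lo, w.hi) == (100_000, 310_000)

    def test_clipped_at_chromosome_start(self):
        w = cis_window(_tx(30_000, 40_000), flank=100_000)
        assert w.lo == 0

    def test_wide_flank_selects_superset(self):
        sites = pd.DataFrame({
            "snp": [f"s{i}" for i in range(8)],
            "chrom": "chr1",
            "pos": [50_000, 120_000, 199_999, 205_000, 310_000, 400_000,
                    650_000, 800_000],
        })
        narrow = select_test_snps(sites, cis_window(_tx(200_000, 210_000), 100_000))
        wide = select_test_snps(sites, cis_window(_tx(200_000, 210_000), 500_000))
        assert set(narrow) <= set(wide)
        assert len(wide) > len(narrow)
        # closed interval: boundary SNPs included
        assert 4 in narrow and 1 in narrow

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            cis_window(_tx(0, 10), flank=-1)


class TestAseGroups:
    def test_coding_definitions(self):
        # sites with alt as minor allele
        hap1 = np.array([0, 1, 1, 0, ap.MISSING, 0], np.int8)
        hap2 = np.array([1, 0, 1, 0, ap.MISSING, 1], np.int8)
        phased = np.array([True, True, True, True, True, False])
        x = ap.ase_groups(hap1, hap2, phased, minor_is_alt=True)
        assert x[0] == -1.0  # 0|1: minor allele on hap2
        assert x[1] == +1.0  # 1|0: minor allele on hap1
        assert x[2] == 0.0   # 1|1 homozygote baseline
        assert x[3] == 0.0   # 0|0 homozygote baseline
        assert np.isnan(x[4])  # missing call excluded
        assert np.isnan(x[5])  # unphased het excluded

    def test_ref_minor_flips_coding(self):
        hap1 = np.array([0, 1], np.int8)
        hap2 = np.array([1, 0], np.int8)
        phased = np.ones(2, bool)
        x = ap.ase_groups(hap1, hap2, phased, minor_is_alt=False)
        assert x[0] == +1.0 and x[1] == -1.0


class TestGroupFilters:
    def test_small_ase_group_skips_test(self, rng):
        # groups: +1 x3, -1 x10, 0 x20 -> smallest non-empty group below 4
        x = np.r_[np.ones(3), -np.ones(10), np.zeros(20)]
        y = rng.normal(size=x.size)
        assert ap.ase_association(y, x, min_group=4) is None
        assert ap.ase_association(y, x, min_group=3) is not None

    def test_absent_group_keeps_low_maf_snp_testable(self, rng):
        # no -1 group at all: test runs if both present groups are large enough
        x = np.r_[np.ones(6), np.zeros(30)]
        y = rng.normal(size=x.size)
        assert ap.ase_association(y, x, min_group=4) is not None
        assert ap.ase_association(y, x, min_group=4, require_all_groups=True) is None

    def test_single_group_never_tested(self, rng):
        x = np.zeros(30)
        y = rng.normal(size=30)
        assert ap.ase_association(y, x, min_group=0) is None

    def test_small_gte_group_skips_test(self, rng):
        d = np.r_[np.zeros(2), np.ones(30), np.full(30, 2.0)]
        y = rng.normal(size=d.size)
        age = rng.uniform(18, 65, d.size)
        sex = rng.integers(0, 2, d.size).astype(float)
        assert ap.gte_association(y, d, age, sex, min_group=3) is None
        assert ap.gte_association(y, d, age, sex, min_group=2) is not None

    def test_filter_monotonicity_on_scan(self, small_cohort):
        sizes = [
            len(ap.run_scan(small_cohort, "ase", min_group=m)) for m in (2, 4, 8)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestOLSCorrectness:
    def test_perfect_signal(self):
        x = np.r_[np.ones(5), np.zeros(5), -np.ones(5)]
        rec = ap.ase_association(x.copy(), x, min_group=4)
        assert rec["slope"] == pytest.approx(1.0)
        assert rec["p"] == 0.0

    def test_zero_response_variance_flagged(self):
        x = np.r_[np.ones(5), np.zeros(5), -np.ones(5)]
        rec = ap.ase_association(np.zeros(15), x, min_group=4)
        assert rec["degenerate"] and np.isnan(rec["p"])

    def test_ase_matches_statsmodels(self, rng):
        """The origin regression agrees with an independent OLS to 1e-10."""
        for _ in range(100):
            n = rng.integers(12, 60)
            x = rng.choice([-1.0, 0.0, 1.0], n)
            if len(np.unique(x)) < 2:
                continue
            y = rng.normal(size=n) + 0.3 * x
            rec = ap.ase_association(y, x, min_group=0)
            if rec is None:
                continue
            fit = sm.OLS(y, x).fit()  # through the origin, like the test
            assert rec["slope"] == pytest.approx(fit.params[0], abs=1e-10)
            assert rec["se"] == pytest.approx(fit.bse[0], abs=1e-10)
            assert rec["p"] == pytest.approx(fit.pvalues[0], abs=1e-10)

    def test_gte_matches_statsmodels(self, rng):
        """Covariate-adjusted regression agrees with an independent OLS to 1e-10."""
        for _ in range(100):
            n = int(rng.integers(20, 80))
            d = rng.choice([0.0, 1.0, 2.0], n)
            age = rng.uniform(18, 65, n)
            sex = rng.integers(0, 2, n).astype(float)
            if len(np.unique(d)) < 2 or len(np.unique(sex)) < 2:
                continue
            y = rng.normal(size=n) + 0.4 * d + 0.01 * age + 0.2 * sex
            rec = ap.gte_association(y, d, age, sex, min_group=0)
            if rec is None:
                continue
            X = sm.add_constant(np.column_stack([age, sex, d]))
            fit = sm.OLS(y, X).fit()
            assert rec["slope"] == pytest.approx(fit.params[3], abs=1e-10)
            assert rec["se"] == pytest.approx(fit.bse[3], abs=1e-10)
            assert rec["p"] == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_single_sex_subset_drops_covariate(self, rng, caplog):
        d = np.r_[np.zeros(10), np.ones(10), np.full(10, 2.0)]
        y = rng.normal(size=30)
        age = rng.uniform(18, 65, 30)
        sex = np.zeros(30)
        with caplog.at_level("WARNING"):
            rec = ap.gte_association(y, d, age, sex)
        assert rec is not None and np.isfinite(rec["p"])
        assert "sex" in caplog.text


class TestRunScan:
    def test_deterministic_order(self, small_cohort):
        rec = ap.run_scan(small_cohort, "ase")
        grouped = rec.groupby("transcript", sort=False)["pos"]
        assert all(np.all(np.diff(g.to_numpy()) >= 0) for _, g in grouped)
        assert list(rec["transcript"]) == sorted(rec["transcript"])

    def test_scan_matches_single_test_api(self, small_cohort, small_ase):
        rec = ap.run_scan(small_cohort, "ase", ase=small_ase)
        geno = small_cohort.genotypes
        snp_idx = pd.Index(geno.sites["snp"])
        minor_alt = geno.minor_is_alt()
        row = rec.iloc[len(rec) // 2]
        s = snp_idx.get_loc(row["snp"])
        x = ap.ase_groups(geno.hap1[s], geno.hap2[s], geno.phased[s], minor_alt[s])
        y = small_ase.values.loc[row["transcript"]].to_numpy()
        single = ap.ase_association(y, x)
        assert single["slope"] == pytest.approx(row["slope"], abs=1e-12)
        assert single["p"] == pytest.approx(row["p"], abs=1e-12)

    def test_gte_scan_matches_single_test_api(self, small_cohort):
        rec = ap.run_scan(small_cohort, "gte")
        geno = small_cohort.genotypes
        snp_idx = pd.Index(geno.sites["snp"])
        row = rec.iloc[len(rec) // 3]
        s = snp_idx.get_loc(row["snp"])
        g = geno.genotypes()[s].astype(float)
        g[g == ap.MISSING] = np.nan
        if not geno.minor_is_alt()[s]:
            g = 2.0 - g
        single = ap.gte_association(
            small_cohort.expression.loc[row["transcript"]].to_numpy(),
            g,
            small_cohort.covariates["age"].to_numpy(),
            small_cohort.covariates["sex"].to_numpy(),
        )
        assert single["slope"] == pytest.approx(row["slope"], abs=1e-12)
        assert single["p"] == pytest.approx(row["p"], abs=1e-12)

    def test_sign_invariance_of_pvalues(self, small_cohort, small_ase):
        """Relabeling one sample's haplotypes leaves every ASE p unchanged."""
        base = ap.run_scan(small_cohort, "ase")
        flipped = small_cohort.genotypes.copy()
        j = 7
        h1 = flipped.hap1[:, j].copy()
        flipped.hap1[:, j] = flipped.hap2[:, j]
        flipped.hap2[:, j] = h1
        cohort2 = dataclasses.replace(small_cohort, genotypes=flipped)
        other = ap.run_scan(cohort2, "ase")
        merged = base.merge(other, on=["snp", "transcript"], suffixes=("_a", "_b"))
        # the group-size filter counts +1/-1 membership, which the flip can
        # swap across the threshold, so compare the tests present both times
        assert len(merged) >= 0.95 * len(base)
        np.testing.assert_allclose(
            merged["p_a"].to_numpy(), merged["p_b"].to_numpy(),
            atol=1e-12, equal_nan=True,
        )

    def test_wider_flank_yields_more_tests(self, small_cohort):
        # SNPs exist out to ±100 kb; a 40 kb scan must test fewer pairs
        narrow = ap.run_scan(small_cohort, "ase", flank=40_000)
        default = ap.run_scan(small_cohort, "ase", flank=100_000)
        assert len(default) > len(narrow)

    def test_causal_snp_wins_its_window(self):
        """At effect 0.3 the causal SNP attains the window's minimum ASE p ≥90%."""
        cfg = ap.SimulationConfig(
            n_samples=188, n_transcripts=60, causal_fraction=1.0,
            ase_effect=0.3, maf_range=(0.1, 0.5), seed=53,
        )
        cohort = ap.simulate_cohort(cfg)
        rec = ap.run_scan(cohort, "ase")
        truth = cohort.truth.table.set_index("transcript")["causal_snp"]
        wins = 0
        total = 0
        for tx, grp in rec.groupby("transcript"):
            causal = truth.loc[tx]
            if causal not in set(grp["snp"]):
                continue  # causal SNP itself filtered (tiny het group)
            total += 1
            best = grp.loc[grp["p"].idxmin(), "snp"]
            wins += best == causal
        assert total >= 50
        assert wins / total >= 0.9
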