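"""Power instruments: counting panels, top-list overlap, MAF and position curves."""
import numpy as np
import pandas as pd
import pytest

import asepower as ap
from asepower.power import THRESHOLD_TYPES


def _toy_records(rows):
    df = pd.DataFrame(
        rows,
        columns=["snp", "transcript", "p", "p_bonf", "p_fdr", "maf",
                 "dist_tss", "dist_tts"],
    )
    return df


class TestCountSignificant:
    def test_toy_enumeration(self):
        rec = _toy_records([
            ("s1", "t1", 1e-9, 0.001, 0.001, 0.3, 0, 0),
            ("s1", "t2", 1e-8, 0.010, 0.002, 0.3, 0, 0),
            ("s2", "t1", 1e-7, 0.100, 0.010, 0.2, 0, 0),
            ("s3", "t3", 0.5, 1.0, 0.9, 0.1, 0, 0),
            ("s4", "t3", 0.6, 1.0, 0.9, 0.1, 0, 0),
            ("s5", "t4", 0.7, 1.0, 0.9, 0.4, 0, 0),
        ])
        # bonferroni 0.05: rows 1,2 pass -> 2 assoc; s1 only unique; t1,t2
        assert ap.count_significant(rec, "bonferroni_0.05") == (2, 1, 2)
        # fdr 0.05: rows 1,2,3 -> s1,s2 unique; t1,t2
        assert ap.count_significant(rec, "fdr_0.05") == (3, 2, 2)

    def test_one_snp_many_transcripts(self):
        rec = _toy_records([
            ("s1", "t1", 1e-9, 0.001, 0.001, 0.3, 0, 0),
            ("s1", "t2", 1e-9, 0.001, 0.001, 0.3, 0, 0),
            ("s1", "t3", 1e-9, 0.001, 0.001, 0.3, 0, 0),
        ])
        assert ap.count_significant(rec, "bonferroni_0.05") == (3, 1, 3)

    def test_nothing_passes(self):
        rec = _toy_records([("s1", "t1", 0.5, 1.0, 0.9, 0.3, 0, 0)])
        assert ap.count_significant(rec, "bonferroni_0.01") == (0, 0, 0)

    def test_tie_broken_by_smallest_transcript(self):
        rec = _toy_records([
            ("s1", "t2", 1e-9, 0.001, 0.001, 0.3, 0, 0),
            ("s1", "t1", 1e-9, 0.001, 0.001, 0.3, 0, 0),
        ])
        from asepower.power import _best_per_snp
        assert _best_per_snp(rec)["transcript"].iloc[0] == "t1"

    def test_unknown_threshold_rejected(self):
        rec = _toy_records([("s1", "t1", 0.5, 1.0, 0.9, 0.3, 0, 0)])
        with pytest.raises(ValueError, match="threshold"):
            ap.count_significant(rec, "bonferroni_0.2")

    def test_panel_inequalities_on_real_scan(self, small_cohort):
        rec = ap.add_corrections(ap.run_scan(small_cohort, "ase"))
        for thr in THRESHOLD_TYPES:
            n_assoc, n_snp, n_tx = ap.count_significant(rec, thr)
            assert n_snp <= n_assoc and n_tx <= n_assoc


class TestDownsampling:
    def test_full_cohort_degenerates_to_single_run(self, small_cohort):
        n = small_cohort.n_samples
        table = ap.downsample_counts(small_cohort, "ase", n, n_runs=10, seed=1)
        rec = ap.add_corrections(ap.run_scan(small_cohort, "ase"))
        a, s, t = ap.count_significant(rec, "bonferroni_0.05")
        row = table[(table.threshold == "bonferroni_0.05") & (table.panel == "snps")]
        assert row["count"].iloc[0] == s

    def test_medians_reproducible(self, small_cohort):
        a = ap.downsample_counts(small_cohort, "ase", 40, n_runs=3, seed=5)
        b = ap.downsample_counts(small_cohort, "ase", 40, n_runs=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_subset_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            ap.downsample_counts(small_cohort, "ase", small_cohort.n_samples + 1)

    def test_counts_fall_with_sample_size(self, small_cohort):
        rows = []
        for n in (80, 40):
            t = ap.downsample_counts(small_cohort, "ase", n, n_runs=3, seed=2)
            rows.append(
                t[(t.threshold == "bonferroni_0.05") & (t.panel == "associations")][
                    "count"
                ].iloc[0]
            )
        assert rows[0] >= rows[1]


class TestRatio:
    def test_plain_ratio(self):
        assert ap.ase_gte_ratio(30, 10) == pytest.approx(3.0)

    def test_zero_gte_is_inf(self):
        assert np.isinf(ap.ase_gte_ratio(5, 0))
        assert np.isnan(ap.ase_gte_ratio(0, 0))


class TestToplistOverlap:
    def test_identical_lists_full_overlap(self):
        rec = _toy_records([
            ("s1", "t1", 1e-9, 0.1, 0.1, 0.3, 0, 0),
            ("s2", "t1", 1e-8, 0.1, 0.1, 0.3, 0, 0),
            ("s3", "t1", 1e-7, 0.1, 0.1, 0.3, 0, 0),
        ])
        res = ap.toplist_overlap(rec, rec.copy(), k_ase=3, k_gte=3)
        assert res.overlap_percent == 100.0

    def test_disjoint_toplists(self):
        ase = _toy_records([
            ("s1", "t1", 1e-9, 0.1, 0.1, 0.3, 0, 0),
            ("s2", "t1", 0.9, 1.0, 1.0, 0.3, 0, 0),
        ])
        gte = _toy_records([
            ("s1", "t1", 0.9, 1.0, 1.0, 0.3, 0, 0),
            ("s2", "t1", 1e-9, 0.1, 0.1, 0.3, 0, 0),
        ])
        res = ap.toplist_overlap(ase, gte, k_ase=1, k_gte=1)
        assert res.overlap_percent == 0.0
        assert res.n_eligible == 2

    def test_oversized_k_capped(self, caplog):
        rec = _toy_records([("s1", "t1", 1e-9, 0.1, 0.1, 0.3, 0, 0)])
        with caplog.at_level("WARNING"):
            res = ap.toplist_overlap(rec, rec.copy(), k_ase=10, k_gte=10)
        assert res.k_gte == 1 and "capping" in caplog.text

    def test_intersection_symmetric(self, headline_cohort):
        """Swapping method roles changes the denominator, not the intersection."""
        ase = ap.add_corrections(ap.run_scan(headline_cohort, "ase"))
        gte = ap.add_corrections(ap.run_scan(headline_cohort, "gte"))
        a = ap.toplist_overlap(ase, gte, k_ase=300, k_gte=100)
        b = ap.toplist_overlap(gte, ase, k_ase=100, k_gte=300)
        assert a.n_overlap == b.n_overlap
        assert a.k_gte != b.k_gte

    def test_shared_causal_signal_overlaps(self, headline_cohort):
        ase = ap.add_corrections(ap.run_scan(headline_cohort, "ase"))
        gte = ap.add_corrections(ap.run_scan(headline_cohort, "gte"))
        small = ap.toplist_overlap(ase, gte, k_ase=200, k_gte=50)
        large = ap.toplist_overlap(ase, gte, k_ase=200, k_gte=200)
        # the top GTE hits are overwhelmingly rediscovered by ASE
        assert small.overlap_percent > 50.0
        assert large.n_overlap >= small.n_overlap


class TestMafCurve:
    def test_bin_arithmetic(self):
        rec = _toy_records([
            ("s1", "t1", 1e-9, 0.001, 0.001, 0.237, 0, 0),
            ("s2", "t1", 0.9, 1.0, 1.0, 0.5, 0, 0),
        ])
        curve = ap.maf_power_curve(rec)
        assert curve.loc[23, "tested"] == 1 and curve.loc[23, "significant"] == 1
        assert curve.loc[49, "tested"] == 1  # MAF exactly 0.5 in last bin

    def test_all_significant_fractions_one(self):
        rec = _toy_records(
            [(f"s{i}", "t1", 1e-9, 0.001, 0.001, m, 0, 0)
             for i, m in enumerate((0.05, 0.15, 0.25))]
        )
        curve = ap.maf_power_curve(rec)
        nonempty = curve["tested"] > 0
        assert (curve.loc[nonempty, "fraction"] == 1.0).all()

    def test_empty_bins_excluded_from_smoothing(self):
        rec = _toy_records([("s1", "t1", 1e-9, 0.001, 0.001, 0.25, 0, 0)])
        curve = ap.maf_power_curve(rec)
        assert np.isnan(curve.loc[10, "fraction"])
        # bins within the window of the single datum inherit its value
        assert curve.loc[24, "sliding_fraction"] == 1.0

    def test_gte_detection_rises_with_maf(self, headline_cohort):
        """Equal effects across MAF: the GTE detected fraction grows with MAF."""
        rec = ap.add_corrections(ap.run_scan(headline_cohort, "gte"))
        curve = ap.maf_power_curve(rec)
        lo = curve.loc[2:14, "fraction"].mean()
        hi = curve.loc[30:49, "fraction"].mean()
        assert hi > 2 * lo

    def test_ase_insensitive_to_low_maf(self, headline_cohort):
        """ASE detects a larger fraction of low-MAF (<15%) rSNPs than GTE."""
        curves = {}
        for m in ("ase", "gte"):
            rec = ap.add_corrections(ap.run_scan(headline_cohort, m))
            curves[m] = ap.maf_power_curve(rec)
        ase_lo = curves["ase"].loc[0:14, "fraction"].mean()
        gte_lo = curves["gte"].loc[0:14, "fraction"].mean()
        assert ase_lo > gte_lo


class TestPositionalEnrichment:
    def test_bin_convention_plus_strand(self):
        rec = _toy_records([("s1", "t1", 1e-9, 0.001, 0.001, 0.3, -1500, -12_000)])
        tab = ap.positional_enrichment(rec)
        assert tab[(tab.anchor == "tss")]["bin"].iloc[0] == -2
        assert tab[(tab.anchor == "tts")]["bin"].iloc[0] == -12

    def test_fraction_counts(self):
        rec = _toy_records([
            ("s1", "t1", 1e-9, 0.001, 0.001, 0.3, 500, 0),
            ("s2", "t1", 0.9, 1.0, 1.0, 0.3, 700, 0),
        ])
        tab = ap.positional_enrichment(rec)
        tss0 = tab[(tab.anchor == "tss") & (tab.bin == 0)].iloc[0]
        assert tss0["tested"] == 2 and tss0["significant"] == 1
        assert tss0["fraction"] == pytest.approx(0.5)

    def test_strand_orientation_from_scan(self, small_cohort):
        """Upstream SNPs get negative TSS distances on both strands."""
        rec = ap.run_scan(small_cohort, "ase")
        tx = small_cohort.transcripts.set_index("transcript")
        merged = rec.join(tx[["start", "end", "strand"]], on="transcript")
        plus = merged[merged.strand == "+"]
        minus = merged[merged.strand == "-"]
        assert ((plus.pos < plus.start) == (plus.dist_tss < 0)).all()
        assert ((minus.pos > minus.end - 1) == (minus.dist_tss < 0)).all()

    def test_enrichment_peaks_in_causal_bins(self):
        """Signal localizes: bins holding true causal SNPs are enriched."""
        cfg = ap.SimulationConfig(
            n_samples=150, n_transcripts=60, causal_fraction=1.0,
            maf_range=(0.2, 0.5), seed=61,
        )
        cohort = ap.simulate_cohort(cfg)
        rec = ap.add_corrections(ap.run_scan(cohort, "ase"))
        tab = ap.positional_enrichment(rec)
        causal = set(cohort.truth.table["causal_snp"]) - {""}
        causal_bins = set(
            np.floor(
                rec.loc[rec["snp"].isin(causal), "dist_tss"].to_numpy() / 1000
            ).astype(int)
        )
        tss = tab[tab.anchor == "tss"]
        inside = tss[tss["bin"].isin(causal_bins)]["fraction"].mean()
        outside = tss[~tss["bin"].isin(causal_bins)]["fraction"].mean()
        assert inside > outside
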