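"""Synthetic-cohort generator: determinism, distributional and closed-form checks."""

import numpy as np
import pytest
from scipy import stats

import plasmacna as pc
from plasmacna.synthetic import (
    SimTruth, TruthCna, _gc_bias_curve, simulate_array_profile,
    simulate_clinical_cohort, simulate_donor_counts, simulate_gc_track,
    simulate_plasma_counts, simulate_tumor_truth,
)


class TestGcTrack:
    def test_deterministic_and_bounded(self, layout):
        a = simulate_gc_track(layout, seed=5)
        b = simulate_gc_track(layout, seed=5)
        np.testing.assert_array_equal(a, b)
        assert len(a) == layout.n_bins
        assert a.min() >= 0.3 and a.max() <= 0.7

    def test_seeds_differ(self, layout):
        a = simulate_gc_track(layout, seed=1)
        b = simulate_gc_track(layout, seed=2)
        assert np.any(a != b)

    def test_spatial_autocorrelation(self, layout):
        gc = simulate_gc_track(layout, seed=3)
        lag1 = np.corrcoef(gc[:-1], gc[1:])[0, 1]
        assert lag1 > 0.5


class TestDonorCounts:
    def test_poisson_limit_no_bias(self, layout, gc_track):
        prof = simulate_donor_counts(
            layout, gc_track, seed=1, mean_depth=30, gc_bias_amplitude=0, dispersion=0
        )
        n = layout.n_bins
        se = np.sqrt(30 / n)
        assert abs(prof.raw_counts.mean() - 30) < 3 * se
        # Poisson: variance ~= mean
        assert abs(prof.raw_counts.var() / 30 - 1) < 0.15

    def test_total_count_law_of_large_numbers(self, layout, gc_track):
        expected = 30 * layout.n_bins
        for seed in range(10):
            prof = simulate_donor_counts(layout, gc_track, seed=seed, mean_depth=30)
            assert abs(prof.raw_counts.sum() - expected) / expected < 0.05

    def test_gc_bias_induces_count_correlation(self, layout, gc_track):
        prof = simulate_donor_counts(
            layout, gc_track, seed=2, mean_depth=30, gc_bias_amplitude=0.8, dispersion=0
        )
        curve = _gc_bias_curve(gc_track, 0.8)
        rho, p = stats.spearmanr(prof.raw_counts, curve)
        assert rho > 0.2 and p < 1e-6

    def test_invalid_mean_depth(self, layout, gc_track):
        with pytest.raises(ValueError):
            simulate_donor_counts(layout, gc_track, seed=0, mean_depth=0)


class TestTumorTruth:
    def test_zero_cnas_allowed(self, layout):
        truth = simulate_tumor_truth(layout, 0, seed=0)
        assert truth.tumor_cnas == ()

    def test_twenty_disjoint_regions(self, layout):
        truth = simulate_tumor_truth(layout, 20, seed=1)
        cnas = sorted(truth.tumor_cnas, key=lambda c: (c.chrom, c.start))
        assert len(cnas) == 20
        for a, b in zip(cnas, cnas[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_deterministic(self, layout):
        assert simulate_tumor_truth(layout, 6, seed=7) == simulate_tumor_truth(layout, 6, seed=7)

    def test_unplaceable_request_errors(self):
        tiny = pc.toy_layout(1, 10_000_000)
        with pytest.raises(RuntimeError):
            simulate_tumor_truth(tiny, 50, seed=0, size_range=(5_000_000, 9_000_000))

    def test_overlapping_truth_rejected(self):
        with pytest.raises(ValueError):
            SimTruth(
                (TruthCna("chr1", 0, 10_000_000, 3), TruthCna("chr1", 5_000_000, 15_000_000, 1)),
                0.1, 0,
            )


class TestArrayProfile:
    def test_noiseless_closed_forms(self, layout):
        truth = SimTruth(
            (TruthCna("chr1", 0, 20_000_000, 3), TruthCna("chr2", 0, 20_000_000, 1)),
            0.1, 0,
        )
        log2 = simulate_array_profile(truth, layout, seed=0, noise_sd=0)
        gain_idx = layout.region_bin_indices("chr1", 0, 20_000_000)
        loss_idx = layout.region_bin_indices("chr2", 0, 20_000_000)
        np.testing.assert_allclose(log2[gain_idx], np.log2(1.5))
        np.testing.assert_allclose(log2[loss_idx], -1.0)
        outside = np.setdiff1d(np.arange(layout.n_bins), np.r_[gain_idx, loss_idx])
        assert np.all(log2[outside] == 0)

    def test_noisy_region_mean_clt(self, layout):
        truth = SimTruth((TruthCna("chr3", 0, 50_000_000, 3),), 0.1, 0)
        log2 = simulate_array_profile(truth, layout, seed=1, noise_sd=0.1)
        idx = layout.region_bin_indices("chr3", 0, 50_000_000)
        assert abs(log2[idx].mean() - np.log2(1.5)) < 3 * 0.1 / np.sqrt(len(idx))


class TestPlasmaCounts:
    def test_zero_tumor_fraction_reproduces_donor_model(self, layout, gc_track):
        truth = simulate_tumor_truth(layout, 4, seed=2, tumor_fraction=0.0)
        plasma = simulate_plasma_counts(layout, gc_track, truth, seed=9)
        donor = simulate_donor_counts(layout, gc_track, seed=9)
        np.testing.assert_array_equal(plasma.raw_counts, donor.raw_counts)

    def test_pure_tumor_copy4_doubles_expectation(self, layout, gc_track):
        truth = SimTruth((TruthCna("chr1", 0, 100_000_000, 4),), 1.0, 0)
        idx = layout.region_bin_indices("chr1", 0, 100_000_000)
        means = []
        for seed in range(20):
            p = simulate_plasma_counts(
                layout, gc_track, truth, seed=seed,
                gc_bias_amplitude=0, dispersion=0,
            )
            means.append(p.raw_counts[idx].mean())
        # expectation 60 in region; SE of the 20-rep mean ~ sqrt(60/(100*20))
        assert abs(np.mean(means) - 60.0) < 3 * np.sqrt(60 / (len(idx) * 20))

    def test_admixture_elevates_region_total(self, layout, gc_track):
        truth = SimTruth((TruthCna("chr1", 0, 200_000_000, 3),), 0.05, 0)
        idx = layout.region_bin_indices("chr1", 0, 200_000_000)
        totals = []
        for seed in range(20):
            p = simulate_plasma_counts(
                layout, gc_track, truth, seed=seed, gc_bias_amplitude=0, dispersion=0
            )
            totals.append(p.raw_counts[idx].sum())
        expected = 30 * len(idx) * 1.025
        se = np.sqrt(expected / 20)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_tumor_fraction_out_of_range(self, layout, gc_track):
        truth = simulate_tumor_truth(layout, 1, seed=0)
        with pytest.raises(ValueError):
            simulate_plasma_counts(layout, gc_track, truth, seed=0, tumor_fraction=1.5)

    def test_admixture_linearity_in_log2(self, layout, gc_track, donor_profiles):
        """Average plasma log2 in the CNA region tracks log2(1 + tf*(c/2-1)),
        after the depth-normalization shift (the elevated region inflates the
        sample total) and relative to the panel's own regional mean."""
        panel = pc.build_panel(donor_profiles)
        region = TruthCna("chr1", 50_000_000, 150_000_000, 3)
        idx = layout.region_bin_indices("chr1", 50_000_000, 150_000_000)
        panel_regional = np.nanmean(panel.mean_log2[idx])
        n_usable = int(panel.mask.sum())
        for tf in (0.1, 0.3):
            truth = SimTruth((region,), tf, 0)
            means = []
            for seed in range(20):
                p = simulate_plasma_counts(layout, gc_track, truth, seed=3000 + seed)
                pc.to_log2_ratio(p, panel)
                means.append(np.nanmean(p.log2_ratio[idx]) - panel_regional)
            total_inflation = 1 + len(idx) * tf * 0.5 / n_usable
            expected = np.log2((1 + tf * 0.5) / total_inflation)
            assert abs(np.mean(means) - expected) < 0.02


class TestClinicalCohort:
    def test_degenerate_draw_hits_means(self):
        df = simulate_clinical_cohort(seed=0, ldh_sds=(0, 0), age_sds=(0, 0))
        lm = df[df.diagnosis == "LM"]
        assert (lm.ldh == 191.0).all() and (lm.age == 48.0).all()
        lms = df[df.diagnosis == "LMS"]
        assert (lms.ldh == 288.0).all() and (lms.age == 54.0).all()

    def test_cohort_sizes_and_labels(self):
        df = simulate_clinical_cohort(seed=1, n_lm=9, n_lms=8)
        assert len(df) == 17
        assert (df.diagnosis.value_counts()["LM"], df.diagnosis.value_counts()["LMS"]) == (9, 8)
        assert (df.ldh > 0).all() and (df.age > 0).all()

    def test_deterministic(self):
        a = simulate_clinical_cohort(seed=4)
        b = simulate_clinical_cohort(seed=4)
        assert a.equals(b)
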