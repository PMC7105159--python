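"""Tumor-informed plasma detection: intersection, rules, burden, specificity."""

import numpy as np
import pytest

import plasmacna as pc
from plasmacna.detection import (
    analytic_null_specificity, detect_patient, donor_specificity,
    evaluate_cna_in_plasma, intersect_regions, percent_genome_altered,
    tumor_plasma_agreement, DetectionRecord,
)
from plasmacna.segmentation import Segment
from plasmacna.synthetic import SimTruth, TruthCna, simulate_plasma_counts
from plasmacna.tumor import CnaCall

MB = 1_000_000


def _record(chrom, start, end, detected, z=2.0, kind="gain", pid="p"):
    cna = CnaCall(chrom, start, end, kind, 0.5 if kind == "gain" else -0.5)
    return DetectionRecord(pid, cna, z, 0.1, (end - start) // MB, True, detected)


class TestIntersectRegions:
    def test_disjoint_inputs_empty(self):
        cnas = [CnaCall("chr1", 0, 10, "gain", 0.5)]
        segs = [Segment("chr2", 0, 10, 1, 0.0)]
        assert intersect_regions(cnas, segs).empty

    def test_overlap_arithmetic(self):
        cnas = [CnaCall("chr1", 10, 20, "gain", 0.5)]
        segs = [Segment("chr1", 15, 30, 15, 0.2)]
        df = intersect_regions(cnas, segs)
        assert len(df) == 1 and df.overlap_bp.iloc[0] == 5
        assert df.overlap_fraction.iloc[0] == pytest.approx(0.5)

    def test_cna_spanning_two_segments_conserves_length(self):
        cnas = [CnaCall("chr1", 10, 50, "loss", -0.5)]
        segs = [Segment("chr1", 0, 30, 30, -0.4), Segment("chr1", 30, 80, 50, 0.0)]
        df = intersect_regions(cnas, segs)
        assert len(df) == 2
        assert df.overlap_bp.sum() == 40


class TestEvaluateCna:
    def test_direction_mismatch_blocks_detection(self, layout, gc_track, panel):
        # tumor says gain, but plasma carries a strong loss at that region
        region = TruthCna("chr8", 0, 80 * MB, 1)
        truth = SimTruth((region,), 0.4, 0)
        plasma = simulate_plasma_counts(layout, gc_track, truth, seed=5)
        gain_claim = CnaCall("chr8", 0, 80 * MB, "gain", 0.58)
        rec = evaluate_cna_in_plasma(gain_claim, plasma, panel)
        assert abs(rec.plasma_z) > 1.5
        assert not rec.direction_match and not rec.detected

    def test_strong_spike_detected(self, layout, gc_track, panel):
        region = TruthCna("chr9", 0, 100 * MB, 3)
        truth = SimTruth((region,), 0.3, 0)
        for seed in range(20):
            plasma = simulate_plasma_counts(layout, gc_track, truth, seed=600 + seed)
            rec = evaluate_cna_in_plasma(region.to_cna_call(), plasma, panel)
            assert rec.detected

    def test_invalid_z_cut(self, layout, gc_track, panel):
        plasma = pc.synthetic.simulate_donor_counts(layout, gc_track, seed=0)
        with pytest.raises(ValueError):
            evaluate_cna_in_plasma(CnaCall("chr1", 0, MB, "gain", 0.5), plasma, panel, z_cut=0)


class TestDetectPatient:
    def test_no_cnas_means_undetectable(self, layout, gc_track, panel):
        plasma = pc.synthetic.simulate_donor_counts(layout, gc_track, seed=1)
        records, flag = detect_patient([], plasma, panel)
        assert records == [] and flag is False

    def test_any_rule(self, layout, gc_track, panel):
        spike = TruthCna("chr4", 0, 120 * MB, 3)
        truth = SimTruth((spike,), 0.3, 0)
        plasma = simulate_plasma_counts(layout, gc_track, truth, seed=8)
        cnas = [
            spike.to_cna_call(),
            CnaCall("chr10", 0, 30 * MB, "gain", 0.3),
            CnaCall("chr11", 0, 30 * MB, "loss", -0.3),
        ]
        records, flag = detect_patient(cnas, plasma, panel)
        assert flag and records[0].detected

    def test_infinite_cutoff_never_detects(self, layout, gc_track, panel):
        spike = TruthCna("chr4", 0, 120 * MB, 3)
        truth = SimTruth((spike,), 0.5, 0)
        plasma = simulate_plasma_counts(layout, gc_track, truth, seed=9)
        _, flag = detect_patient([spike.to_cna_call()], plasma, panel, z_cut=np.inf)
        assert flag is False

    def test_detection_probability_monotone_in_tumor_fraction(self, layout, gc_track, panel):
        region = TruthCna("chr2", 0, 100 * MB, 3)
        cna = region.to_cna_call()
        rates = []
        for tf in (0.0, 0.05, 0.2):
            truth = SimTruth((region,), tf, 0)
            hits = 0
            for seed in range(30):
                plasma = simulate_plasma_counts(layout, gc_track, truth, seed=7000 + seed)
                hits += evaluate_cna_in_plasma(cna, plasma, panel).detected
            rates.append(hits / 30)
        assert rates == sorted(rates)


class TestPercentGenomeAltered:
    def test_no_detection_gives_zero(self, layout):
        recs = [_record("chr1", 0, 10 * MB, False)]
        assert percent_genome_altered(recs, layout).pct_genome_altered == 0.0

    def test_single_region_arithmetic(self):
        lay = pc.GenomeLayout((("chr1", 3_000 * MB),), MB)
        recs = [_record("chr1", 0, 30 * MB, True)]
        assert percent_genome_altered(recs, lay).pct_genome_altered == pytest.approx(1.0)

    def test_overlapping_regions_not_double_counted(self):
        lay = pc.GenomeLayout((("chr1", 1_000 * MB),), MB)
        recs = [
            _record("chr1", 0, 30 * MB, True),
            _record("chr1", 20 * MB, 50 * MB, True),
        ]
        assert percent_genome_altered(recs, lay).pct_genome_altered == pytest.approx(5.0)

    def test_matches_brute_force_union(self, layout):
        """pyranges-based union equals a brute-force boolean-array union."""
        rng = np.random.default_rng(4)
        recs = []
        covered = {c: np.zeros(layout.lengths[c] // MB, dtype=bool) for c, _ in layout.chromosomes}
        for _ in range(20):
            chrom = str(rng.choice(layout.chrom_names[:5]))
            n = layout.lengths[chrom] // MB
            a = int(rng.integers(0, n - 10))
            b = a + int(rng.integers(1, 10))
            detected = bool(rng.random() < 0.7)
            recs.append(_record(chrom, a * MB, b * MB, detected))
            if detected:
                covered[chrom][a:b] = True
        expected = 100.0 * sum(v.sum() for v in covered.values()) * MB / layout.total_length
        got = percent_genome_altered(recs, layout).pct_genome_altered
        assert got == pytest.approx(expected)

    def test_invariant_to_record_order(self, layout):
        recs = [
            _record("chr1", 0, 10 * MB, True),
            _record("chr2", 5 * MB, 25 * MB, True),
        ]
        a = percent_genome_altered(recs, layout).pct_genome_altered
        b = percent_genome_altered(recs[::-1], layout).pct_genome_altered
        assert a == b


class TestDonorSpecificity:
    QUERIES = [
        CnaCall("chr1", 0, 40 * MB, "gain", 0.5),
        CnaCall("chr5", 10 * MB, 60 * MB, "loss", -0.5),
        CnaCall("chr12", 0, 30 * MB, "gain", 0.4),
    ]

    def test_infinite_cutoff_perfect_specificity(self, donor_profiles):
        donors = donor_profiles[:8]
        tn, n, frac = donor_specificity(donors, self.QUERIES, z_cut=np.inf)
        assert (tn, n, frac) == (8, 8, 1.0)

    def test_no_query_regions_trivially_specific(self, donor_profiles):
        tn, n, frac = donor_specificity(donor_profiles[:4], [])
        assert frac == 1.0

    def test_monotone_in_z_cut(self, donor_profiles):
        donors = donor_profiles[:10]
        _, _, loose = donor_specificity(donors, self.QUERIES, z_cut=1.0)
        _, _, tight = donor_specificity(donors, self.QUERIES, z_cut=2.5)
        assert tight >= loose


class TestTumorPlasmaAgreement:
    def test_collinear_points_r2_one(self):
        recs = [
            _record("chr1", 0, 10 * MB, True, z=1.0),
            _record("chr2", 0, 10 * MB, True, z=2.0),
            _record("chr3", 0, 10 * MB, True, z=3.0),
        ]
        for r, x in zip(recs, (0.2, 0.4, 0.6)):
            r.cna = CnaCall(r.cna.chrom, r.cna.start, r.cna.end, "gain", x)
        fit = tumor_plasma_agreement(recs)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(5.0)

    def test_two_points_degenerate_warns(self):
        recs = [_record("chr1", 0, MB, True, z=1.0), _record("chr2", 0, MB, True, z=2.5)]
        recs[1].cna = CnaCall("chr2", 0, MB, "gain", 0.9)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = tumor_plasma_agreement(recs)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            tumor_plasma_agreement([_record("chr1", 0, MB, True)])

    def test_simulated_cohort_positive_slope(self, layout, gc_track, panel):
        records = []
        for seed in range(6):
            truth = pc.synthetic.simulate_tumor_truth(layout, 3, seed=seed, tumor_fraction=0.25)
            plasma = simulate_plasma_counts(layout, gc_track, truth, seed=900 + seed)
            recs, _ = detect_patient([c.to_cna_call() for c in truth.tumor_cnas], plasma, panel)
            records.extend(recs)
        fit = tumor_plasma_agreement(records)
        assert fit["slope"] > 0 and fit["n"] >= 15


def test_analytic_null_specificity_values():
    # one-region null tail at z=1.5 against a 25-donor panel is ~7.7%
    one = analytic_null_specificity(1, 25)
    assert 1 - one == pytest.approx(0.0772, abs=0.002)
    eleven = analytic_null_specificity(11, 25)
    assert eleven == pytest.approx(one**11, rel=1e-9)
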