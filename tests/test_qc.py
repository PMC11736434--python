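import numpy as np
import pandas as pd
import pytest

from apakit import discovery, qc
from apakit.simulate import SimConfig, generate_reference, simulate_tags


def peak_row(peak_id="P1", edge3=500, strand="+", region="utr3", chrom="chr1"):
    return dict(peak_id=peak_id, gene_id="G1", region_class=region, chrom=chrom,
                start=edge3 - 49, end=edge3 + 1, strand=strand, edge3=edge3)


def flat_genome(n=2000, base="C"):
    return {"chr1": base * n}


class TestFilterPeaks:
    def test_a_run_downstream_removes_utr_peak(self):
        genome = {"chr1": "C" * 521 + "A" * 8 + "C" * 500}  # run starts +21
        peaks = pd.DataFrame([peak_row()])
        cpm = pd.DataFrame({"c1": [100.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, genome, "utr3")
        assert len(rep.surviving) == 0
        assert rep.removed_by_rule["internal_priming"] == 1

    def test_a_run_outside_window_kept(self):
        genome = {"chr1": "C" * 701 + "A" * 8 + "C" * 500}  # run starts +201
        peaks = pd.DataFrame([peak_row()])
        cpm = pd.DataFrame({"c1": [100.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, genome, "utr3")
        assert len(rep.surviving) == 1

    def test_seven_a_not_enough_for_utr(self):
        genome = {"chr1": "C" * 521 + "A" * 7 + "C" * 500}
        peaks = pd.DataFrame([peak_row()])
        cpm = pd.DataFrame({"c1": [100.0]}, index=["P1"])
        assert len(qc.filter_peaks(peaks, cpm, genome, "utr3").surviving) == 1

    def test_cpm_boundary_exact(self):
        # summed CPM 9.5 removed; exactly 10.0 retained ("<10" rule)
        peaks = pd.DataFrame([peak_row("P1"), peak_row("P2", edge3=1000)])
        cpm = pd.DataFrame({"c1": [4.5, 5.0], "c2": [5.0, 5.0]},
                           index=["P1", "P2"])
        rep = qc.filter_peaks(peaks, cpm, flat_genome(), "utr3")
        assert list(rep.surviving["peak_id"]) == ["P2"]
        assert rep.removed_by_rule["low_total_cpm"] == 1

    def test_intron_rules_counted_once_per_rule(self):
        # CPM 4.9 in one cluster AND A7 at +150 -> both tallies increment
        genome = {"chr1": "C" * 650 + "A" * 7 + "C" * 500}  # run starts +150
        peaks = pd.DataFrame([peak_row(region="intron")])
        cpm = pd.DataFrame({"c1": [4.9], "c2": [100.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, genome, "intron")
        assert len(rep.surviving) == 0
        assert rep.removed_by_rule["low_cluster_cpm"] == 1
        assert rep.removed_by_rule["internal_priming"] == 1

    def test_intron_a_window_starts_at_one(self):
        genome = {"chr1": "C" * 501 + "A" * 7 + "C" * 500}  # run starts +1
        peaks = pd.DataFrame([peak_row(region="intron")])
        cpm = pd.DataFrame({"c1": [50.0], "c2": [50.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, genome, "intron")
        assert len(rep.surviving) == 0

    def test_minus_strand_downstream_window(self):
        # minus strand: downstream = decreasing coords, sense A = ref T
        seq = "G" * 500
        edge3 = 400
        run = "T" * 8  # sense AAAAAAAA at offsets 21..28 downstream
        genome = {"chr1": seq[: edge3 - 28] + run + seq[edge3 - 20 :]}
        peaks = pd.DataFrame([peak_row(edge3=edge3, strand="-")])
        cpm = pd.DataFrame({"c1": [100.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, genome, "utr3")
        assert len(rep.surviving) == 0

    def test_window_truncated_at_chromosome_end(self):
        peaks = pd.DataFrame([peak_row(edge3=1995)])
        cpm = pd.DataFrame({"c1": [100.0]}, index=["P1"])
        rep = qc.filter_peaks(peaks, cpm, flat_genome(), "utr3")  # no error
        assert rep.n_input == 1

    def test_idempotence(self, pipeline_result, sim_bundle):
        genome, _, _, _ = sim_bundle
        res = pipeline_result
        again = qc.filter_peaks(res.utr_filter.surviving, res.counts.cpm,
                                genome, "utr3")
        assert len(again.removed) == 0

    def test_order_insensitivity(self, pipeline_result, sim_bundle):
        genome, _, _, _ = sim_bundle
        peaks = pipeline_result.peaks
        cpm = pipeline_result.counts.cpm
        fwd = qc.filter_peaks(peaks, cpm, genome, "utr3")
        rev = qc.filter_peaks(peaks.iloc[::-1], cpm, genome, "utr3")
        assert fwd.removed_by_rule == rev.removed_by_rule
        assert set(fwd.surviving["peak_id"]) == set(rev.surviving["peak_id"])

    def test_artifact_recovery_on_simulation(self, pipeline_result, sim_bundle):
        # 100% of planted artifact peaks removed, >= 95% true peaks survive
        genome, _, truth, _ = sim_bundle
        res = pipeline_result
        art_sites = truth.sites[truth.sites["kind"] == "artifact"]
        utr_sites = truth.sites[truth.sites["kind"] == "utr3"]

        def nearest_kind(edge3):
            d_art = (art_sites["pos3"] - edge3).abs().min() if len(art_sites) else 1e9
            d_true = (utr_sites["pos3"] - edge3).abs().min()
            return "artifact" if d_art < d_true else "true"

        utr_peaks = res.peaks[res.peaks["region_class"] == "utr3"]
        surviving_ids = set(res.utr_filter.surviving["peak_id"])
        n_art = n_art_removed = n_true = n_true_kept = 0
        for _, pk in utr_peaks.iterrows():
            kind = nearest_kind(pk["edge3"])
            if kind == "artifact":
                n_art += 1
                n_art_removed += pk["peak_id"] not in surviving_ids
            else:
                n_true += 1
                n_true_kept += pk["peak_id"] in surviving_ids
        assert n_art >= 3
        assert n_art_removed == n_art
        assert n_true_kept / n_true >= 0.95


class TestScanPolyaSignals:
    def test_planted_signal_histogram_mode(self):
        # with zero jitter the peak edge equals the cleavage site, so the
        # planted motif end sits exactly signal_offset nt upstream
        cfg = SimConfig(seed=17, n_genes=40, jitter_sd=0.0, artifact_rate=0.0)
        genome, ann, truth = generate_reference(cfg)
        tags = simulate_tags(genome, ann, truth, cfg)
        called = discovery.call_peaks(tags, ann)
        peaks, _ = discovery.build_count_matrices(called, tags)
        profiles = qc.scan_polya_signals(peaks[peaks["region_class"] == "utr3"], genome)
        assert profiles["AATAAA"].mode_offset() == -21

    def test_no_signal_no_flag(self):
        peaks = pd.DataFrame([peak_row()])
        profiles = qc.scan_polya_signals(peaks, flat_genome())
        assert not profiles["AATAAA"].per_peak["P1"]
        assert profiles["AATAAA"].offsets.size == 0

    def test_plus_strand_offset_arithmetic(self):
        # AATAAA ending exactly at offset -21 from edge3=500
        seq = list("C" * 1000)
        seq[474:480] = "AATAAA"  # end index 479 -> offset 479-500 = -21
        peaks = pd.DataFrame([peak_row()])
        profiles = qc.scan_polya_signals(peaks, {"chr1": "".join(seq)})
        assert list(profiles["AATAAA"].offsets) == [-21]
        assert profiles["AATAAA"].per_peak["P1"]

    def test_minus_strand_offset_arithmetic(self):
        # sense AATAAA ending 21 nt upstream of edge3 on '-' strand
        seq = list("C" * 1000)
        seq[521:527] = "TTTATT"  # revcomp(AATAAA) at genomic [521,527)
        peaks = pd.DataFrame([peak_row(edge3=500, strand="-")])
        profiles = qc.scan_polya_signals(peaks, {"chr1": "".join(seq)})
        assert list(profiles["AATAAA"].offsets) == [-21]

    def test_offsets_respect_window(self, sim_bundle, pipeline_result):
        genome, _, _, _ = sim_bundle
        profiles = qc.scan_polya_signals(pipeline_result.peaks, genome,
                                         upstream=30, downstream=150)
        for prof in profiles.values():
            if prof.offsets.size:
                assert prof.offsets.min() >= -30
                assert prof.offsets.max() <= 150

    def test_canonical_fraction_matches_planting(self, sim_bundle):
        # every true PAS has a planted signal -> fraction ~ 1.0 at n >= 200
        cfg = SimConfig(seed=31, n_genes=120, artifact_rate=0.0,
                        cells_per_cluster=30, jitter_sd=2.0)
        genome, ann, truth = generate_reference(cfg)
        tags = simulate_tags(genome, ann, truth, cfg)
        called = discovery.call_peaks(tags, ann)
        peaks, _ = discovery.build_count_matrices(called, tags)
        utr = peaks[peaks["region_class"] == "utr3"]
        assert len(utr) >= 200
        profiles = qc.scan_polya_signals(utr, genome)
        frac = profiles["AATAAA"].per_peak.mean()
        assert frac == pytest.approx(1.0, abs=0.05)

    def test_empty_peak_list_gives_empty_profile(self):
        peaks = pd.DataFrame(columns=["peak_id", "chrom", "strand", "edge3"])
        profiles = qc.scan_polya_signals(peaks, flat_genome())
        assert all(p.offsets.size == 0 for p in profiles.values())


class TestCompareSignalDensity:
    def test_identical_samples(self):
        offs = np.array([-50, -21, 0, 30])
        d, p = qc.compare_signal_density(offs, offs)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = qc.compare_signal_density(np.array([-90, -80, -70]),
                                         np.array([50, 60, 70]))
        assert d == 1.0

    def test_window_restriction_applied(self):
        a = np.array([-21, -500, 900])  # outliers fall outside +/-100
        d, _ = qc.compare_signal_density(a, np.array([-21]))
        assert d == 0.0

    def test_empty_after_window_rejected(self):
        with pytest.raises(ValueError):
            qc.compare_signal_density(np.array([500]), np.array([-21]))

    def test_null_calibration(self):
        # same planted distribution, n=500 each: rejection at 5% +/- 2%
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(-20, 15, size=500).round()
            b = rng.normal(-20, 15, size=500).round()
            _, p = qc.compare_signal_density(a, b)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestBenchmarkKnownPas:
    def test_distance_and_threshold(self):
        peaks = pd.DataFrame([peak_row(edge3=1000)])
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [1050], "strand": ["+"]})
        res = qc.benchmark_known_pas(peaks, known, threshold=100)
        assert res.distances["P1"] == -50
        assert res.fraction_within == 1.0

    def test_truth_sites_zero_jitter_all_within(self):
        cfg = SimConfig(seed=13, n_genes=20, jitter_sd=0.0, artifact_rate=0.0)
        genome, ann, truth = generate_reference(cfg)
        tags = simulate_tags(genome, ann, truth, cfg)
        called = discovery.call_peaks(tags, ann)
        peaks, _ = discovery.build_count_matrices(called, tags)
        known = truth.sites[truth.sites["kind"] == "utr3"].rename(
            columns={"pos3": "pos"})[["chrom", "pos", "strand"]]
        res = qc.benchmark_known_pas(peaks[peaks["region_class"] == "utr3"], known)
        assert res.fraction_within == 1.0

    def test_empty_known_set_rejected(self):
        peaks = pd.DataFrame([peak_row()])
        with pytest.raises(ValueError):
            qc.benchmark_known_pas(peaks, pd.DataFrame())

    def test_strand_matching(self):
        peaks = pd.DataFrame([peak_row(edge3=1000)])
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "strand": ["-"]})
        res = qc.benchmark_known_pas(peaks, known)
        assert np.isnan(res.distances["P1"])

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        L = 10_000
        edges = rng.integers(100, L - 100, size=30)
        sites = rng.integers(100, L - 100, size=50)
        peaks = pd.DataFrame([peak_row(f"P{i}", e) for i, e in enumerate(edges)])
        known = pd.DataFrame({"chrom": "chr1", "pos": sites, "strand": "+"})
        fwd = qc.benchmark_known_pas(peaks, known)
        m_peaks = peaks.assign(edge3=L - 1 - peaks["edge3"], strand="-")
        m_known = known.assign(pos=L - 1 - known["pos"], strand="-")
        rev = qc.benchmark_known_pas(m_peaks, m_known)
        assert np.allclose(np.abs(fwd.distances), np.abs(rev.distances))
        assert fwd.fraction_within == rev.fraction_within
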