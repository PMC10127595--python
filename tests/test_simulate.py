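"""Synthetic genome, read-set and count-table generators."""

import numpy as np
import pytest

import prophagemap as pm
from prophagemap.simulate import _CONTAMINANT_LEN

from conftest import coverage_from_truth


class TestSimulateGenome:
    def test_planted_prophage_has_requested_length(self, prophage_genome):
        (p,) = prophage_genome.prophages
        assert (p.start, p.end) == (100_000, 144_597)
        assert p.length == 44_597

    def test_no_specs_gives_empty_truth(self):
        g = pm.simulate_genome(50_000, seed=0)
        assert g.prophages == [] and g.is_copies == []

    def test_gc_content_matches_request(self):
        g = pm.simulate_genome(1_000_000, gc=0.635, seed=3)
        seq = g.replicons[0].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.635) < 0.005

    def test_overlapping_prophages_rejected_with_intervals_named(self):
        specs = [
            pm.PlantedProphage(10_000, 20_000, core_rate=100.0),
            pm.PlantedProphage(15_000, 30_000, core_rate=100.0),
        ]
        with pytest.raises(ValueError, match=r"\[10000, 20000\).*\[15000, 30000\)"):
            pm.simulate_genome(50_000, prophage_specs=specs, seed=0)

    def test_spec_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pm.simulate_genome(
                20_000, prophage_specs=[pm.PlantedProphage(15_000, 25_000, core_rate=10.0)]
            )
        with pytest.raises(ValueError, match="exceeds"):
            pm.simulate_genome(20_000, is_specs=[pm.ISSpec(19_500, "IS21", 1000)])

    def test_is_family_copies_identical(self):
        g = pm.simulate_genome(
            30_000,
            is_specs=[pm.ISSpec(1000, "IS66", 800), pm.ISSpec(9000, "IS66", 800),
                      pm.ISSpec(20_000, "IS21", 700)],
            seed=5,
        )
        seqs = g.is_sequences()
        s = g.replicons[0].sequence
        assert s[1000:1800] == s[9000:9800] == seqs["IS66"]
        assert s[20_000:20_700] == seqs["IS21"]
        assert s[1000:1800] != s[20_000:20_800]

    def test_seed_determinism_genome_and_fastq(self, tmp_path):
        from prophagemap.io import write_fastq

        g1 = pm.simulate_genome(20_000, seed=9)
        g2 = pm.simulate_genome(20_000, seed=9)
        assert g1.replicons[0].sequence == g2.replicons[0].sequence
        params = pm.ReadSimParams(background_rate=5.0, error_rate=0.01, seed=4)
        paths = []
        for tag in ("a", "b"):
            rs = pm.simulate_phage_reads(g1, params)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(rs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSimulatePhageReads:
    def test_read_count_matches_poisson_mean(self):
        g = pm.simulate_genome(
            30_000, prophage_specs=[pm.PlantedProphage(10_000, 20_000, core_rate=1000.0)], seed=1
        )
        params = pm.ReadSimParams(read_length=100, background_rate=0.0, seed=2)
        rs = pm.simulate_phage_reads(g, params)
        expected = 1000.0 * 10_000 / 100  # 100,000
        assert abs(len(rs) - expected) < 3 * np.sqrt(expected)

    def test_no_contaminants_when_fraction_zero(self):
        g = pm.simulate_genome(20_000, seed=1)
        rs = pm.simulate_phage_reads(g, pm.ReadSimParams(background_rate=5.0, seed=3))
        assert rs.label_counts().get("contaminant", 0) == 0

    def test_core_to_background_coverage_ratio(self):
        # fold ratio of empirical mean coverages recovers the planted 2,000x
        g = pm.simulate_genome(
            100_000, prophage_specs=[pm.PlantedProphage(45_000, 55_000, core_rate=2000.0)], seed=6
        )
        params = pm.ReadSimParams(background_rate=1.0, seed=7)
        rs = pm.simulate_phage_reads(g, params)
        cov = coverage_from_truth(g, rs)
        core = cov[45_000:55_000].mean()
        bg = np.concatenate([cov[:44_000], cov[56_000:]]).mean()
        assert abs(core / bg - 2000) / 2000 < 0.10

    def test_truth_labels_cover_every_read(self):
        g = pm.simulate_genome(
            30_000,
            prophage_specs=[pm.PlantedProphage(
                10_000, 18_000, core_rate=200.0, flank_side="right",
                flank_rate=40.0, flank_extent=2000,
            )],
            seed=2,
        )
        params = pm.ReadSimParams(background_rate=4.0, contaminant_fraction=0.05, seed=5)
        rs = pm.simulate_phage_reads(g, params)
        counts = rs.label_counts()
        assert sum(counts.values()) == len(rs)
        assert set(counts) <= {"core", "flank", "background", "contaminant"}
        assert counts["flank"] > 0 and counts["contaminant"] > 0

    def test_read_count_cap_refuses_large_runs(self):
        g = pm.simulate_genome(50_000, seed=1)
        with pytest.raises(ValueError, match="exceeds cap"):
            pm.simulate_phage_reads(g, pm.ReadSimParams(background_rate=1000.0), cap=10_000)

    def test_windowed_coverage_matches_expected_profile(self):
        # 1-kb window means within 3 standard errors of the analytic profile
        g = pm.simulate_genome(
            60_000,
            prophage_specs=[pm.PlantedProphage(
                20_000, 35_000, core_rate=300.0, flank_side="left",
                flank_rate=60.0, flank_extent=3000,
            )],
            seed=8,
        )
        params = pm.ReadSimParams(read_length=100, background_rate=5.0, seed=9)
        rs = pm.simulate_phage_reads(g, params)
        cov = coverage_from_truth(g, rs)
        expected = pm.expected_coverage_profile(g, params)["chr"].values
        w = 1000
        for s in range(0, 60_000, w):
            # skip windows straddling a rate step (read-length edge ramps)
            if len(set(expected[max(0, s - 100) : s + w + 100])) > 1:
                continue
            rate = expected[s]
            se = np.sqrt(rate * params.read_length / w)
            assert abs(cov[s : s + w].mean() - rate) < 3 * se + 1e-9

    def test_contaminant_reads_come_from_disjoint_sequence(self):
        g = pm.simulate_genome(20_000, seed=1)
        params = pm.ReadSimParams(background_rate=10.0, contaminant_fraction=0.2, seed=3)
        rs = pm.simulate_phage_reads(g, params)
        host = g.replicons[0].sequence
        cont = [r for r, t in zip(rs.reads, rs.truth) if t.label == "contaminant"]
        assert cont and all(c.sequence not in host for c in cont[:20])
        assert _CONTAMINANT_LEN == 50_000


class TestSimulateHostReads:
    def test_read_count_matches_depth(self):
        g = pm.simulate_genome(60_000, seed=4)
        rs = pm.simulate_host_reads(g, depth=50.0, seed=5)
        expected = 50.0 * 60_000 / 100
        assert abs(len(rs) - expected) < 3 * np.sqrt(expected)

    def test_zero_depth_rejected(self, small_genome):
        with pytest.raises(ValueError, match="depth"):
            pm.simulate_host_reads(small_genome, depth=0.0)

    def test_windowed_coverage_cv_is_small(self):
        g = pm.simulate_genome(60_000, seed=10)
        rs = pm.simulate_host_reads(g, depth=200.0, seed=11)
        cov = coverage_from_truth(g, rs)
        means = cov.reshape(60, 1000).mean(axis=1)
        assert means.std() / means.mean() < 0.2

    def test_no_hidden_structure_without_planted_features(self):
        # windowed fold over the median stays < 3 across seeds
        g = pm.simulate_genome(50_000, seed=0)
        for seed in range(20):
            rs = pm.simulate_host_reads(g, depth=30.0, seed=seed)
            cov = coverage_from_truth(g, rs)
            means = cov.reshape(50, 1000).mean(axis=1)
            assert means.max() / np.median(means) < 3


class TestExpectedProfile:
    def test_no_prophage_constant_background(self, small_genome):
        params = pm.ReadSimParams(background_rate=35.0)
        track = pm.expected_coverage_profile(small_genome, params)["chr"]
        assert np.all(track.values == 35.0)

    def test_flat_flank_exact_extent(self):
        g = pm.simulate_genome(
            50_000,
            prophage_specs=[pm.PlantedProphage(
                10_000, 20_000, core_rate=5000.0, flank_side="right",
                flank_rate=1000.0, flank_extent=2000,
            )],
        )
        track = pm.expected_coverage_profile(g, pm.ReadSimParams(background_rate=5.0))["chr"]
        assert (track.values == 1000.0).sum() == 2000
        assert np.all(track.values[20_000:22_000] == 1000.0)

    def test_geometric_flank_halves_per_kb(self):
        g = pm.simulate_genome(
            50_000,
            prophage_specs=[pm.PlantedProphage(
                10_000, 20_000, core_rate=5000.0, flank_side="right",
                flank_rate=1000.0, flank_extent=3000, flank_decay="geometric",
                decay_per_kb=0.5,
            )],
        )
        track = pm.expected_coverage_profile(g, pm.ReadSimParams(background_rate=5.0))["chr"]
        # 1 kb from the prophage edge the flank rate has decayed to half
        assert track.values[20_999] == pytest.approx(500.0, rel=1e-3)

    def test_poisson_sampled_track_matches_profile_mean(self, prophage_genome):
        params = pm.ReadSimParams(background_rate=35.0)
        tr = pm.sample_coverage_track(prophage_genome, params, seed=3)["chr"]
        assert tr.values[100_000:144_597].mean() == pytest.approx(70_000, rel=0.01)
        assert np.median(tr.values[:100_000]) == pytest.approx(35, abs=2)


class TestSimulateGrowthCounts:
    def test_plps_constant_without_induction_or_decay(self):
        p = pm.GrowthParams(induction_yield=0.0, phage_decay=0.0, initial_plps=5e4, noise=None)
        s = pm.simulate_growth_counts(p)
        assert np.allclose(s.plps, 5e4, rtol=1e-6)

    def test_two_doublings_quadruple_cells(self):
        p = pm.GrowthParams(
            initial_cells=1e6, doubling_time=7.1, induction_yield=0.0,
            timepoints=(0.0, 7.1, 14.2), noise=None,
        )
        s = pm.simulate_growth_counts(p)
        assert s.cells[-1] == pytest.approx(4e6, rel=1e-9)

    def test_plp_accumulation_matches_direct_integration(self):
        p = pm.GrowthParams(
            initial_cells=1e6, doubling_time=8.0, induction_yield=0.1,
            phage_decay=0.02, initial_plps=1e4, noise=None,
        )
        s = pm.simulate_growth_counts(p)
        # independent fine-grid Euler integration of dP/dt = y B(t) - d P
        mu = np.log(2) / 8.0
        dt = 1e-3
        t_grid = np.arange(0, 48 + dt, dt)
        P = 1e4
        vals = {0.0: P}
        for t in t_grid[1:]:
            B = 1e6 * np.exp(mu * (t - dt))
            P += dt * (0.1 * B - 0.02 * P)
            vals[round(t, 3)] = P
        for tp, plp in zip(s.timepoints, s.plps):
            assert plp == pytest.approx(vals[round(tp, 3)], rel=1e-2)

    def test_ratio_nondecreasing_while_decay_negligible(self):
        p = pm.GrowthParams(
            initial_cells=1e6, doubling_time=7.0, induction_yield=0.5,
            phage_decay=0.0, initial_plps=0.0, noise=None,
        )
        s = pm.simulate_growth_counts(p)
        ratios = s.plps[1:] / s.cells[1:]
        assert np.all(np.diff(ratios) >= -1e-9)

    def test_invalid_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            pm.GrowthParams(timepoints=(0.0, 6.0, 6.0))
        with pytest.raises(ValueError, match="timepoints"):
            pm.GrowthParams(timepoints=(1.0, 6.0))
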