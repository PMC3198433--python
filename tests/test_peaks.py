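"""Peak-calling stack: normalization, moving-average scoring, region calling,
label-swap FDR, read-window scans, gene assignment, E-box scanning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mycoresig import peaks, synthdata
from mycoresig.containers import ReadSet, TilingProbeSet
from conftest import random_tiling, small_config, track_from
import oracles


def _uniform_probes(n, spacing=35, chrom="chr1"):
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + 25,
         "probe_id": [f"p{i}" for i in range(n)]}
    )


class TestQuantileNormalization:
    def test_identical_replicates_are_a_fixed_point(self):
        probes = _uniform_probes(10)
        row = np.linspace(5, 9, 10)
        tiling = TilingProbeSet(probes, np.vstack([row, row]), ["IP", "control"])
        out = peaks.normalize_probes(tiling)
        np.testing.assert_allclose(out.intensities, tiling.intensities)

    def test_monotone_shift_collapses_to_identity(self):
        probes = _uniform_probes(10)
        rng = np.random.default_rng(0)
        row = rng.normal(8, 1, 10)
        tiling = TilingProbeSet(probes, np.vstack([row, row + 2.5]), ["IP", "control"])
        out = peaks.normalize_probes(tiling)
        np.testing.assert_allclose(out.intensities[0], out.intensities[1])

    def test_matches_direct_oracle_on_random_replicates(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            probes = _uniform_probes(15)
            x = rng.normal(8, 1, size=(3, 15))
            tiling = TilingProbeSet(probes, x, ["IP", "IP", "control"])
            out = peaks.normalize_probes(tiling)
            np.testing.assert_allclose(out.intensities, oracles.quantile_norm_oracle(x))

    def test_non_finite_intensity_names_the_probe(self):
        probes = _uniform_probes(3)
        x = np.array([[1.0, np.nan, 3.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="p1"):
            peaks.normalize_probes(TilingProbeSet(probes, x, ["IP", "control"]))


class TestMovingAverage:
    def test_identical_ip_and_control_gives_all_zero(self):
        probes = _uniform_probes(12)
        rng = np.random.default_rng(2)
        x = rng.normal(8, 1, size=(2, 12))
        tiling = TilingProbeSet(probes, np.vstack([x, x]), ["IP", "IP", "control", "control"])
        track = peaks.moving_average_statistic(tiling, 5)
        np.testing.assert_allclose(track.m, 0.0)

    def test_window_one_equals_per_probe_statistic(self):
        rng = np.random.default_rng(3)
        tiling = random_tiling(rng, n_probes=30)
        track = peaks.moving_average_statistic(tiling, 1)
        expected = oracles.shrunken_t_oracle(
            tiling.intensities[tiling.ip_index], tiling.intensities[tiling.ctrl_index]
        )
        np.testing.assert_allclose(track.m, expected)

    def test_even_window_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="odd"):
            peaks.moving_average_statistic(random_tiling(rng), 4)

    def test_matches_brute_force_windowing_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            tiling = random_tiling(rng, n_probes=20, n_chroms=2)
            window = rng.choice([1, 3, 5])
            track = peaks.moving_average_statistic(tiling, window)
            t = oracles.shrunken_t_oracle(
                tiling.intensities[tiling.ip_index],
                tiling.intensities[tiling.ctrl_index],
            )
            segments = peaks._contiguous_segments(tiling.probes)
            expected = oracles.moving_average_oracle(t, segments, window)
            np.testing.assert_allclose(track.m, expected)


class TestRegionCalling:
    def test_all_below_threshold_yields_empty_set(self):
        track = track_from(_uniform_probes(5), [0.1, 0.2, 0.1, 0.0, 0.2])
        assert len(peaks.call_binding_regions(track, 1.0)) == 0

    def test_hand_enumerated_run_with_zero_gap_merging(self):
        """m=(0,5,5,0,5), threshold 1, max_gap 0, min_probes 2: one region over
        the two adjacent above-threshold probes."""
        track = track_from(_uniform_probes(5), [0, 5, 5, 0, 5])
        regions = peaks.call_binding_regions(track, 1.0, max_gap_bp=0, min_probes=2)
        assert len(regions) == 1
        r = regions.regions.iloc[0]
        assert (r["start"], r["end"], r["n_probes"]) == (35, 95, 2)

    def test_lowering_threshold_never_shrinks_coverage(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            tiling = random_tiling(rng, n_probes=40)
            track = peaks.moving_average_statistic(tiling, 3)
            prev = -1
            for th in (2.0, 1.0, 0.5, 0.0, -1.0):
                regs = peaks.call_binding_regions(track, th, 100, 1).regions
                covered = int((regs["end"] - regs["start"]).sum())
                assert covered >= prev
                prev = covered

    def test_matches_brute_force_run_finder_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            tiling = random_tiling(rng, n_probes=25, n_chroms=2)
            m = rng.normal(0, 2, 25)
            track = track_from(tiling.probes, m)
            th = float(rng.normal(0, 1))
            gap = int(rng.choice([0, 50, 300]))
            minp = int(rng.choice([1, 2, 3]))
            got = peaks.call_binding_regions(track, th, gap, minp).regions
            expected = oracles.region_call_oracle(
                tiling.probes["start"].to_numpy(), tiling.probes["end"].to_numpy(),
                peaks._contiguous_segments(tiling.probes), m, th, gap, minp,
            )
            assert [
                (s, e, n) for s, e, n in zip(got["start"], got["end"], got["n_probes"])
            ] == expected


class TestEmpiricalFdr:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        tiling = random_tiling(rng, n_probes=200, n_ip=2, n_ctrl=2)
        a = peaks.estimate_fdr(tiling, 0.5, seed=42)
        b = peaks.estimate_fdr(tiling, 0.5, seed=42)
        assert a == b

    def test_too_few_replicates_suggests_more(self):
        rng = np.random.default_rng(9)
        tiling = random_tiling(rng, n_probes=10, n_ip=1, n_ctrl=2)
        with pytest.raises(ValueError, match="n_rep >= 2"):
            peaks.estimate_fdr(tiling, 0.5)

    def test_null_data_estimates_fdr_near_one(self):
        """With no planted signal the label-swapped null matches the observed
        calls, so the capped estimate sits at 1 for most simulations."""
        fdrs = []
        for seed in range(6):
            cfg = small_config(seed=100 + seed, n_genes=20, binding_shift=0.0,
                               n_rep_ip=2, n_rep_ctrl=2)
            truth = synthdata.plant_truth(cfg)
            ann, _, truth = synthdata.make_annotation(cfg, truth)
            tiling = peaks.normalize_probes(synthdata.simulate_tiling(cfg, ann, truth))
            fdrs.append(peaks.estimate_fdr(tiling, 0.6, window_probes=5,
                                           min_probes=2, n_swaps=8, seed=seed))
        assert np.mean(fdrs) > 0.7

    def test_strong_planted_signal_gives_low_fdr(self):
        cfg = small_config(seed=31, n_genes=30, binding_shift=3.0, noise_sd=0.3)
        truth = synthdata.plant_truth(cfg)
        ann, _, truth = synthdata.make_annotation(cfg, truth)
        tiling = peaks.normalize_probes(synthdata.simulate_tiling(cfg, ann, truth))
        assert peaks.estimate_fdr(tiling, 1.0, n_swaps=10, seed=0) < 0.1


class TestWindowScan:
    def test_no_reads_gives_empty_table(self):
        empty = ReadSet(pd.DataFrame(columns=["chrom", "pos", "strand"]))
        assert len(peaks.window_scan_reads(empty)) == 0

    def test_hand_positions_match_brute_force(self):
        reads = ReadSet(
            pd.DataFrame({"chrom": "chr1", "pos": [10, 50, 120], "strand": "+"})
        )
        counts = peaks.window_scan_reads(reads, 100, 25)
        expected = oracles.window_count_oracle([10, 50, 120], 100, 25, len(counts))
        assert counts["count"].tolist() == expected

    def test_coverage_conservation_away_from_origin(self):
        """Each read lands in exactly window/step windows."""
        rng = np.random.default_rng(10)
        pos = np.sort(rng.integers(200, 5000, size=50))
        reads = ReadSet(pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+"}))
        counts = peaks.window_scan_reads(reads, 100, 25)
        assert counts["count"].sum() == (100 // 25) * len(pos)

    def test_invalid_window_step_rejected(self):
        reads = ReadSet(pd.DataFrame({"chrom": ["chr1"], "pos": [5], "strand": ["+"]}))
        with pytest.raises(ValueError):
            peaks.window_scan_reads(reads, 10, 0)
        with pytest.raises(ValueError):
            peaks.window_scan_reads(reads, 10, 25)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            pos = np.sort(rng.integers(0, 800, size=rng.integers(1, 40)))
            reads = ReadSet(pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+"}))
            window = int(rng.choice([50, 100, 75]))
            step = int(rng.choice([25, 50]))
            if window < step:
                continue
            counts = peaks.window_scan_reads(reads, window, step)
            expected = oracles.window_count_oracle(pos.tolist(), window, step, len(counts))
            assert counts["count"].tolist() == expected


class TestGeneAssignment:
    @pytest.fixture(scope="class")
    def annotation(self, small_world):
        return small_world[1]

    def test_region_upstream_of_plus_strand_tss_is_assigned(self, small_world):
        cfg, ann, _, _ = small_world
        gene = ann.genes[ann.genes["strand"] == "+"].iloc[0]
        start = gene["tss"] - 500
        regions = peaks.BindingRegionSet(
            pd.DataFrame([{"chrom": gene["chrom"], "start": start, "end": start + 100,
                           "region_id": "r1", "score": 2.0, "n_probes": 4}]),
            threshold=0.5,
        )
        out = peaks.assign_regions_to_genes(regions, ann, (8000, 2000))
        assert gene["gene_id"] in out.regions.iloc[0]["genes"]

    def test_region_far_upstream_is_not_assigned(self, small_world):
        cfg, ann, _, _ = small_world
        gene = ann.genes[ann.genes["strand"] == "+"].iloc[0]
        start = gene["tss"] - 10_000
        regions = peaks.BindingRegionSet(
            pd.DataFrame([{"chrom": gene["chrom"], "start": start, "end": start + 100,
                           "region_id": "r1", "score": 2.0, "n_probes": 4}]),
            threshold=0.5,
        )
        out = peaks.assign_regions_to_genes(regions, ann, (8000, 2000))
        assert gene["gene_id"] not in out.regions.iloc[0]["genes"]

    def test_random_regions_match_quadratic_oracle(self, small_world):
        cfg, ann, _, _ = small_world
        rng = np.random.default_rng(12)
        genes = list(
            ann.genes[["gene_id", "chrom", "strand", "tss"]].itertuples(index=False)
        )
        for _ in range(20):
            n = 8
            chroms = rng.choice(sorted(ann.chrom_sizes), size=n)
            # non-overlapping by construction (grid spacing > region length)
            starts = rng.choice(np.arange(0, 50_000, 250), size=n, replace=False)
            regions = peaks.BindingRegionSet(
                pd.DataFrame({
                    "chrom": chroms, "start": starts, "end": starts + 200,
                    "region_id": [f"r{i}" for i in range(n)],
                    "score": 1.0, "n_probes": 3,
                }).sort_values(["chrom", "start"], ignore_index=True),
                threshold=0.5,
            )
            up, down = int(rng.choice([2000, 8000])), 2000
            out = peaks.assign_regions_to_genes(regions, ann, (up, down))
            expected = oracles.assignment_oracle(
                list(zip(out.regions["chrom"], out.regions["start"], out.regions["end"])),
                [tuple(g) for g in genes], up, down,
            )
            assert [set(g) for g in out.regions["genes"]] == expected


class TestEboxScan:
    def test_canonical_hit(self):
        hits = peaks.scan_eboxes({"r1": "AACACGTGTT"})
        assert len(hits) == 1
        assert (hits[0].motif_class, hits[0].offset, hits[0].hexamer) == (
            "canonical", 2, "CACGTG",
        )

    def test_degenerate_hit(self):
        hits = peaks.scan_eboxes({"r1": "CATATG"})
        assert [(h.motif_class, h.offset) for h in hits] == [("degenerate", 0)]

    def test_no_hits(self):
        assert peaks.scan_eboxes({"r1": "AAAAAA"}) == []

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            peaks.scan_eboxes({"r1": "ACXGT"})

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=80))
    def test_reverse_complement_leaves_counts_unchanged(self, seq):
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = peaks.scan_eboxes({"r": seq})
        rev = peaks.scan_eboxes({"r": rc})
        assert len(fwd) == len(rev)
        assert sum(h.motif_class == "canonical" for h in fwd) == sum(
            h.motif_class == "canonical" for h in rev
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    def test_matches_regex_free_oracle(self, seq):
        got = [(h.offset, h.motif_class) for h in peaks.scan_eboxes({"r": seq})]
        assert got == oracles.ebox_oracle(seq)
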