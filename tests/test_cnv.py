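"""Copy-number pipeline: binning, double normalization, segmentation, IO."""

import numpy as np
import pytest
from sklearn.base import clone

from minichrom.cnv import (
    BinnedCoverageTrack,
    CopyNumberCaller,
    ParseError,
    ScoreTrack,
    TrackError,
    bin_reads,
    chromosome_copy_table,
    compare_strains,
    detect_mini_segment,
    normalize_to_control,
    normalize_to_reference_chrom,
    read_counts_tsv,
    read_read_positions_bed,
    segment_score_track,
    write_counts_tsv,
    write_read_positions_bed,
    write_score_bedgraph,
    write_segments_bed,
)
from minichrom.karyotype import KaryotypeError, copy_number_profile
from minichrom.simulate import (
    CoverageSimConfig,
    expected_coverage,
    simulate_binned_coverage,
    simulate_read_positions,
)

BS = 10_000
CEN = (52_200_000, 52_700_000)


def noiseless_track(karyotype, config=None):
    """Deterministic track at the exact per-bin expectation (integral here)."""
    lam = expected_coverage(karyotype, config or CoverageSimConfig())
    return BinnedCoverageTrack(
        strain=karyotype.strain,
        bin_size=BS,
        counts={c: np.rint(v).astype(np.int64) for c, v in lam.items()},
    )


def make_score(sample_track, control_track, floor=0.1):
    return normalize_to_control(
        normalize_to_reference_chrom(sample_track),
        normalize_to_reference_chrom(control_track),
        floor,
    )


@pytest.fixture(scope="module")
def sim_scores(karyotypes):
    """Seeded noisy score tracks for each strain against CL18."""
    cfg = CoverageSimConfig()
    tracks = {
        name: simulate_binned_coverage(k, cfg, seed=50 + i)
        for i, (name, k) in enumerate(karyotypes.items())
    }
    control = simulate_binned_coverage(karyotypes["CL18"], cfg, seed=49)
    return {name: make_score(t, control) for name, t in tracks.items()}


class TestBinReads:
    def test_boundary_semantics(self, genome):
        track = bin_reads({"chr2": [0, 9_999, 10_000]}, genome, BS)
        assert track.counts["chr2"][0] == 2
        assert track.counts["chr2"][1] == 1

    def test_empty_input_all_zero(self, genome):
        track = bin_reads({}, genome, BS)
        assert all(v.sum() == 0 for v in track.counts.values())
        assert len(track.counts["chr2"]) == 15_300

    def test_out_of_bounds_handling(self, genome):
        track = bin_reads({"chr2": [-1, 5, 200_000_000]}, genome, BS)
        assert track.counts["chr2"].sum() == 1
        with pytest.raises(KaryotypeError):
            bin_reads({"chr2": [-1]}, genome, BS, strict=True)

    def test_binning_simulated_positions_matches_direct_simulation(
        self, genome, karyotypes
    ):
        """Cross-check the two synthetic routes: binning sampled read starts
        agrees with the binned-coverage expectation."""
        kary = karyotypes["Chr2_1_1_q"]
        cfg = CoverageSimConfig()
        pos = simulate_read_positions(kary, ("chr2", 50_000_000, 54_000_000), cfg, seed=77)
        track = bin_reads({"chr2": pos}, genome, BS)
        lam = expected_coverage(kary, cfg)["chr2"]
        window = slice(5000, 5400)
        observed = track.counts["chr2"][window].astype(float)
        mu = lam[window]
        live = mu > 0
        z = (observed[live] - mu[live]) / np.sqrt(mu[live])
        assert abs(z.mean()) < 4 / np.sqrt(live.sum())


class TestNormalization:
    def test_uniform_track_unit_ratio(self, genome):
        counts = {c.name: np.full(-(-c.length // BS), 12) for c in genome}
        ratio = normalize_to_reference_chrom(
            BinnedCoverageTrack("flat", BS, counts)
        )
        for values in ratio.values.values():
            assert np.allclose(values, 1.0)

    def test_scale_invariance_exact(self, genome, karyotypes):
        track = simulate_binned_coverage(karyotypes["CL18"], seed=4)
        scaled = BinnedCoverageTrack(
            "x7", BS, {c: v * 7 for c, v in track.counts.items()}
        )
        a = normalize_to_reference_chrom(track)
        b = normalize_to_reference_chrom(scaled)
        for chrom in a.values:
            np.testing.assert_allclose(a.values[chrom], b.values[chrom])

    def test_zero_reference_rejected(self, genome):
        counts = {c.name: np.zeros(-(-c.length // BS), dtype=int) for c in genome}
        with pytest.raises(TrackError, match="zero mean"):
            normalize_to_reference_chrom(BinnedCoverageTrack("z", BS, counts))

    def test_trisomy_ratio_one_point_five(self, karyotypes):
        """Control chr2 (3 copies) against chr1 (2 copies) averages 1.5."""
        track = simulate_binned_coverage(karyotypes["CL18"], seed=8)
        ratio = normalize_to_reference_chrom(track)
        unmasked = np.ones(15_300, dtype=bool)
        unmasked[5220:5270] = False
        assert ratio.values["chr2"][unmasked].mean() == pytest.approx(1.5, rel=0.02)

    def test_self_normalization_identity(self, karyotypes):
        """normalize_to_control(t, t) is exactly 1 on unmasked bins, NaN on
        the centromere where the control has no signal."""
        track = simulate_binned_coverage(karyotypes["CL18"], seed=9)
        score = make_score(track, track)
        chr2 = score.scores["chr2"]
        assert np.all(np.isnan(chr2[5220:5270]))
        assert np.allclose(chr2[~np.isnan(chr2)], 1.0)
        for chrom in ("chr1", "chr3", "chr24"):
            vals = score.scores[chrom]
            assert np.allclose(vals[~np.isnan(vals)], 1.0)

    def test_double_normalization_identity_random_track(self, genome):
        rng = np.random.default_rng(0)
        counts = {
            c.name: rng.integers(1, 100, size=-(-c.length // BS)) for c in genome
        }
        track = BinnedCoverageTrack("rnd", BS, counts)
        score = make_score(track, track)
        for vals in score.scores.values():
            assert np.allclose(vals[~np.isnan(vals)], 1.0)

    def test_binning_mismatch_rejected(self, karyotypes):
        a = normalize_to_reference_chrom(
            simulate_binned_coverage(karyotypes["CL18"], seed=1)
        )
        cfg = CoverageSimConfig(bin_size=20_000)
        b = normalize_to_reference_chrom(
            simulate_binned_coverage(karyotypes["CL18"], cfg, seed=1)
        )
        with pytest.raises(TrackError):
            normalize_to_control(a, b)

    def test_depth_invariance(self, karyotypes):
        """Scores are invariant to the sample's total sequencing depth."""
        control = simulate_binned_coverage(karyotypes["CL18"], seed=60)
        means = []
        for depth, seed in [(10.0, 61), (30.0, 62)]:
            cfg = CoverageSimConfig(depth_per_copy=depth)
            sample = simulate_binned_coverage(karyotypes["Chr2-2"], cfg, seed=seed)
            means.append(make_score(sample, control).chromosome_mean("chr2"))
        assert means[0] == pytest.approx(means[1], abs=0.01)


class TestCopyTable:
    def test_self_comparison_exact(self, karyotypes):
        track = simulate_binned_coverage(karyotypes["CL18"], seed=10)
        table = chromosome_copy_table(
            make_score(track, track), karyotypes["CL18"].genome
        ).set_index("chromosome")
        assert table.loc["chr2", "copies_raw"] == pytest.approx(3.0)
        assert table.loc["chr1", "copies_raw"] == pytest.approx(2.0)
        assert table.loc["chr24", "copies_raw"] == pytest.approx(4.0)

    def test_disomy_strain_copies(self, genome, sim_scores):
        table = chromosome_copy_table(sim_scores["Chr2-2"], genome).set_index(
            "chromosome"
        )
        assert table.loc["chr2", "mean_score"] == pytest.approx(2 / 3, abs=0.02)
        assert table.loc["chr2", "copies_rounded"] == 2
        for chrom in ("chr1", "chr3", "chr24"):
            assert table.loc[chrom, "copies_raw"] == pytest.approx(
                genome[chrom].control_copies, rel=0.02
            )

    def test_q_strain_read_count_decrease(self, genome, sim_scores):
        """Losing one 52-Mb p-arm out of 3x153 Mb cuts chr2 reads by ~11.4%."""
        table = chromosome_copy_table(sim_scores["Chr2_1_1_q"], genome)
        mean = table.set_index("chromosome").loc["chr2", "mean_score"]
        assert 100 * (1 - mean) == pytest.approx(11.37, abs=1.0)

    def test_fully_masked_chromosome_reported_missing(self, genome):
        score = ScoreTrack(
            "s", "c", "chr1", BS,
            {"chr24": np.full(600, np.nan), "chr1": np.ones(19_600)},
        )
        table = chromosome_copy_table(score, genome).set_index("chromosome")
        assert np.isnan(table.loc["chr24", "copies_raw"])
        assert table.loc["chr24", "n_bins_used"] == 0


class TestSegmentation:
    def test_constant_track_single_segment(self, genome, karyotypes):
        track = noiseless_track(karyotypes["CL18"])
        segments = segment_score_track(make_score(track, track), genome)
        per_chrom = {}
        for seg in segments:
            per_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in per_chrom.items():
            assert len(segs) == 1
            assert segs[0].start == 0 and segs[0].end == genome[chrom].length
            assert segs[0].level == 1.0

    def test_noiseless_step_exact_boundary(self, genome, karyotypes):
        """The q-retaining strain: 2/3 level up to exactly 52.0 Mb, then 1."""
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_1_q"]),
            noiseless_track(karyotypes["CL18"]),
        )
        segs = [s for s in segment_score_track(score, genome) if s.chromosome == "chr2"]
        assert [(s.start, s.end, s.level) for s in segs] == [
            (0, 52_000_000, pytest.approx(2 / 3)),
            (52_000_000, 153_000_000, 1.0),
        ]
        assert segs[0].copies == 2 and segs[1].copies == 3

    def test_noiseless_mini_plateau_bridges_mask(self, genome, karyotypes):
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_1_mini"]),
            noiseless_track(karyotypes["CL18"]),
        )
        segs = [s for s in segment_score_track(score, genome) if s.chromosome == "chr2"]
        assert [(s.start, s.end) for s in segs] == [
            (0, 52_000_000),
            (52_000_000, 52_700_000),
            (52_700_000, 153_000_000),
        ]
        assert [s.level for s in segs] == [pytest.approx(2 / 3), 1.0, pytest.approx(2 / 3)]

    def test_score_only_fallback_matches_count_path(self, genome, karyotypes):
        """Without raw counts the least-squares fallback segments noiseless
        tracks identically."""
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_1_mini"]),
            noiseless_track(karyotypes["CL18"]),
        )
        bare = ScoreTrack(
            score.sample_strain, score.control_strain,
            score.reference_chromosome, score.bin_size, score.scores,
        )
        assert segment_score_track(bare, genome) == segment_score_track(score, genome)

    def test_noisy_boundaries_close(self, genome, sim_scores):
        """At default depth the recovered breakpoints sit within a few bins
        of the truth (exact +/-1-bin recovery rates are measured in the
        acceptance suite)."""
        segs = [
            s
            for s in segment_score_track(sim_scores["Chr2_1_1_q"], genome)
            if s.chromosome == "chr2"
        ]
        boundary = min((s.start for s in segs if s.start > 0), key=lambda b: abs(b - 52_000_000))
        assert abs(boundary - 52_000_000) <= 3 * BS


class TestMiniDetection:
    def test_mini_strain_interval(self, genome, karyotypes):
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_1_mini"]),
            noiseless_track(karyotypes["CL18"]),
        )
        mini = detect_mini_segment(segment_score_track(score, genome), "chr2", CEN)
        assert (mini.start, mini.end) == (52_000_000, 52_700_000)
        assert mini.length == 700_000

    def test_flat_strain_has_no_mini(self, genome, karyotypes):
        score = make_score(
            noiseless_track(karyotypes["Chr2-2"]),
            noiseless_track(karyotypes["CL18"]),
        )
        assert detect_mini_segment(segment_score_track(score, genome), "chr2", CEN) is None

    def test_p_q_strain_indistinguishable_from_mini(self, genome, karyotypes):
        """Coverage cannot separate the two mini-carrying architectures."""
        prof = copy_number_profile(
            karyotypes["Chr2_1_p_q"], "chr2", np.arange(0, 153_000_000, BS)
        )
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_p_q"]),
            noiseless_track(karyotypes["CL18"]),
        )
        mini = detect_mini_segment(segment_score_track(score, genome), "chr2", CEN)
        assert (mini.start, mini.end) == (52_000_000, 52_700_000)
        assert prof[5210] == 3  # the elevated stretch really is there


class TestCompareStrains:
    def test_identical_tracks_no_regions(self, genome, karyotypes):
        t = noiseless_track(karyotypes["Chr2_1_1_q"])
        c = noiseless_track(karyotypes["CL18"])
        assert compare_strains(make_score(t, c), make_score(t, c), genome) == []

    def test_incremental_loss_starts_at_q_break(self, genome, karyotypes):
        """The mini strains lost what the q-retaining strain still has,
        starting right after the centromere."""
        control = noiseless_track(karyotypes["CL18"])
        regions = compare_strains(
            make_score(noiseless_track(karyotypes["Chr2_1_1_mini"]), control),
            make_score(noiseless_track(karyotypes["Chr2_1_1_q"]), control),
            genome,
        )
        assert len(regions) == 1
        region = regions[0]
        assert (region.chromosome, region.start, region.end) == ("chr2", 52_700_000, 153_000_000)
        assert region.direction == "loss"

    def test_p_arm_loss_region(self, genome, karyotypes):
        control = noiseless_track(karyotypes["CL18"])
        regions = compare_strains(
            make_score(noiseless_track(karyotypes["Chr2_1_1_q"]), control),
            make_score(control, control),
            genome,
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 52_000_000)
        assert regions[0].direction == "loss"

    def test_noisy_q_break_recovered(self, genome, sim_scores):
        """The dominant loss region between a mini strain and the q-retaining
        strain spans the entire q arm; its left edge lies between the p-side
        break and the far centromere edge (the exact +/-1-bin rate is
        measured in the acceptance suite)."""
        regions = [
            r
            for r in compare_strains(
                sim_scores["Chr2_1_1_mini"], sim_scores["Chr2_1_1_q"], genome
            )
            if r.chromosome == "chr2" and r.direction == "loss" and r.length >= 3 * BS
        ]
        longest = max(regions, key=lambda r: r.length)
        assert longest.end == genome["chr2"].length
        assert 52_000_000 <= longest.start <= 52_700_000 + BS

    def test_binning_mismatch_rejected(self, genome, karyotypes):
        t = noiseless_track(karyotypes["CL18"])
        score = make_score(t, t)
        other = ScoreTrack("a", "b", "chr1", 20_000, {"chr2": np.ones(10)})
        with pytest.raises(TrackError):
            compare_strains(score, other, genome)


class TestTrackIO:
    def test_counts_round_trip(self, tmp_path, karyotypes):
        track = simulate_binned_coverage(karyotypes["Chr2_1_1_mini"], seed=15)
        path = tmp_path / "counts.tsv"
        write_counts_tsv(track, path)
        back = read_counts_tsv(path)
        assert back.strain == track.strain
        assert back.bin_size == track.bin_size
        for chrom in track.counts:
            np.testing.assert_array_equal(back.counts[chrom], track.counts[chrom])

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\tend\tcount\nchr1\t0\t10000\tnope\n")
        with pytest.raises(ParseError, match="line 2"):
            read_counts_tsv(path)

    def test_bedgraph_omits_masked_bins(self, tmp_path, karyotypes):
        track = noiseless_track(karyotypes["CL18"])
        score = make_score(track, track)
        path = tmp_path / "score.bedgraph"
        write_score_bedgraph(score, path)
        lines = path.read_text().splitlines()
        n_unmasked = sum(
            int(np.sum(~np.isnan(v))) for v in score.scores.values()
        )
        assert len(lines) == n_unmasked
        masked_bin = "chr2\t52200000\t52210000"
        assert not any(line.startswith(masked_bin) for line in lines)

    def test_segments_bed_matches_calls(self, tmp_path, genome, karyotypes):
        score = make_score(
            noiseless_track(karyotypes["Chr2_1_1_mini"]),
            noiseless_track(karyotypes["CL18"]),
        )
        segments = segment_score_track(score, genome)
        path = tmp_path / "segs.bed"
        write_segments_bed(segments, path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == len(segments)
        for row, seg in zip(rows, segments):
            assert (row[0], int(row[1]), int(row[2])) == (
                seg.chromosome,
                seg.start,
                seg.end,
            )

    def test_read_positions_bed_round_trip(self, tmp_path, karyotypes):
        pos = simulate_read_positions(
            karyotypes["CL18"], ("chr24", 0, 100_000), seed=3
        )
        path = tmp_path / "reads.bed"
        write_read_positions_bed(pos, "chr24", path)
        back = read_read_positions_bed(path)
        np.testing.assert_array_equal(back["chr24"], pos)


class TestCopyNumberCaller:
    def test_fit_exposes_pipeline_results(self, genome, karyotypes):
        sample = simulate_binned_coverage(karyotypes["Chr2_1_1_mini"], seed=70)
        control = simulate_binned_coverage(karyotypes["CL18"], seed=71)
        caller = CopyNumberCaller(genome=genome).fit(sample, control)
        assert caller.mini_segment_ is not None
        assert abs(caller.mini_segment_.length - 700_000) <= 2 * BS
        table = caller.copy_table_.set_index("chromosome")
        assert table.loc["chr2", "copies_rounded"] == 2.0
        assert {s.chromosome for s in caller.segments_} == set(genome.names)

    def test_fit_accepts_pair_tuple(self, genome, karyotypes):
        t = noiseless_track(karyotypes["CL18"])
        caller = CopyNumberCaller(genome=genome).fit((t, t))
        assert caller.mini_segment_ is None

    def test_sklearn_protocol(self, genome):
        caller = CopyNumberCaller(genome=genome, control_floor=0.2)
        assert clone(caller).get_params()["control_floor"] == 0.2
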