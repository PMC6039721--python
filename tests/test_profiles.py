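"""Profile matrices, normalization steps and bootstrap inference."""

import numpy as np
import pytest

from chromdyn import (
    CoverageTrack,
    GenomeModel,
    ProfileMatrix,
    aggregate_replicates,
    baseline_normalize,
    bootstrap_ci,
    compute_matrix,
    empirical_pvalue,
    rowwise_normalize,
    sem_profile,
)


def make_matrix(values, replicate_id="rep", binsize=5, upstream=50, downstream=50):
    values = np.asarray(values, dtype=float)
    refs = [("chr1", 1000 + 100 * i, "+") for i in range(values.shape[0])]
    return ProfileMatrix(replicate_id, refs, values, binsize, upstream, downstream)


def uniform_track(value, length=20_000, binsize=1):
    genome = GenomeModel((("chr1", length),))
    track = CoverageTrack.zeros(genome, binsize)
    track.data["chr1"][:] = value
    return track


class TestComputeMatrix:
    def test_uniform_track_fills_every_cell(self):
        track = uniform_track(3.5)
        m = compute_matrix(track, [("chr1", 5000, "+"), ("chr1", 9000, "-")])
        np.testing.assert_allclose(m.values, 3.5)
        assert m.n_bins == 600

    def test_step_track_steps_at_center_bin(self):
        track = uniform_track(0.0)
        track.data["chr1"][5000:] = 1.0
        m = compute_matrix(track, [("chr1", 5000, "+")])
        row = m.values[0]
        center = m.upstream // m.binsize
        np.testing.assert_allclose(row[:center], 0.0)
        np.testing.assert_allclose(row[center:], 1.0)

    def test_minus_strand_row_is_reversed_mirror(self):
        """A minus-strand reference over the mirror-image track must equal
        the reversed plus-strand row."""
        rng = np.random.default_rng(5)
        genome = GenomeModel((("chr1", 12_000),))
        fwd = CoverageTrack(1, {"chr1": rng.random(12_000)}, genome)
        rev = CoverageTrack(1, {"chr1": fwd.data["chr1"][::-1].copy()}, genome)
        p = 4000
        row_fwd = compute_matrix(fwd, [("chr1", p, "+")]).values[0]
        row_rev = compute_matrix(rev, [("chr1", 12_000 - 1 - p, "-")]).values[0]
        np.testing.assert_allclose(row_rev, row_fwd)

    def test_out_of_chromosome_bases_read_zero(self):
        track = uniform_track(2.0, length=2000)
        m = compute_matrix(track, [("chr1", 100, "+")])
        assert m.values[0, 0] == 0.0  # entirely left of the chromosome
        assert m.values[0, -1] == 2.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        genome = GenomeModel((("chr1", 3000),))
        track = CoverageTrack(1, {"chr1": rng.random(3000)}, genome)
        refs = [("chr1", int(p), s) for p, s in
                zip(rng.integers(100, 2900, 8), "+-+-+-+-")]
        up = down = 300
        binsize = 5
        m = compute_matrix(track, refs, "center", up, down, binsize)
        for row, (chrom, pos, strand) in zip(m.values, refs):
            per_base = []
            for off in range(-up, down):
                base = pos + off if strand == "+" else pos - off
                per_base.append(track.data[chrom][base] if 0 <= base < 3000 else 0.0)
            expected = np.array(per_base).reshape(-1, binsize).mean(axis=1)
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_tss_mode_uses_gene_strand(self):
        from chromdyn import GeneModel
        track = uniform_track(0.0, length=30_000)
        track.data["chr1"][10_000:] = 1.0
        gene = GeneModel("g", "chr1", "+", 10_000, 15_000)
        m = compute_matrix(track, [gene], "tss")
        assert m.values[0, m.upstream // m.binsize] == 1.0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            compute_matrix(uniform_track(1.0), [("chrX", 5000, "+")])


class TestRowwiseNormalize:
    def test_row_scaled_to_its_mean(self):
        m = make_matrix(np.tile([2.0, 4.0, 6.0], (1, 20 // 3 + 1))[:, :20])
        normed = rowwise_normalize(m)
        np.testing.assert_allclose(normed.values.mean(axis=1), 1.0)

    def test_simple_row_values(self):
        m = ProfileMatrix("r", [("chr1", 0, "+")], [[2.0, 4.0, 6.0]],
                          binsize=1, upstream=1, downstream=2)
        np.testing.assert_allclose(rowwise_normalize(m).values[0], [0.5, 1.0, 1.5])

    def test_zero_rows_dropped_and_counted(self):
        m = make_matrix(np.vstack([np.ones((3, 20)), np.zeros((2, 20))]))
        normed = rowwise_normalize(m)
        assert normed.n_locations == 3
        assert normed.n_dropped == 2

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            rowwise_normalize(make_matrix(np.zeros((4, 20))))


class TestBaselineNormalize:
    def test_constant_profile_becomes_one(self):
        out = baseline_normalize(np.full(600, 7.0), 5, 1500, 1500)
        np.testing.assert_allclose(out, 1.0)

    def test_center_enrichment_over_flanks(self):
        profile = np.full(600, 2.0)
        profile[290:310] = 6.0
        out = baseline_normalize(profile, 5, 1500, 1500)
        assert out[300] == pytest.approx(3.0)

    def test_output_flank_mean_is_one(self):
        rng = np.random.default_rng(3)
        out = baseline_normalize(rng.random(600) + 0.1, 5, 1500, 1500)
        flanks = np.r_[out[:10], out[-10:]]
        assert flanks.mean() == pytest.approx(1.0, abs=1e-12)

    def test_window_too_small_for_flanks_rejected(self):
        with pytest.raises(ValueError):
            baseline_normalize(np.ones(10), 5, 25, 25)

    def test_zero_flanks_rejected(self):
        profile = np.zeros(600)
        profile[300] = 1.0
        with pytest.raises(ValueError, match="flank"):
            baseline_normalize(profile, 5, 1500, 1500)


class TestAggregateReplicates:
    def test_identical_replicates_equal_single(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 20)) + 0.1
        mats = [make_matrix(vals, f"r{i}") for i in range(3)]
        agg = aggregate_replicates(mats, normalized=False)
        np.testing.assert_allclose(agg.mean, vals.mean(axis=0))

    def test_constant_replicates_average(self):
        mats = [make_matrix(np.full((5, 20), c), f"r{c}") for c in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(mats, normalized=False)
        np.testing.assert_allclose(agg.mean, 2.0)

    def test_normalized_constant_replicates_are_one(self):
        mats = [make_matrix(np.full((5, 20), c), f"r{c}") for c in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(mats, normalized=True)
        np.testing.assert_allclose(agg.mean, 1.0)

    def test_geometry_mismatch_rejected(self):
        a = make_matrix(np.ones((3, 20)))
        b = make_matrix(np.ones((3, 10)), upstream=25, downstream=25)
        with pytest.raises(ValueError, match="geometry"):
            aggregate_replicates([a, b])

    def test_pipeline_invariant_to_track_scaling(self):
        rng = np.random.default_rng(1)
        vals = rng.random((20, 20)) + 0.05
        mats = [make_matrix(vals * (i + 1), f"r{i}") for i in range(3)]
        scaled = [make_matrix(m.values * 37.0, m.replicate_id) for m in mats]
        a = aggregate_replicates(mats, normalized=True)
        b = aggregate_replicates(scaled, normalized=True)
        np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)


class TestBootstrapCI:
    def test_zero_variance_collapses_interval(self):
        mats = [make_matrix(np.ones((8, 20))) for _ in range(3)]
        agg = bootstrap_ci(mats, iterations=100, seed=0, normalized=False)
        np.testing.assert_allclose(agg.ci_low, agg.mean)
        np.testing.assert_allclose(agg.ci_high, agg.mean)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(2)
        mats = [make_matrix(rng.random((30, 20)) + 0.1, f"r{i}") for i in range(3)]
        a = bootstrap_ci(mats, iterations=200, seed=42)
        b = bootstrap_ci(mats, iterations=200, seed=42)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_interval_brackets_mean_on_iid_data(self):
        rng = np.random.default_rng(3)
        mats = [make_matrix(rng.normal(1.0, 0.2, (50, 20)), f"r{i}")
                for i in range(3)]
        agg = bootstrap_ci(mats, iterations=500, seed=1, normalized=False)
        assert np.all(agg.ci_low <= agg.mean + 1e-9)
        assert np.all(agg.ci_high >= agg.mean - 1e-9)

    def test_width_shrinks_with_locations(self):
        """CI width scales roughly like 1/sqrt(n_locations)."""
        def width(n, seed):
            rng = np.random.default_rng(seed)
            mats = [make_matrix(rng.normal(1.0, 0.5, (n, 20)), f"r{i}")
                    for i in range(3)]
            agg = bootstrap_ci(mats, iterations=400, seed=seed, normalized=False)
            return float(np.mean(agg.ci_high - agg.ci_low))

        w50 = np.mean([width(50, s) for s in range(5)])
        w200 = np.mean([width(200, s) for s in range(5)])
        assert w200 < w50 / 1.5  # expect ~ /2


class TestEmpiricalPvalue:
    def test_identical_zero_variance_gives_p_one(self):
        mats = [make_matrix(np.ones((8, 20))) for _ in range(3)]
        test = empirical_pvalue(mats, mats, iterations=100, seed=0, normalized=False)
        assert test.p == 1.0
        assert test.observed_diff == 0.0

    def test_p_respects_smoothing_floor(self):
        a = [make_matrix(np.full((8, 20), 5.0)) for _ in range(3)]
        b = [make_matrix(np.ones((8, 20))) for _ in range(3)]
        test = empirical_pvalue(a, b, iterations=99, seed=0, normalized=False)
        assert test.p >= 1 / 100
        assert test.p == pytest.approx(2 / 100)

    def test_default_position_is_center_bin(self):
        mats = [make_matrix(np.ones((4, 20))) for _ in range(2)]
        test = empirical_pvalue(mats, mats, iterations=10, seed=0, normalized=False)
        assert test.position == 10


class TestSemProfile:
    def test_two_replicate_half_width(self):
        reps = [make_matrix(np.full((4, 20), 1.0)), make_matrix(np.full((4, 20), 3.0))]
        agg = sem_profile(reps)
        np.testing.assert_allclose(agg.mean, 2.0)
        np.testing.assert_allclose(agg.ci_high - agg.mean, 1.96)

    def test_identical_replicates_zero_width(self):
        reps = [make_matrix(np.ones((4, 20))) for _ in range(3)]
        agg = sem_profile(reps)
        np.testing.assert_allclose(agg.ci_high, agg.ci_low)

    def test_half_width_over_sem_is_196(self):
        rng = np.random.default_rng(9)
        reps = [make_matrix(rng.random((6, 20)), f"r{i}") for i in range(4)]
        agg = sem_profile(reps)
        profs = np.stack([m.values.mean(axis=0) for m in reps])
        sem = profs.std(axis=0, ddof=1) / np.sqrt(4)
        np.testing.assert_allclose((agg.ci_high - agg.mean) / sem, 1.96)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            sem_profile([make_matrix(np.ones((4, 20)))])
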