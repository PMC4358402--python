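import math

import numpy as np
import pytest

from conftest import make_track, naive_mean

from dreamchip.annotations import GeneModel, GenomicInterval, RegionSpec
from dreamchip.errors import ConfigError, DataError
from dreamchip.signal import (
    average_profile,
    kmeans_rows,
    mean_over,
    profile_matrix,
    read_track,
    zscore,
)


class TestReadTrack:
    def test_bedgraph_parse(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrI\t0\t100\t2.0\nchrI\t100\t200\t4.0\n")
        t = read_track(p)
        starts, ends, values = t.runs["chrI"]
        assert list(starts) == [0, 100]
        assert list(values) == [2.0, 4.0]

    def test_fixedstep_wiggle_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chrI start=1 step=50 span=50\n1\n2\n")
        t = read_track(p)
        starts, ends, values = t.runs["chrI"]
        assert list(starts) == [0, 50]
        assert list(ends) == [50, 100]
        assert list(values) == [1.0, 2.0]

    def test_variablestep_wiggle(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("variableStep chrom=chrII span=10\n11\t3.5\n31\t1.5\n")
        t = read_track(p)
        starts, ends, values = t.runs["chrII"]
        assert list(starts) == [10, 30]
        assert list(values) == [3.5, 1.5]

    def test_overlapping_intervals_error_names_pair(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrI\t0\t100\t1\nchrI\t50\t150\t2\n")
        with pytest.raises(DataError, match=r"\[0,100\).*\[50,150\)"):
            read_track(p)


class TestZscore:
    def test_three_unit_runs(self):
        t = make_track([(0, 1, 1.0), (1, 2, 2.0), (2, 3, 3.0)])
        z = zscore(t)
        vals = z.runs["chrI"][2]
        expect = 1.0 / math.sqrt(2 / 3)
        assert vals == pytest.approx([-expect, 0.0, expect], abs=1e-9)
        assert z.mu == pytest.approx(2.0)

    def test_constant_track_warns_and_zeroes(self):
        t = make_track([(0, 10, 5.0), (10, 20, 5.0)])
        with pytest.warns(UserWarning, match="sigma"):
            z = zscore(t)
        assert np.all(z.runs["chrI"][2] == 0)

    def test_mean_is_coverage_length_weighted(self):
        t = make_track([(0, 10, 4.0), (10, 40, 0.0)])
        z = zscore(t)
        assert z.mu == pytest.approx(1.0)  # not the unweighted 2.0

    def test_zscored_moments_are_standard(self):
        rng = np.random.default_rng(0)
        t = make_track(
            [(i * 10, i * 10 + int(rng.integers(1, 10)), float(v))
             for i, v in enumerate(rng.normal(3, 2, 50))]
        )
        z = zscore(t)
        mu, sd = z.weighted_moments()
        assert abs(mu) < 1e-6 and abs(sd - 1) < 1e-6

    def test_zscore_of_zscore_is_identity(self):
        t = make_track([(0, 5, 1.0), (5, 9, 7.0), (20, 30, -2.0)])
        z1 = zscore(t)
        z2 = zscore(z1)
        for a, b in zip(z1.runs["chrI"][2], z2.runs["chrI"][2]):
            assert a == pytest.approx(b, abs=1e-9)

    def test_log2_floor_applied_before_transform(self):
        t = make_track([(0, 10, 0.0), (10, 20, 4.0)])
        z = zscore(t, log2_first=True, log_floor=0.25)
        # log2 values: -2 and 2 -> z-scores are +-1
        assert z.runs["chrI"][2] == pytest.approx([-1.0, 1.0])

    def test_empty_track_errors(self):
        with pytest.raises(DataError):
            zscore(make_track([(0, 1, 1.0)]))


class TestMeanOver:
    def test_constant_region(self):
        t = make_track([(0, 1000, 5.0)])
        assert mean_over(t, GenomicInterval("chrI", 100, 200)) == 5.0

    def test_halfway_between_two_values(self):
        t = make_track([(0, 100, 2.0), (100, 200, 4.0)])
        assert mean_over(t, GenomicInterval("chrI", 50, 150)) == 3.0

    def test_low_coverage_returns_missing(self):
        t = make_track([(0, 10, 5.0)])
        m = mean_over(t, GenomicInterval("chrI", 0, 100))  # 10% covered
        assert math.isnan(m)

    def test_uncovered_positions_excluded_from_denominator(self):
        t = make_track([(0, 50, 2.0), (80, 100, 8.0)])
        m = mean_over(t, GenomicInterval("chrI", 0, 100))
        assert m == pytest.approx((50 * 2 + 20 * 8) / 70)

    def test_matches_per_base_oracle_on_random_tracks(self, random_toy_track):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = random_toy_track(rng)
            for _ in range(50):
                s = int(rng.integers(0, 950))
                e = s + int(rng.integers(1, 50))
                got = mean_over(t, GenomicInterval("chrI", s, e))
                want = naive_mean(t, "chrI", s, e, length=1000)
                assert (math.isnan(got) and math.isnan(want)) or got == (
                    pytest.approx(want, abs=1e-9)
                )


class TestProfileMatrix:
    SPEC = RegionSpec("tss", upstream_bp=100, downstream_bp=200)

    def test_flat_track_gives_constant_cells(self):
        t = make_track([(0, 5000, 3.0)])
        genes = [GeneModel("a", "chrI", 1000, 2000, "+"),
                 GeneModel("b", "chrI", 3000, 4000, "-")]
        pm = profile_matrix(t, genes, self.SPEC, bin_size=10)
        assert np.all(pm.data.to_numpy() == 3.0)
        assert list(pm.data.columns)[0] == -100

    def test_tss_bump_peaks_at_offset_zero(self):
        t = make_track([(0, 1000, 1.0), (1000, 1010, 9.0), (1010, 5000, 1.0)])
        g = GeneModel("a", "chrI", 1000, 2000, "+")
        pm = profile_matrix(t, [g], self.SPEC, bin_size=10)
        assert pm.data.loc["a"].idxmax() == 0

    def test_minus_strand_row_mirrors_plus_strand(self):
        # bump just downstream of each gene's TSS, strand-relative
        t = make_track(
            [(0, 1000, 1.0), (1000, 1010, 9.0), (1010, 3990, 1.0),
             (3990, 4000, 9.0), (4000, 5000, 1.0)]
        )
        gp = GeneModel("p", "chrI", 1000, 2000, "+")
        gm = GeneModel("m", "chrI", 3000, 4000, "-")
        pm = profile_matrix(t, [gp, gm], self.SPEC, bin_size=10)
        assert np.allclose(pm.data.loc["p"], pm.data.loc["m"])

    def test_rows_equal_mean_over_bin_by_bin(self, random_toy_track):
        rng = np.random.default_rng(7)
        t = random_toy_track(rng)
        g = GeneModel("a", "chrI", 400, 800, "+")
        pm = profile_matrix(t, [g], self.SPEC, bin_size=10)
        for off in pm.data.columns:
            s = 400 + off
            want = mean_over(t, GenomicInterval("chrI", s, s + 10))
            got = pm.data.loc["a", off]
            assert (math.isnan(got) and math.isnan(want)) or got == (
                pytest.approx(want, abs=1e-12)
            )

    def test_scaled_body_layout_and_short_gene_exclusion(self):
        t = make_track([(0, 10_000, 2.0)])
        spec = RegionSpec("tss_and_tts", upstream_bp=100, downstream_bp=100,
                          scaled_body_bins=10)
        genes = [GeneModel("ok", "chrI", 1000, 2000, "+"),
                 GeneModel("tiny", "chrI", 5000, 5005, "+")]
        pm = profile_matrix(t, genes, spec, bin_size=10)
        assert pm.excluded == {"tiny": "short_gene"}
        assert pm.data.shape == (1, 10 + 10 + 10)
        assert np.all(pm.data.to_numpy() == 2.0)

    def test_bin_size_must_divide_flanks(self):
        t = make_track([(0, 100, 1.0)])
        with pytest.raises(ConfigError):
            profile_matrix(t, [], RegionSpec("tss", 105, 200), bin_size=10)


class TestAverageProfile:
    def test_row_mean(self):
        t = make_track([(0, 200, 0.0), (200, 400, 2.0)])
        genes = [GeneModel("a", "chrI", 100, 300, "+"),
                 GeneModel("b", "chrI", 300, 350, "+")]
        spec = RegionSpec("tss", upstream_bp=100, downstream_bp=100)
        pm = profile_matrix(t, genes, spec, bin_size=100)
        avg = average_profile(pm)
        assert list(avg["mean"]) == [1.0, 1.0]
        assert list(avg["n"]) == [2, 2]

    def test_missing_cells_reduce_n(self):
        t = make_track([(0, 140, 1.0), (200, 400, 3.0)])
        genes = [GeneModel("a", "chrI", 100, 300, "+"),
                 GeneModel("b", "chrI", 300, 350, "+")]
        spec = RegionSpec("tss", upstream_bp=100, downstream_bp=100)
        pm = profile_matrix(t, genes, spec, bin_size=100)
        avg = average_profile(pm)
        # gene a's downstream bin [100,200) is 40% covered -> missing,
        # gene b's [300,400) is fully covered; both upstream bins covered
        assert avg.loc[0, "n"] == 1
        assert avg.loc[-100, "n"] == 2

    def test_union_equals_weighted_mean_of_parts(self, random_toy_track):
        rng = np.random.default_rng(3)
        t = random_toy_track(rng, gap_prob=0.0)
        spec = RegionSpec("tss", upstream_bp=50, downstream_bp=50)
        set1 = [GeneModel(f"a{i}", "chrI", 100 + 60 * i, 160 + 60 * i, "+")
                for i in range(3)]
        set2 = [GeneModel(f"b{i}", "chrI", 500 + 60 * i, 560 + 60 * i, "-")
                for i in range(5)]
        a1 = average_profile(profile_matrix(t, set1, spec, bin_size=10))
        a2 = average_profile(profile_matrix(t, set2, spec, bin_size=10))
        au = average_profile(profile_matrix(t, set1 + set2, spec, bin_size=10))
        want = (a1["mean"] * a1["n"] + a2["mean"] * a2["n"]) / (
            a1["n"] + a2["n"]
        )
        assert np.allclose(au["mean"], want)

    def test_empty_matrix_errors(self):
        t = make_track([(0, 100, 1.0)])
        pm = profile_matrix(t, [], RegionSpec("tss", 50, 50), bin_size=10)
        with pytest.raises(DataError):
            average_profile(pm)


class TestKmeansRows:
    def _matrix(self, levels, n_each, rng):
        t = make_track([(0, 10, 1.0)])
        spec = RegionSpec("tss", upstream_bp=50, downstream_bp=50)
        pm = profile_matrix(t, [], spec, bin_size=10)
        import pandas as pd

        rows, idx = [], []
        for li, lv in enumerate(levels):
            for j in range(n_each):
                rows.append(lv + rng.normal(0, 0.05, 10))
                idx.append(f"c{li}_{j}")
        pm.data = pd.DataFrame(rows, index=idx, columns=pm.data.columns)
        return pm

    def test_well_separated_levels_recovered_in_descending_order(self):
        rng = np.random.default_rng(0)
        pm = self._matrix([10.0, 5.0, 0.0], 20, rng)
        labels = kmeans_rows(pm, k=3, seed=1)
        for li, expect in enumerate([1, 2, 3]):
            got = labels[[f"c{li}_{j}" for j in range(20)]]
            assert (got == expect).all()

    def test_k_equals_one_labels_everything_one(self):
        rng = np.random.default_rng(0)
        pm = self._matrix([1.0], 5, rng)
        assert set(kmeans_rows(pm, k=1, seed=0)) == {1}

    def test_identical_rows_still_partition(self):
        rng = np.random.default_rng(0)
        pm = self._matrix([2.0], 6, rng)
        pm.data.iloc[:, :] = 2.0
        labels = kmeans_rows(pm, k=2, seed=0)
        assert len(labels) == 6 and set(labels) <= {1, 2}

    def test_k_larger_than_rows_errors(self):
        rng = np.random.default_rng(0)
        pm = self._matrix([1.0], 2, rng)
        with pytest.raises(ConfigError):
            kmeans_rows(pm, k=5, seed=0)
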