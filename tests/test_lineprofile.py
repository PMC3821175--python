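"""Colocalization along line profiles: threshold rule, peak calling,
nearest-peak matching, paired/shuffled pixel correlations, raster
extraction — checked against hand arithmetic and generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synaptiq.data import LineProfilePair
from synaptiq.synthgen import ProfileParams, gen_profile_pair
from synaptiq.lineprofile import (
    estimate_threshold, detect_peaks, PeakCaller, nearest_peak_distances,
    paired_correlation, shuffled_correlation, analyze_pair, summarize_coloc,
    extract_line_profile, PeakSet,
)


def gauss_profile(centers, amps, sigma=300.0, length=20000.0, pixel=100.0,
                  baseline=2.0):
    x = np.arange(0, length + pixel / 2, pixel)
    y = np.full_like(x, baseline)
    for c, a in zip(centers, amps):
        y = y + a * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return x, y


class TestThreshold:
    def test_constant_positive_trace(self):
        x = np.arange(11) * 100.0
        assert estimate_threshold(x, np.full(11, 7.0)) == pytest.approx(7.0)

    def test_worked_example_exact(self):
        # floor 2 at index 1; 600 nm window covers indices 0-4
        x = np.arange(11) * 100.0
        y = np.array([0, 2, 2, 2, 2, 2, 2, 10, 30, 10, 2], dtype=float)
        expected = 2.0 + 3.5 * np.std([0, 2, 2, 2, 2], ddof=1)
        assert estimate_threshold(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(mult=st.floats(0.5, 10.0))
    def test_monotone_in_sd_multiplier(self, mult):
        x = np.arange(20) * 100.0
        y = np.abs(np.sin(x / 300.0)) + 1.0
        t1 = estimate_threshold(x, y, sd_multiplier=mult)
        t2 = estimate_threshold(x, y, sd_multiplier=2 * mult)
        assert t2 > t1  # SD > 0 here

    def test_invariant_to_far_punctum(self):
        x, y = gauss_profile([15000.0], [100.0])
        base = estimate_threshold(x, y)
        x2, y2 = gauss_profile([15000.0, 18000.0], [100.0, 200.0])
        assert estimate_threshold(x2, y2) == pytest.approx(base)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="non-zero"):
            estimate_threshold(np.arange(5) * 100.0, np.zeros(5))


class TestDetectPeaks:
    def test_single_gaussian_center(self):
        x, y = gauss_profile([5000.0], [100.0])
        peaks = detect_peaks(x, y, threshold=10.0)
        assert peaks.n == 1
        assert abs(peaks.positions_nm[0] - 5000.0) <= 100.0

    def test_two_gaussians_one_micron_apart(self):
        x, y = gauss_profile([5000.0, 6000.0], [100.0, 80.0])
        peaks = detect_peaks(x, y, threshold=10.0)
        assert peaks.n == 2

    def test_plateau_centroid(self):
        x = np.arange(7) * 100.0
        y = np.array([0, 1, 5, 5, 5, 1, 0], dtype=float)
        peaks = detect_peaks(x, y, threshold=2.0)
        assert peaks.n == 1
        assert peaks.positions_nm[0] == pytest.approx(300.0)

    def test_merge_keeps_higher(self):
        x = np.arange(9) * 100.0
        y = np.array([0, 0, 5, 4, 8, 4, 0, 0, 0], dtype=float)
        peaks = detect_peaks(x, y, threshold=1.0, min_separation_nm=300.0)
        assert peaks.n == 1
        assert peaks.heights[0] == 8.0

    def test_recall_on_generator_truth(self):
        # SNR 10 synthetic profile: every ground-truth punctum recovered
        p = ProfileParams(n_puncta=10, noise_sd=5.0,
                          punctum_amp_range=(50.0, 200.0))
        pair, truth = gen_profile_pair(p, 21)
        caller = PeakCaller(channel="ch1").fit(pair.position_nm, pair.ch1)
        found = 0
        for c in truth["ch1_centers_nm"]:
            if np.min(np.abs(caller.peaks_.positions_nm - c)) <= 200.0:
                found += 1
        assert found == 10

    def test_empty_peakset_allowed(self):
        x = np.arange(10) * 100.0
        peaks = detect_peaks(x, np.ones(10), threshold=5.0)
        assert peaks.n == 0


class TestNearestPeakDistances:
    def _ps(self, positions):
        pos = np.asarray(positions, dtype=float)
        return PeakSet("ch", pos, np.full(pos.size, 10.0), 0.0)

    def test_identical_sets_zero(self):
        res = nearest_peak_distances(self._ps([100, 500]), self._ps([100, 500]))
        assert np.allclose(res.distances_nm, 0.0)

    def test_uniform_shift(self):
        res = nearest_peak_distances(
            self._ps([1000, 3000, 5000]), self._ps([1300, 3300, 5300])
        )
        assert np.allclose(res.distances_nm, 300.0)

    def test_matching_cutoff(self):
        # ref {0, 2000}, other {100, 950}: only the 100 nm pair matches
        res = nearest_peak_distances(self._ps([0, 2000]), self._ps([100, 950]))
        assert list(res.distances_nm) == [100.0]
        assert list(res.unmatched_ref_idx) == [1]

    def test_directional(self):
        a, b = self._ps([0.0]), self._ps([100.0, 300.0])
        assert nearest_peak_distances(a, b).n_matched == 1
        assert nearest_peak_distances(b, a).n_matched == 2


class TestPairedCorrelation:
    def _pair(self, ch1, ch2):
        x = np.arange(len(ch1)) * 100.0
        return LineProfilePair("a", x, np.asarray(ch1, float),
                               np.asarray(ch2, float))

    def test_affine_relation_r1(self):
        ch1 = np.abs(np.sin(np.arange(50) / 3.0)) + 1
        pair = self._pair(ch1, 2 * ch1 + 5)
        assert paired_correlation(pair) == pytest.approx(1.0)

    def test_anticorrelated_r_minus1(self):
        ch1 = np.abs(np.sin(np.arange(50) / 3.0)) + 1
        pair = self._pair(ch1, 10 - ch1)
        assert paired_correlation(pair) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        pair = self._pair(rng.uniform(1, 2, 500), rng.uniform(1, 2, 500))
        assert abs(paired_correlation(pair)) < 0.15

    def test_channel_swap_invariance(self):
        pair, _ = gen_profile_pair(ProfileParams(), 3)
        swapped = LineProfilePair("a", pair.position_nm, pair.ch2, pair.ch1)
        assert paired_correlation(pair) == pytest.approx(
            paired_correlation(swapped))

    def test_too_few_retained_errors(self):
        pair = self._pair(np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            paired_correlation(pair, 5.0, 5.0, retain="either")

    def test_zero_variance_errors(self):
        pair = self._pair(np.ones(10), np.arange(10) + 1.0)
        with pytest.raises(ValueError):
            paired_correlation(pair)


class TestShuffledCorrelation:
    def test_counting_all_ordered_pairs(self):
        pairs = [gen_profile_pair(ProfileParams(), s)[0] for s in range(3)]
        rs, _ = shuffled_correlation(pairs)
        assert len(rs) == 6

    def test_duplicated_animals_equal_paired(self):
        pair, _ = gen_profile_pair(ProfileParams(), 5)
        clones = [
            LineProfilePair(f"a{i}", pair.position_nm, pair.ch1, pair.ch2)
            for i in range(3)
        ]
        rs, mean_r = shuffled_correlation(clones)
        assert mean_r == pytest.approx(paired_correlation(pair))

    def test_independent_animals_near_zero_mean(self):
        # the between-animal null: mean shuffled r is nearly zero while the
        # paired correlation of colocalized channels stays high
        pairs = [gen_profile_pair(ProfileParams(), 2000 + s, f"an{s}")[0]
                 for s in range(10)]
        rs, mean_r = shuffled_correlation(pairs)
        assert len(rs) == 90
        assert abs(mean_r) < 0.1
        paired = np.mean([paired_correlation(p) for p in pairs])
        assert paired > 5 * abs(mean_r)

    def test_single_animal_errors(self):
        pair, _ = gen_profile_pair(ProfileParams(), 5)
        with pytest.raises(ValueError):
            shuffled_correlation([pair])

    def test_random_scheme_seeded(self):
        pairs = [gen_profile_pair(ProfileParams(), s)[0] for s in range(4)]
        rs1, _ = shuffled_correlation(pairs, scheme="random", seed=1, n_random=10)
        rs2, _ = shuffled_correlation(pairs, scheme="random", seed=1, n_random=10)
        assert rs1 == rs2


class TestSummarize:
    def test_single_animal_sem_undefined(self):
        pair, _ = gen_profile_pair(ProfileParams(), 1)
        df = summarize_coloc([analyze_pair(pair)])
        assert df.loc[0, "n_animals"] == 1
        assert np.isnan(df.loc[0, "paired_r_sem"])

    def test_offset_recovery_with_spread(self):
        # parameter recovery: offset 300 +- 50 nm over 12 animals
        results = []
        for i in range(12):
            p = ProfileParams(offset_mean_nm=300.0, offset_sd_nm=50.0)
            pair, _ = gen_profile_pair(p, 4000 + i, f"an{i}")
            results.append(analyze_pair(pair))
        df = summarize_coloc(results)
        mean, sem = df.loc[0, "mean_distance_nm_mean"], df.loc[0, "mean_distance_nm_sem"]
        assert abs(mean - 300.0) < 3 * sem + 1e-9


class TestExtractLineProfile:
    def test_constant_raster(self):
        raster = np.full((2, 30, 30), 7.0)
        poly = np.array([[15.0, 2.0], [15.0, 27.0]])
        pair = extract_line_profile(raster, poly, width_pixels=6)
        assert np.allclose(pair.ch1, 7.0) and np.allclose(pair.ch2, 7.0)

    def test_direct_averaging_oracle_20x20(self, rng):
        raster = rng.uniform(0, 100, (2, 20, 20))
        row = 10.0
        poly = np.array([[row, 4.0], [row, 15.0]])
        pair = extract_line_profile(raster, poly, width_pixels=6)
        # independent oracle: mean of bilinear samples at rows 10 +- offsets
        offsets = np.arange(6) - 2.5
        for k, col in enumerate(np.arange(4.0, 16.0)):
            vals = []
            for off in offsets:
                r = row + off
                r0 = int(np.floor(r))
                frac = r - r0
                vals.append((1 - frac) * raster[0, r0, int(col)]
                            + frac * raster[0, min(r0 + 1, 19), int(col)])
            assert pair.ch1[k] == pytest.approx(np.mean(vals))

    def test_width_6_vs_8_same_ridge_position(self):
        x = np.arange(40)
        ridge = np.exp(-((x - 20.0) ** 2) / 18.0)
        raster = np.tile(ridge, (2, 40, 1))
        poly = np.array([[20.0, 5.0], [20.0, 35.0]])
        p6 = extract_line_profile(raster, poly, width_pixels=6)
        p8 = extract_line_profile(raster, poly, width_pixels=8)
        assert np.argmax(p6.ch1) == np.argmax(p8.ch1)

    def test_polyline_exit_names_vertex(self):
        raster = np.zeros((2, 10, 10))
        poly = np.array([[5.0, 5.0], [5.0, 25.0]])
        with pytest.raises(ValueError, match="vertex 1"):
            extract_line_profile(raster, poly)

    def test_band_exit_detected(self):
        raster = np.zeros((2, 10, 30))
        poly = np.array([[1.0, 2.0], [1.0, 27.0]])  # band extends above row 0
        with pytest.raises(ValueError, match="exits"):
            extract_line_profile(raster, poly, width_pixels=6)
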