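"""Preprocessing: smoothing/baseline/normalization oracles, alignment
recovery, peak detection, replicate merge and matrix exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painprint.spectra import Spectrum
from painprint.preprocess import (ParameterError, PeakList, PreprocessConfig,
                                  align_spectra, detect_peaks,
                                  exclude_matrix_peaks, merge_replicates,
                                  normalize_max100, preprocess_cohort,
                                  smooth_savgol, subtract_baseline_loess)


def brute_force_savgol(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Independent Savitzky-Golay oracle: explicit least-squares polynomial
    fit in every centred window, evaluated at the centre (interior points)."""
    half = window // 2
    out = np.full_like(np.asarray(y, float), np.nan)
    x = np.arange(-half, half + 1)
    for c in range(half, len(y) - half):
        coeffs = np.polynomial.polynomial.polyfit(x, y[c - half:c + half + 1], order)
        out[c] = coeffs[0]   # polynomial evaluated at window centre (x=0)
    return out


def gaussian_peak_spectrum(grid, positions, heights, width=4.0, **kw):
    inten = np.zeros_like(grid)
    for p, h in zip(positions, heights):
        inten += h * np.exp(-0.5 * ((grid - p) / width) ** 2)
    return Spectrum(grid, inten, **kw)


class TestSavgol:
    def test_polynomial_reproduced_exactly(self):
        x = np.arange(200.0)
        y = 3.0 + 0.5 * x - 0.01 * x ** 2
        s = Spectrum(x + 1.0, y - y.min() + 1.0)
        out = smooth_savgol(s, window=7, order=2)
        np.testing.assert_allclose(out.intensity, s.intensity, rtol=1e-9)

    def test_constant_preserved(self):
        s = Spectrum(np.arange(50.0) + 1, np.full(50, 7.0))
        np.testing.assert_allclose(smooth_savgol(s, 9, 2).intensity, 7.0)

    def test_matches_brute_force_oracle(self, rng):
        y = rng.exponential(10.0, 101)
        s = Spectrum(np.arange(101.0) + 1, y)
        out = smooth_savgol(s, window=5, order=2).intensity
        oracle = brute_force_savgol(y, 5, 2)
        interior = ~np.isnan(oracle)
        np.testing.assert_allclose(out[interior], oracle[interior],
                                   rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("window,order", [(8, 2), (5, 5), (999, 2)])
    def test_invalid_parameters_rejected(self, window, order):
        s = Spectrum(np.arange(100.0) + 1, np.ones(100))
        with pytest.raises(ParameterError):
            smooth_savgol(s, window, order)

    def test_appends_one_log_entry(self):
        s = Spectrum(np.arange(20.0) + 1, np.ones(20))
        assert len(smooth_savgol(s, 5, 2).processing_log) == 1


class TestLoessBaseline:
    def test_pure_baseline_removed(self):
        grid = np.arange(0.0, 5000.0, 5.0)
        base = 40.0 * np.exp(-grid / 1500.0)
        s = Spectrum(grid + 1, base)
        out = subtract_baseline_loess(s, span=0.1)
        assert out.intensity.max() < 0.05 * base.max()

    def test_narrow_peaks_survive(self):
        grid = np.arange(0.0, 3000.0, 2.0)
        s = gaussian_peak_spectrum(grid + 1, [500.0, 1500.0, 2500.0],
                                   [80.0, 50.0, 60.0])
        out = subtract_baseline_loess(s, span=0.3)
        for p, h in [(500.0, 80.0), (1500.0, 50.0), (2500.0, 60.0)]:
            apex = out.intensity[np.argmin(np.abs(out.mz - (p + 1)))]
            assert apex == pytest.approx(h, rel=0.10)

    def test_all_zero_stays_zero(self):
        s = Spectrum(np.arange(100.0) + 1, np.zeros(100))
        np.testing.assert_array_equal(subtract_baseline_loess(s, 0.2).intensity, 0.0)

    def test_invalid_span_rejected(self):
        s = Spectrum(np.arange(100.0) + 1, np.ones(100))
        with pytest.raises(ParameterError):
            subtract_baseline_loess(s, span=1.5)


class TestNormalize:
    def test_definition(self):
        s = Spectrum(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 8.0]))
        np.testing.assert_allclose(normalize_max100(s).intensity, [25.0, 50.0, 100.0])

    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_max_is_100_and_idempotent(self, vals):
        s = Spectrum(np.arange(len(vals), dtype=float) + 1, np.asarray(vals))
        once = normalize_max100(s)
        assert once.intensity.max() == pytest.approx(100.0, abs=1e-9)
        twice = normalize_max100(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_all_zero_rejected(self):
        from painprint.preprocess import NormalizationError
        s = Spectrum(np.array([1.0, 2.0]), np.zeros(2))
        with pytest.raises(NormalizationError):
            normalize_max100(s)


class TestAlignment:
    def _reference(self):
        grid = np.arange(0.0, 4000.0, 1.0)
        pos = np.array([300.0, 800.0, 1400.0, 2100.0, 2900.0, 3500.0])
        return gaussian_peak_spectrum(grid + 0.5, pos, np.full(6, 50.0),
                                      sample_id="ref")

    def test_constructed_shift_recovered(self):
        ref = self._reference()
        shifted = ref.copy_with(mz=ref.mz + 2.0)
        out = align_spectra([ref, shifted, ref.copy_with()], tolerance=3.0)
        rec = out[1].mz[0] - shifted.mz[0]
        assert rec == pytest.approx(-2.0, abs=1.0)   # within one grid step

    def test_identical_spectra_zero_shift(self):
        ref = self._reference()
        out = align_spectra([ref, ref.copy_with(), ref.copy_with()], tolerance=3.0)
        for s in out:
            np.testing.assert_array_equal(s.mz, ref.mz)

    def test_shift_beyond_tolerance_keeps_identity(self):
        ref = self._reference()
        far = ref.copy_with(mz=ref.mz + 50.0)
        out = align_spectra([ref, far], tolerance=3.0)
        # no landmark can match within 1.5 Da at any |shift| <= 3 -> identity
        np.testing.assert_array_equal(out[1].mz, far.mz)


class TestDetectPeaks:
    def test_single_peak_on_noise(self, rng):
        grid = np.arange(0.0, 2000.0, 2.0)
        s = gaussian_peak_spectrum(grid + 1, [1000.0], [100.0])
        s = s.copy_with(intensity=np.clip(s.intensity + rng.normal(0, 1.0, grid.shape),
                                          0, None))
        pl = detect_peaks(s, snr_threshold=5.0)
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(1001.0, abs=2.0)

    def test_flat_zero_gives_empty(self):
        s = Spectrum(np.arange(100.0) + 1, np.zeros(100))
        assert len(detect_peaks(s, 3.0)) == 0

    def test_two_peaks_ascending(self):
        grid = np.arange(0.0, 500.0, 1.0)
        s = gaussian_peak_spectrum(grid + 1, [200.0, 250.0], [50.0, 80.0], width=3.0)
        pl = detect_peaks(s, 3.0)
        assert len(pl) == 2
        assert pl.mz[0] < pl.mz[1]


class TestMergeReplicates:
    def _pl(self, mz, inten, sid="s1"):
        return PeakList(np.asarray(mz, float), np.asarray(inten, float), sample_id=sid)

    def test_identical_lists_unchanged(self):
        pls = [self._pl([100, 200], [10, 20]) for _ in range(3)]
        out = merge_replicates(pls, tolerance=0.5)
        np.testing.assert_allclose(out.mz, [100, 200])
        np.testing.assert_allclose(out.intensity, [10, 20])
        assert out.n_replicates_merged == 3

    def test_minority_peak_dropped(self):
        pls = [self._pl([100, 500], [10, 5]),
               self._pl([100], [12]),
               self._pl([100], [11])]
        out = merge_replicates(pls, tolerance=0.5)
        np.testing.assert_allclose(out.mz, [100])

    def test_hand_computed_merge(self):
        pls = [self._pl([500.0], [30.0]), self._pl([500.2], [33.0]),
               self._pl([499.9], [27.0])]
        out = merge_replicates(pls, tolerance=0.5)
        assert len(out) == 1
        assert out.mz[0] == pytest.approx(np.mean([500.0, 500.2, 499.9]))
        assert out.intensity[0] == pytest.approx(30.0)

    def test_mixed_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            merge_replicates([self._pl([1], [1], "a"), self._pl([1], [1], "b")])


class TestMatrixExclusion:
    def _pl(self, mz, sid="s1"):
        return PeakList(np.asarray(mz, float), np.ones(len(mz)), sample_id=sid)

    def test_hand_case(self):
        out = exclude_matrix_peaks(self._pl([300.0, 600.0]),
                                   [self._pl([600.1], "b")], tolerance=0.5)
        np.testing.assert_allclose(out.mz, [300.0])

    def test_disjoint_blank_unchanged(self):
        out = exclude_matrix_peaks(self._pl([300.0]), [self._pl([900.0], "b")], 0.5)
        np.testing.assert_allclose(out.mz, [300.0])

    def test_sample_identical_to_blank_emptied(self):
        out = exclude_matrix_peaks(self._pl([300.0, 600.0]),
                                   [self._pl([300.0, 600.0], "b")], 0.5)
        assert len(out) == 0

    def test_idempotent(self):
        sample = self._pl([300.0, 600.0, 900.0])
        blanks = [self._pl([600.2], "b")]
        once = exclude_matrix_peaks(sample, blanks, 0.5)
        twice = exclude_matrix_peaks(once, blanks, 0.5)
        np.testing.assert_array_equal(once.mz, twice.mz)

    def test_empty_blank_set_warns_noop(self):
        sample = self._pl([300.0])
        with pytest.warns(UserWarning, match="skipped"):
            out = exclude_matrix_peaks(sample, [], 0.5)
        np.testing.assert_array_equal(out.mz, sample.mz)


class TestPipelineOrder:
    def test_each_stage_appends_one_log_entry(self):
        grid = np.arange(0.0, 3000.0, 2.0)
        s = gaussian_peak_spectrum(grid + 1, [500.0, 1500.0], [80.0, 60.0],
                                   sample_id="s1")
        out = normalize_max100(subtract_baseline_loess(smooth_savgol(s, 9, 2), 0.1))
        steps = [e.split("(")[0] for e in out.processing_log]
        assert steps == ["savgol", "loess_baseline", "normalize_max100"]

    def test_ground_truth_peaks_recovered(self, small_cohort):
        """>=90% of library peaks whose rendered apex clears 3x the noise
        level are detected within the alignment tolerance."""
        spectra, blanks, _, truth = small_cohort
        cfg = PreprocessConfig()
        peaklists, _ = preprocess_cohort(spectra, blanks, cfg)
        from painprint.synthetic import peak_fwhm
        positions = truth.peak_positions
        fw = peak_fwhm(positions)
        # a truth peak only counts if it is clear of matrix-exclusion
        # windows and resolvable from its nearest library neighbour at
        # the simulated TOF peak width
        clear = np.array([np.min(np.abs(truth.matrix_peak_positions - p)) >
                          cfg.blank_match_tolerance + f
                          for p, f in zip(positions, fw)])
        nn = np.array([np.sort(np.abs(positions - p))[1] for p in positions])
        clear &= nn > 1.5 * fw
        raw_max: dict = {}
        for s in spectra:
            raw_max[s.sample_id] = max(raw_max.get(s.sample_id, 0.0),
                                       float(s.intensity.max()))
        recovered = []
        for sid, pl in peaklists.items():
            g = truth.labels[sid]
            heights = truth.base_intensities * truth.class_multipliers[g]
            # detectable = apex comfortably above the ~3-sigma relative
            # noise floor after base-peak normalization
            rel = heights / raw_max[sid] * 100.0
            detectable = clear & (rel > 5.0)
            if len(pl) == 0:
                recovered.append(0.0)
                continue
            d = np.array([np.min(np.abs(pl.mz - p)) for p in positions[detectable]])
            recovered.append(np.mean(d <= cfg.align_tolerance))
        assert np.mean(recovered) >= 0.90
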