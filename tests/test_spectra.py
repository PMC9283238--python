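"""Raman processing: each stage against closed forms and simulations."""

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_coeffs

from osteoquant.simulate import generate_spectrum, BAND_CENTERS
from osteoquant.spectra import (
    BandDefinition, DEFAULT_BANDS, FWHM_FACTOR, GridMismatchError,
    RamanSpectrum, SpectrumState, average_accumulations, band_area,
    compute_raman_parameters, correct_baseline, fit_phosphate_gaussian,
    process_spectrum, remove_cosmic_rays, smooth)

from conftest import make_spectrum


def gauss(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestAverageAccumulations:
    def test_mean_of_identical_inputs_is_identity(self, grid):
        s = make_spectrum(np.linspace(1, 5, grid.size), grid)
        avg = average_accumulations([s, s])
        np.testing.assert_array_equal(avg.intensity, s.intensity)

    def test_pointwise_arithmetic_mean(self):
        g = np.arange(64, dtype=float)
        a = make_spectrum(np.full(64, 0.0).copy() + np.arange(64) % 2 * 2, g)
        b = make_spectrum(np.full(64, 4.0) + np.arange(64) % 2 * 2, g)
        avg = average_accumulations([a, b])
        np.testing.assert_allclose(avg.intensity, (a.intensity + b.intensity) / 2)

    def test_standard_error_shrinks_as_sqrt_n(self, grid):
        # averaging 8 replicates must shrink pointwise noise by sqrt(8)
        rng = np.random.default_rng(0)
        base = gauss(grid, 100.0, 1000.0, 15.0) + 50.0
        means = []
        for _ in range(200):
            reps = [make_spectrum(base + rng.standard_normal(grid.size), grid)
                    for _ in range(8)]
            means.append(average_accumulations(reps).intensity)
        pointwise_sd = np.asarray(means).std(axis=0).mean()
        assert pointwise_sd == pytest.approx(1.0 / np.sqrt(8), rel=0.1)

    def test_grid_mismatch_and_empty_input(self, grid):
        s = make_spectrum(np.ones(grid.size), grid)
        other = make_spectrum(np.ones(grid.size), grid + 0.5)
        with pytest.raises(GridMismatchError):
            average_accumulations([s, other])
        with pytest.raises(ValueError):
            average_accumulations([])


class TestBaseline:
    def test_pure_polynomial_is_fully_removed(self, grid):
        u = (grid - grid[0]) / 1000.0
        coefs = 100 * np.array([5, -3, 2, 1, -0.5, 0.2, 0.3,
                                -0.1, 0.05, 0.1, -0.05, 0.02])
        y = npoly.polyval(u, coefs)
        y = y - y.min() + 10.0
        out = correct_baseline(make_spectrum(y, grid))
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.ptp(y)
        assert out.state == SpectrumState.BASELINED

    def test_flat_spectrum_maps_to_zero(self, grid):
        out = correct_baseline(make_spectrum(np.full(grid.size, 37.0), grid))
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_band_areas_survive_cubic_background(self, grid):
        # Gaussian triplet + cubic background: areas within 2% of the
        # clean-signal reference integrals
        bands = gauss(grid, 60, 959, 7.2) + gauss(grid, 10, 1070, 8.5) + \
            gauss(grid, 25, 1665, 19.0)
        u = (grid - grid[0]) / 1000.0
        background = 30 + 20 * u - 15 * u ** 2 + 10 * u ** 3
        s = make_spectrum(bands + background, grid)
        out = smooth(remove_cosmic_rays(correct_baseline(s)))
        clean = make_spectrum(bands, grid, SpectrumState.SMOOTHED)
        for band in DEFAULT_BANDS.values():
            assert band_area(out, band) == pytest.approx(
                band_area(clean, band), rel=0.02)

    def test_rank_deficiency_reports_order(self, grid):
        s = make_spectrum(np.ones(70), np.arange(70, dtype=float))
        with pytest.raises(ValueError, match="order"):
            correct_baseline(s, order=80)


class TestDespike:
    def _baselined(self, y, grid):
        return make_spectrum(y, grid, SpectrumState.BASELINED)

    def test_single_spike_removed_neighbours_untouched(self, grid):
        rng = np.random.default_rng(3)
        y = gauss(grid, 50, 1200, 15.0) + rng.normal(0, 0.5, grid.size)
        spiked = y.copy()
        spiked[400] += 50 * np.median(np.abs(np.diff(y, 2)))
        out = remove_cosmic_rays(self._baselined(spiked, grid))
        untouched = np.ones(grid.size, dtype=bool)
        untouched[400] = False
        np.testing.assert_array_equal(out.intensity[untouched], y[untouched])
        assert abs(out.intensity[400] - y[400]) < 3.0  # interpolation error

    def test_spike_free_spectrum_is_bit_identical(self, grid):
        rng = np.random.default_rng(4)
        y = gauss(grid, 50, 1000, 20.0) + rng.normal(0, 0.5, grid.size)
        out = remove_cosmic_rays(self._baselined(y, grid))
        np.testing.assert_array_equal(out.intensity, y)

    def test_genuine_band_is_preserved(self, grid):
        # a real 15 cm^-1 FWHM band must not be treated as a spike
        y = gauss(grid, 100, 959, 15.0 / FWHM_FACTOR)
        out = remove_cosmic_rays(self._baselined(y, grid))
        area_before = np.trapezoid(y, grid)
        area_after = np.trapezoid(out.intensity, grid)
        assert abs(area_after / area_before - 1) < 1e-3

    def test_idempotence(self, grid):
        rng = np.random.default_rng(5)
        y = gauss(grid, 60, 959, 8.0) + rng.normal(0, 1.0, grid.size)
        y[200] += 200.0
        once = remove_cosmic_rays(self._baselined(y, grid))
        twice = remove_cosmic_rays(
            self._baselined(once.intensity, grid)).intensity
        np.testing.assert_array_equal(twice, once.intensity)


class TestSmooth:
    def _despiked(self, y, grid):
        return make_spectrum(y, grid, SpectrumState.DESPIKED)

    def test_low_degree_polynomial_is_exact(self, grid):
        u = (grid - 1300) / 500
        y = 3 - 2 * u + 0.5 * u ** 2 + 4 * u ** 3
        out = smooth(self._despiked(y, grid), window=11, polyorder=4)
        np.testing.assert_allclose(out.intensity, y, rtol=1e-10, atol=1e-10)

    def test_white_noise_variance_reduction_matches_theory(self):
        # output variance of unit white noise equals the sum of squared
        # filter coefficients
        window, polyorder = 11, 4
        factor = float(np.sum(savgol_coeffs(window, polyorder) ** 2))
        g = np.arange(200, dtype=float)
        rng = np.random.default_rng(6)
        ratios = []
        for _ in range(500):
            y = rng.standard_normal(g.size)
            out = smooth(self._despiked(y, g), window, polyorder)
            ratios.append(out.intensity[20:-20].var())
        assert np.mean(ratios) == pytest.approx(factor, rel=0.1)

    def test_band_maximum_position_preserved(self, grid):
        y = gauss(grid, 80, 1234.0, 20.0 / FWHM_FACTOR)
        out = smooth(self._despiked(y, grid), window=5, polyorder=2)
        shift = abs(grid[np.argmax(out.intensity)] - grid[np.argmax(y)])
        assert shift <= 1.0

    def test_parameter_validation(self, grid):
        s = self._despiked(np.ones(grid.size), grid)
        with pytest.raises(ValueError):
            smooth(s, window=10, polyorder=4)
        with pytest.raises(ValueError):
            smooth(s, window=5, polyorder=5)
        with pytest.raises(ValueError):
            smooth(s, window=2001, polyorder=4)


class TestBandArea:
    def test_gaussian_closed_form(self, grid):
        sigma = 10.0
        s = make_spectrum(gauss(grid, 1.0, 959.0, sigma), grid,
                          SpectrumState.SMOOTHED)
        wide = BandDefinition("nu1_phosphate", (880.0, 1040.0))
        assert band_area(s, wide) == pytest.approx(
            sigma * np.sqrt(2 * np.pi), rel=0.005)

    def test_zero_spectrum_zero_area(self, grid):
        s = make_spectrum(np.zeros(grid.size), grid, SpectrumState.SMOOTHED)
        assert band_area(s, DEFAULT_BANDS["nu1_phosphate"]) == 0.0

    def test_window_isolates_one_of_two_bands(self, grid):
        only_a = gauss(grid, 2.0, 959.0, 8.0)
        both = only_a + gauss(grid, 1.0, 1070.0, 8.0)
        s = make_spectrum(both, grid, SpectrumState.SMOOTHED)
        ref = make_spectrum(only_a, grid, SpectrumState.SMOOTHED)
        band = DEFAULT_BANDS["nu1_phosphate"]
        assert band_area(s, band) == pytest.approx(band_area(ref, band),
                                                   rel=0.01)

    def test_window_outside_grid_raises(self, grid):
        s = make_spectrum(np.ones(grid.size), grid, SpectrumState.SMOOTHED)
        with pytest.raises(ValueError):
            band_area(s, BandDefinition("x", (100.0, 200.0)))


class TestPhosphateGaussianFit:
    def test_noiseless_fwhm_recovery(self, grid):
        sigma = 8.5
        s = make_spectrum(gauss(grid, 5.0, 959.0, sigma), grid,
                          SpectrumState.SMOOTHED)
        _, center, fwhm = fit_phosphate_gaussian(
            s, DEFAULT_BANDS["nu1_phosphate"])
        assert fwhm == pytest.approx(FWHM_FACTOR * sigma, rel=1e-3)
        assert center == pytest.approx(959.0, abs=0.1)

    def test_fwhm_under_noise(self, grid):
        sigma, true_fwhm = 8.5, FWHM_FACTOR * 8.5
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            y = gauss(grid, 5.0, 959.0, sigma) * \
                (1 + 0.01 * rng.standard_normal(grid.size))
            s = make_spectrum(np.clip(y, 0, None), grid, SpectrumState.SMOOTHED)
            _, _, fwhm = fit_phosphate_gaussian(
                s, DEFAULT_BANDS["nu1_phosphate"])
            errs.append(abs(fwhm / true_fwhm - 1))
        assert max(errs) < 0.02

    def test_lorentzian_input_converges_with_larger_residual(self, grid):
        w = DEFAULT_BANDS["nu1_phosphate"]
        gamma = 8.0
        lor = 5.0 / (1 + ((grid - 959.0) / gamma) ** 2)
        gau = gauss(grid, 5.0, 959.0, 8.0)

        def resid_norm(y):
            s = make_spectrum(y, grid, SpectrumState.SMOOTHED)
            amp, center, fwhm = fit_phosphate_gaussian(s, w)
            m = w.slice(grid)
            model = gauss(grid[m], amp, center, fwhm / FWHM_FACTOR)
            return np.linalg.norm(y[m] - model)

        assert resid_norm(lor) > resid_norm(gau)


class TestRamanParameters:
    def test_known_area_ratios(self):
        # phosphate:carbonate:amide = 10:1:4  ->  mmr 2.5, carbonate 0.1
        s = generate_spectrum((2.5, 0.1, 17.0), noise=0.0, seed=0)
        p = process_spectrum(s)
        assert p.mmr == pytest.approx(2.5, rel=0.02)
        assert p.carbonate_substitution == pytest.approx(0.1, rel=0.02)

    def test_scale_invariance(self):
        s = generate_spectrum((3.0, 0.2, 20.0), noise=0.0, seed=1)
        doubled = RamanSpectrum(s.wavenumber, 2.0 * s.intensity)
        p1, p2 = process_spectrum(s), process_spectrum(doubled)
        assert p2.mmr == pytest.approx(p1.mmr, rel=1e-3)
        assert p2.carbonate_substitution == pytest.approx(
            p1.carbonate_substitution, rel=1e-3)
        assert p2.crystallinity == pytest.approx(p1.crystallinity, rel=1e-3)

    def test_crystallinity_is_exact_reciprocal_of_fwhm(self):
        s = generate_spectrum((2.0, 0.15, 20.0), noise=0.0, seed=2)
        p = process_spectrum(s)
        assert p.crystallinity * p.fwhm_phosphate == pytest.approx(1.0, abs=1e-15)
        assert p.fwhm_phosphate == pytest.approx(20.0, rel=0.01)

    def test_zero_matrix_band_raises(self, grid):
        y = gauss(grid, 10.0, 959.0, 7.0)  # mineral only, no Amide I
        s = make_spectrum(y, grid, SpectrumState.SMOOTHED)
        with pytest.raises(ZeroDivisionError):
            compute_raman_parameters(s)


class TestStateMachine:
    def test_states_only_advance_forward(self, grid):
        s = make_spectrum(np.ones(grid.size) + gauss(grid, 5, 959, 7), grid)
        with pytest.raises(ValueError):
            remove_cosmic_rays(s)       # raw cannot be despiked
        with pytest.raises(ValueError):
            smooth(s)                   # raw cannot be smoothed
        b = correct_baseline(s)
        with pytest.raises(ValueError):
            correct_baseline(b)         # already baselined
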