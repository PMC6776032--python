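"""Preprocessing: baseline removal, despiking, reference band, band signal."""

import numpy as np
import pytest

from ramanfish.spectra import (
    ANALYTES,
    POLY_P,
    AnalyteDefinition,
    CalibrationWarning,
    ReferenceBandMissingError,
    Spectrum,
    band_signal,
    baseline_correct,
    despike,
    find_spikes,
    preprocess,
    reference_check,
)
from ramanfish.synthetic import SyntheticTruth, generate_spectrum


def _poly_baseline(w, coeffs):
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    return np.polynomial.polynomial.polyval(x, coeffs)


def _gaussian(w, center, height, fwhm=15.0):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return height * np.exp(-0.5 * ((w - center) / sigma) ** 2)


class TestSpectrumModel:
    def test_rejects_unequal_lengths(self, grid):
        with pytest.raises(ValueError):
            Spectrum(grid, np.zeros(grid.size - 1))

    def test_rejects_non_monotone_grid(self, grid):
        w = grid.copy()
        w[10] = w[9]
        with pytest.raises(ValueError):
            Spectrum(w, np.zeros(grid.size))

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(10.0), np.zeros(10))


class TestBaselineCorrect:
    def test_pure_polynomial_removed_exactly(self, grid):
        coeffs = (200.0, -80.0, 50.0, -30.0, 12.0, -5.0, 2.0)
        y = _poly_baseline(grid, coeffs)
        out = baseline_correct(Spectrum(grid, y))
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.max(np.abs(y))

    def test_zero_spectrum_stays_zero(self, grid):
        out = baseline_correct(Spectrum(grid, np.zeros(grid.size)))
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_band_height_preserved_over_polynomial(self, grid):
        coeffs = (150.0, -60.0, 40.0, -20.0, 8.0, -4.0, 2.0)
        h = 1000.0
        y = _poly_baseline(grid, coeffs) + _gaussian(grid, 1170.0, h)
        out = baseline_correct(Spectrum(grid, y))
        recovered = out.intensities[np.abs(grid - 1170.0) <= 5].max()
        assert abs(recovered - h) / h < 0.02

    def test_idempotent(self, grid):
        y = _poly_baseline(grid, (100.0, 30.0, -20.0)) + _gaussian(grid, 1170.0, 800.0)
        once = baseline_correct(Spectrum(grid, y))
        twice = baseline_correct(once)
        scale = np.max(np.abs(once.intensities))
        assert np.max(np.abs(twice.intensities - once.intensities)) < 1e-6 * scale

    def test_rejects_nonfinite(self, grid):
        y = np.zeros(grid.size)
        y[5] = np.nan
        with pytest.raises(ValueError):
            baseline_correct(Spectrum(grid, y))

    def test_order_must_fit_data(self):
        w = np.arange(200.0, 260.0)
        with pytest.raises(ValueError):
            baseline_correct(Spectrum(w, np.zeros(w.size)), order=60)


class TestDespike:
    def _noisy_spectrum(self, grid, seed, sigma=10.0):
        rng = np.random.default_rng(seed)
        y = 300.0 + _gaussian(grid, 1170.0, 1000.0) + rng.normal(0, sigma, grid.size)
        return Spectrum(grid, y), sigma

    def test_single_spike_removed_others_bitwise_identical(self, grid):
        spec, sigma = self._noisy_spectrum(grid, 0)
        y = spec.intensities.copy()
        y[700] += 50 * sigma
        spiked = Spectrum(grid, y)
        out = despike(spiked)
        changed = np.flatnonzero(out.intensities != y)
        assert changed.tolist() == [700]
        assert out.meta["spikes_removed"] == 1

    def test_two_adjacent_spikes_both_replaced(self, grid):
        spec, sigma = self._noisy_spectrum(grid, 1)
        y = spec.intensities.copy()
        y[[900, 901]] += 60 * sigma
        out = despike(Spectrum(grid, y))
        flagged = find_spikes(Spectrum(grid, y))
        assert set(flagged) == {900, 901}
        assert out.meta["spikes_removed"] == 2

    def test_smooth_spectrum_unchanged(self, grid):
        spec, _ = self._noisy_spectrum(grid, 2)
        out = despike(spec)
        assert np.array_equal(out.intensities, spec.intensities)

    def test_boundary_spike_replaced_by_extension(self, grid):
        spec, sigma = self._noisy_spectrum(grid, 3)
        y = spec.intensities.copy()
        y[0] += 80 * sigma
        out = despike(Spectrum(grid, y))
        assert out.intensities[0] == y[1]

    def test_alteration_bound_per_spike(self, grid):
        # never alters more channels than spikes + 2 per spike
        spec, sigma = self._noisy_spectrum(grid, 4)
        y = spec.intensities.copy()
        spikes = [300, 650, 1200]
        for ch in spikes:
            y[ch] += 40 * sigma
        out = despike(Spectrum(grid, y))
        changed = np.flatnonzero(out.intensities != y)
        assert len(changed) <= 3 * len(spikes)
        assert set(spikes) <= set(changed.tolist())


class TestReferenceCheck:
    def test_centered_band_zero_offset(self, noiseless_truth):
        spec = generate_spectrum(noiseless_truth, {})
        assert abs(reference_check(spec)) <= 1.0  # within one grid step

    def test_shifted_band_warns(self, grid):
        y = 50.0 + _gaussian(grid, 324.0, 2000.0)
        with pytest.warns(CalibrationWarning):
            offset = reference_check(Spectrum(grid, y))
        assert offset == pytest.approx(3.0, abs=1.0)

    def test_missing_band_raises(self, grid):
        y = 50.0 + _gaussian(grid, 1170.0, 1000.0)
        with pytest.raises(ReferenceBandMissingError):
            reference_check(Spectrum(grid, y))


class TestBandSignal:
    def test_synthetic_band_height_recovered(self, noiseless_truth):
        density = 1000.0 * 4.98e-16
        spec = preprocess(generate_spectrum(noiseless_truth, {"poly-P": density}))
        sig = band_signal(spec, POLY_P)
        assert sig.confirmed
        assert sig.value == pytest.approx(1000.0, rel=0.02)

    def test_unconfirmed_polyp_censored(self, grid):
        # band at 1170 without the 690 P-O-P confirmation band
        y = _gaussian(grid, 1170.0, 1000.0)
        sig = band_signal(Spectrum(grid, y), POLY_P, detection_threshold=50.0)
        assert sig.value == 0.0
        assert not sig.confirmed

    def test_flat_spectrum_zero(self, grid):
        sig = band_signal(Spectrum(grid, np.zeros(grid.size)), POLY_P,
                          require_confirmation=False)
        assert sig.value == 0.0

    def test_invariant_to_added_polynomial(self, grid, noiseless_truth):
        density = 800.0 * 4.98e-16
        spec = generate_spectrum(noiseless_truth, {"poly-P": density})
        ref = band_signal(preprocess(spec), POLY_P).value
        extra = _poly_baseline(grid, (500.0, -100.0, 80.0, -40.0, 20.0, -10.0, 5.0))
        shifted = spec.copy_with(spec.intensities + extra)
        out = band_signal(preprocess(shifted), POLY_P).value
        assert out == pytest.approx(ref, rel=0.02)

    def test_atp_amp_bands_do_not_interfere(self, grid, noiseless_truth):
        # strongest ATP/AMP bands sit at 1125 and 990, outside the 1170+/-5 window
        density = 500.0 * 4.98e-16
        clean = generate_spectrum(noiseless_truth, {"poly-P": density})
        ref = band_signal(preprocess(clean), POLY_P).value
        contaminated = clean.copy_with(
            clean.intensities
            + _gaussian(grid, 1125.0, 800.0)
            + _gaussian(grid, 990.0, 800.0)
        )
        out = band_signal(preprocess(contaminated), POLY_P).value
        assert abs(out - ref) / ref < 0.05

    def test_marker_window_outside_grid_raises(self):
        w = np.arange(200.0, 400.0)
        fake = AnalyteDefinition("poly-P", 1170.0, (690.0,), "P")
        with pytest.raises(ValueError):
            band_signal(Spectrum(w, np.zeros(w.size)), fake)

    def test_area_mode_scales_with_height(self, grid):
        y1 = _gaussian(grid, 1170.0, 500.0)
        y2 = _gaussian(grid, 1170.0, 1000.0)
        a1 = band_signal(Spectrum(grid, y1), POLY_P, require_confirmation=False,
                         mode="area").value
        a2 = band_signal(Spectrum(grid, y2), POLY_P, require_confirmation=False,
                         mode="area").value
        assert a2 == pytest.approx(2 * a1, rel=1e-9)
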