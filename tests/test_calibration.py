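"""Calibration coefficient: worked example, closed loops, linearity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanfish.calibration import (
    CalibrationResult,
    calibration_coefficient,
    estimate_k,
    fit_linearity,
    material_density,
    segment_droplet,
)
from ramanfish.spectra import POLY_P, RamanMap
from ramanfish.synthetic import SyntheticTruth, generate_droplet_map


@pytest.fixture(scope="module")
def small_droplet():
    """Noiseless droplet map small enough for per-test reuse."""
    truth = SyntheticTruth(seed=21)
    rmap, table = generate_droplet_map(1e-8, 40000.0, 400.0, truth=truth)
    return rmap, table, truth


class TestCoefficientArithmetic:
    def test_unit_identity(self):
        assert calibration_coefficient(1.0, 1.0, 1, 1.0) == 1.0

    def test_published_polyp_worked_example(self):
        # 0.5 ul of 0.1 mg P/ml deposits 5e-8 g over 324,473 um^2,
        # mapped at 1452 points summing to 450,042 counts
        k = calibration_coefficient(5e-8, 324473.0, 1452, 450042.0)
        assert k == pytest.approx(4.97e-16, rel=0.005)
        assert abs(k - 4.98e-16) <= 0.2e-16

    def test_exact_inversion_of_stored_fields(self):
        res = CalibrationResult(
            analyte="poly-P", k=calibration_coefficient(5e-8, 324473.0, 1452, 450042.0),
            sd=0.0, n_replicates=1, area_um2=324473.0, n_points=1452,
            total_signal=450042.0, deposited_mass_g=5e-8,
        )
        rebuilt = (res.deposited_mass_g / res.area_um2) * (
            res.n_points / res.total_signal
        )
        assert rebuilt == res.k

    def test_invalid_inputs_rejected(self):
        for args in [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)]:
            with pytest.raises(ValueError):
                calibration_coefficient(*args)


class TestMaterialDensity:
    def test_published_droplet_density(self):
        # ~0.16 ug/mm^2 for 5e-8 g over ~0.32 mm^2
        d = material_density(5e-8, 324473.0)  # g/um^2
        assert d * 1e6 * 1e6 == pytest.approx(0.154, rel=0.01)  # ug/mm^2

    def test_zero_mass(self):
        assert material_density(0.0, 10.0) == 0.0

    def test_halves_when_area_doubles(self):
        assert material_density(1e-8, 200.0) == material_density(1e-8, 100.0) / 2

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            material_density(1e-8, 0.0)


class TestSegmentation:
    def test_recovers_disk_area_within_one_pixel_ring(self, small_droplet):
        rmap, table, _ = small_droplet
        seg = segment_droplet(rmap, POLY_P)
        true_pixels = int(table.in_droplet.sum())
        radius_px = np.sqrt(true_pixels / np.pi)
        ring = 2 * np.pi * radius_px + 4
        assert abs(seg.pixel_indices.size - true_pixels) <= ring
        assert seg.area_um2 == seg.pixel_indices.size * rmap.pixel_area

    def test_zero_map_is_empty_droplet_error(self, grid):
        coords = np.array([[0.0, 0.0], [20.0, 0.0]])
        rmap = RamanMap(grid, np.zeros((2, grid.size)), coords, 400.0)
        with pytest.raises(ValueError, match="empty droplet"):
            segment_droplet(rmap, POLY_P, preprocessed=True)

    def test_zero_threshold_keeps_every_signal_pixel(self, small_droplet):
        rmap, table, _ = small_droplet
        seg = segment_droplet(rmap, POLY_P, threshold_fraction=0.0)
        # all pixels with any positive signal — at least the true droplet
        assert seg.pixel_indices.size >= table.in_droplet.sum()


class TestEstimateK:
    def test_noiseless_closed_loop_recovers_k_true(self, small_droplet):
        rmap, _, truth = small_droplet
        res = estimate_k(rmap, 1e-8, POLY_P)
        assert res.k == pytest.approx(truth.k_true["poly-P"], rel=1e-6)

    def test_replicates_mean_sd(self):
        maps = []
        for seed in (31, 32):
            t = SyntheticTruth(seed=seed, noise_sd=0.5)
            rmap, _ = generate_droplet_map(1e-8, 30000.0, 900.0, truth=t)
            maps.append(rmap)
        res = estimate_k(maps, 1e-8, POLY_P)
        assert res.n_replicates == 2
        assert res.sd >= 0.0
        assert res.k == pytest.approx(4.98e-16, rel=0.02)

    def test_scale_equivariance(self, small_droplet):
        rmap, _, truth = small_droplet
        res = estimate_k(rmap, 1e-8, POLY_P)
        scaled = RamanMap(
            rmap.wavenumbers, rmap.intensities * 3.0, rmap.coords,
            rmap.pixel_area, rmap.map_id,
        )
        res3 = estimate_k(scaled, 1e-8, POLY_P)
        assert res3.total_signal == pytest.approx(3 * res.total_signal, rel=1e-9)
        assert res3.k == pytest.approx(res.k / 3, rel=1e-9)

    def test_whole_map_mode_uses_all_pixels(self, small_droplet):
        rmap, _, _ = small_droplet
        res = estimate_k(rmap, 1e-8, POLY_P, whole_map=True)
        assert res.n_points == rmap.n_pixels


class TestLinearity:
    def _series(self, truth, densities):
        from ramanfish.spectra import band_signal, preprocess
        from ramanfish.synthetic import generate_spectrum

        return [
            band_signal(
                preprocess(generate_spectrum(truth, {"poly-P": d}, salt=i)),
                POLY_P,
            ).value
            for i, d in enumerate(densities)
        ]

    def test_noiseless_series_r2_one_slope_inverse_k(self, noiseless_truth):
        densities = np.array([1, 2, 4, 6, 8]) * 1e-13
        fit = fit_linearity(densities, self._series(noiseless_truth, densities))
        assert fit.r_squared > 1 - 1e-6
        assert fit.slope == pytest.approx(1 / noiseless_truth.k_true["poly-P"], rel=0.01)

    def test_one_percent_noise_keeps_r2_high(self):
        densities = np.array([1, 2, 4, 6, 8]) * 1e-13
        for seed in range(3):
            truth = SyntheticTruth(seed=seed, noise_sd=2.0)
            fit = fit_linearity(densities, self._series(truth, densities))
            assert fit.r_squared > 0.99

    def test_two_routes_agree_noiseless(self, small_droplet):
        rmap, _, truth = small_droplet
        densities = np.array([1, 2, 4, 8]) * 1e-13
        fit = fit_linearity(densities, self._series(truth, densities))
        res = estimate_k(rmap, 1e-8, POLY_P)
        assert 1 / fit.slope == pytest.approx(res.k, rel=0.01)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fit_linearity([1e-13, 1e-13], [10.0, 10.0])
        with pytest.raises(ValueError):
            fit_linearity([1e-13, 1e-13, 1e-13], [10.0, 11.0, 12.0])


@given(c=st.floats(min_value=0.1, max_value=100.0))
def test_coefficient_inverse_scaling_in_signal(c):
    base = calibration_coefficient(1e-8, 1e5, 100, 1e4)
    assert calibration_coefficient(1e-8, 1e5, 100, c * 1e4) == pytest.approx(
        base / c, rel=1e-12
    )
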