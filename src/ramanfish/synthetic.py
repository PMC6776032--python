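"""Seeded generators for spectra, calibration maps, cell populations and
batch-cycling trajectories with known ground truth.

Everything downstream of the instrument can be exercised against these
generators: they emulate the statistical structure the analysis assumes
(polynomial backgrounds, Gaussian analyte bands whose height is density
divided by the true calibration coefficient, a CaF₂ reference band at
321 cm⁻¹, additive CCD noise, cosmic-ray impulses, lognormal
between-cell heterogeneity, and anaerobic/aerobic storage kinetics with
exact phosphorus conservation). Fixing the seed makes every generator
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import ANALYTES, POLY_P, AnalyteDefinition, RamanMap, Spectrum

__all__ = [
    "SyntheticTruth",
    "BatchTrajectoryTruth",
    "default_truth",
    "generate_spectrum",
    "generate_droplet_map",
    "generate_cell_population",
    "generate_batch_trajectory",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Fixed height ratios of confirmation bands relative to the marker band.
CONFIRMATION_RATIOS: dict[str, dict[float, float]] = {
    "poly-P": {690.0: 0.55},
    "PHA": {432.0: 0.30, 840.0: 0.35},
    "glycogen": {850.0: 0.45},
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters shared by the spectrum-level generators.

    ``k_true`` maps analyte name → true calibration coefficient
    (g µm⁻² count⁻¹); a band of surface density ``d`` is drawn with
    marker peak height ``d / k_true`` so the calibration loop closes
    exactly in the noiseless limit.
    """

    seed: int = 0
    wavenumber_start: float = 200.0
    wavenumber_stop: float = 1850.0
    wavenumber_step: float = 1.0
    k_true: Mapping[str, float] = field(
        default_factory=lambda: {a.name: a.k for a in ANALYTES.values()}
    )
    baseline_coeffs: tuple[float, ...] = (120.0, -40.0, 60.0, -25.0, 10.0, -6.0, 3.0)
    caf2_height: float = 2000.0
    band_fwhm: float = 15.0
    noise_sd: float = 0.0
    cosmic_rate: float = 0.0
    spike_height: tuple[float, float] = (500.0, 3000.0)

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(
            self.wavenumber_start,
            self.wavenumber_stop + 0.5 * self.wavenumber_step,
            self.wavenumber_step,
        )

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *salt])


def default_truth(**overrides) -> SyntheticTruth:
    """Convenience constructor with keyword overrides."""
    return SyntheticTruth(**overrides)


def _gaussian(w: np.ndarray, center: float, height: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * FWHM_TO_SIGMA
    return height * np.exp(-0.5 * ((w - center) / sigma) ** 2)


def _baseline(truth: SyntheticTruth, w: np.ndarray) -> np.ndarray:
    # Coefficients apply to the grid scaled onto [-1, 1]; a 6th-order
    # polynomial background is exactly removable by baseline correction.
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    return np.polynomial.polynomial.polyval(x, np.asarray(truth.baseline_coeffs))


def _clean_bands(
    truth: SyntheticTruth, w: np.ndarray, densities: Mapping[str, float]
) -> np.ndarray:
    y = _gaussian(w, 321.0, truth.caf2_height, truth.band_fwhm)
    for name, density in densities.items():
        if density < 0:
            raise ValueError(f"negative density for {name}")
        if density == 0:
            continue
        analyte = ANALYTES[name]
        height = density / truth.k_true[name]
        y += _gaussian(w, analyte.marker_wavenumber, height, truth.band_fwhm)
        for conf, ratio in CONFIRMATION_RATIOS.get(name, {}).items():
            y += _gaussian(w, conf, height * ratio, truth.band_fwhm)
    return y


def _noise_and_spikes(
    truth: SyntheticTruth, rng: np.random.Generator, n: int
) -> np.ndarray:
    y = np.zeros(n)
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, n)
    if truth.cosmic_rate > 0:
        n_spikes = rng.poisson(truth.cosmic_rate)
        if n_spikes:
            idx = rng.choice(n, size=min(n_spikes, n), replace=False)
            lo, hi = truth.spike_height
            y[idx] += rng.uniform(lo, hi, idx.size)
    return y


def generate_spectrum(
    truth: SyntheticTruth,
    analyte_densities: Mapping[str, float] | None = None,
    salt: int = 0,
    meta: dict | None = None,
) -> Spectrum:
    """One synthetic acquisition.

    ``analyte_densities`` maps analyte name → surface density (g µm⁻²).
    ``salt`` decorrelates the noise of sibling spectra generated from the
    same truth (pixels of a map, cells of a population) while keeping the
    whole ensemble a pure function of ``truth.seed``.
    """
    densities = dict(analyte_densities or {})
    w = truth.wavenumbers
    y = _baseline(truth, w) + _clean_bands(truth, w, densities)
    y += _noise_and_spikes(truth, truth.rng(salt), w.size)
    return Spectrum(w, y, {"synthetic": True, "salt": salt, **(meta or {})})


def generate_droplet_map(
    total_mass: float,
    droplet_area: float,
    pixel_area: float,
    analyte: AnalyteDefinition | str = POLY_P,
    truth: SyntheticTruth | None = None,
    radial_gamma: float = 0.0,
    margin: float = 1.15,
    map_id: str = "droplet",
) -> tuple[RamanMap, pd.DataFrame]:
    """Raster map of a dried standard droplet of known deposited mass.

    A disk of the requested area is rasterised at ``sqrt(pixel_area)``
    step; in-droplet pixels carry surface density ``total_mass`` divided
    by the *pixelated* droplet area so that Σ(density × pixel_area)
    equals the deposited mass exactly. ``radial_gamma`` adds a
    coffee-ring-like radial density modulation (1 + γ·(r/R)²),
    renormalised to conserve the total mass.

    Returns the map and a per-pixel truth table
    (x_um, y_um, in_droplet, density_g_um2).
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    if pixel_area > droplet_area:
        raise ValueError("pixel_area exceeds droplet_area")
    truth = truth or SyntheticTruth()
    name = analyte if isinstance(analyte, str) else analyte.name

    step = float(np.sqrt(pixel_area))
    radius = float(np.sqrt(droplet_area / np.pi))
    half = radius * margin
    axis = np.arange(-half, half + 0.5 * step, step)
    xx, yy = np.meshgrid(axis, axis)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    rr = np.hypot(coords[:, 0], coords[:, 1])
    inside = rr <= radius
    if not inside.any():
        raise ValueError("droplet smaller than one pixel")

    weights = np.zeros(coords.shape[0])
    weights[inside] = 1.0 + radial_gamma * (rr[inside] / radius) ** 2
    weights /= weights.sum()  # mass fractions per pixel; sums to 1 exactly
    densities = weights * total_mass / pixel_area

    w = truth.wavenumbers
    base = _baseline(truth, w)
    intensities = np.empty((coords.shape[0], w.size))
    for i in range(coords.shape[0]):
        y = base + _clean_bands(truth, w, {name: densities[i]})
        y = y + _noise_and_spikes(truth, truth.rng(1, i), w.size)
        intensities[i] = y

    rmap = RamanMap(
        w, intensities, coords, pixel_area, map_id,
        {"synthetic": True, "analyte": name, "total_mass_g": total_mass},
    )
    table = pd.DataFrame(
        {
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
            "in_droplet": inside,
            "density_g_um2": densities,
        }
    )
    return rmap, table


def generate_cell_population(
    n_cells: int,
    mass_mean: float,
    mass_sd: float,
    area_mean: float = 3.79,
    area_sd: float = 0.0,
    analyte: AnalyteDefinition | str = POLY_P,
    taxon: str = "Tetrasphaera",
    condition: str = "aerobic",
    loss_fraction: float = 0.0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Per-cell spectra for a FISH-identified population with known truth.

    Per-cell true analyte mass is lognormal with the given real-space
    mean and SD (right-skewed between-cell heterogeneity); the projected
    cell area is lognormal around ``area_mean`` (default 3.79 µm², the
    mean footprint of *T. elongata* rods on CaF₂). The measured surface
    density is ``mass × (1 − loss_fraction) / area``, emulating the
    fixation/FISH leakage that quantification later corrects for.

    Returns the spectra and the truth table (cell_id, taxon, condition,
    true_mass_g, area_um2).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mass_mean <= 0 or mass_sd < 0:
        raise ValueError("invalid mass distribution parameters")
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    truth = truth or SyntheticTruth()
    name = analyte if isinstance(analyte, str) else analyte.name
    rng = truth.rng(2)

    masses = _lognormal(rng, mass_mean, mass_sd, n_cells)
    areas = _lognormal(rng, area_mean, area_sd, n_cells)

    spectra = []
    for i in range(n_cells):
        density = masses[i] * (1.0 - loss_fraction) / areas[i]
        spectra.append(
            generate_spectrum(
                truth,
                {name: density},
                salt=1000 + i,
                meta={"cell_id": i, "taxon": taxon, "condition": condition},
            )
        )
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "taxon": taxon,
            "condition": condition,
            "analyte": name,
            "true_mass_g": masses,
            "area_um2": areas,
        }
    )
    return spectra, table


def _lognormal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Lognormal draws parameterised by real-space mean and SD (degenerate
    at ``mean`` when ``sd`` is 0)."""
    if sd == 0:
        return np.full(n, mean)
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * var
    return rng.lognormal(mu, np.sqrt(var), n)


@dataclass(frozen=True)
class BatchTrajectoryTruth:
    """Ground truth for an anaerobic/aerobic P-cycling batch experiment.

    ``cell_masses`` is (n_times, n_cells) in g P per cell; ``bulk_p`` and
    ``assimilated_p`` are mg P l⁻¹. Total P (bulk + intracellular +
    assimilated) is conserved at every sampling time by construction.
    """

    times_h: np.ndarray
    cell_masses: np.ndarray
    bulk_p: np.ndarray
    assimilated_p: np.ndarray
    cell_density: float  # cells per ml
    anaerobic_h: float
    aerobic_h: float

    @property
    def mean_cell_mass(self) -> np.ndarray:
        return self.cell_masses.mean(axis=1)

    def intracellular_mgP_per_l(self) -> np.ndarray:
        return self.cell_masses.sum(axis=1) / self.cell_masses.shape[1] * (
            self.cell_density * 1e6
        )

    def total_p(self) -> np.ndarray:
        return self.bulk_p + self.intracellular_mgP_per_l() + self.assimilated_p


def generate_batch_trajectory(
    n_cells: int = 100,
    anaerobic_h: float = 4.0,
    aerobic_h: float = 8.0,
    sample_interval_h: float = 0.5,
    initial_mass_mean: float = 0.6e-13,
    initial_mass_sd: float = 0.3e-13,
    floor_fraction: float = 0.3,
    capacity_mean: float = 1.1e-13,
    capacity_sd: float = 0.5e-13,
    release_rate: float = 1.2,
    uptake_rate: float = 0.5,
    cell_density: float = 7.9e7,
    initial_bulk_p: float = 15.5,
    assimilated_fraction: float = 0.15,
    seed: int = 0,
) -> BatchTrajectoryTruth:
    """Feed-famine storage dynamics with population heterogeneity.

    Anaerobic phase: each cell's poly-P decays first-order toward a floor
    (energy for substrate uptake is paid in released ortho-P). Aerobic
    phase: poly-P rises first-order toward a per-cell capacity; a fixed
    fraction of the P removed from the bulk is assimilated into biomass
    rather than stored. The bulk ortho-P closes the balance exactly.
    Sampling every 30 min mirrors standard batch protocols. Heat-killed
    controls are obtained with both rate constants 0.
    """
    if anaerobic_h <= 0 or aerobic_h <= 0:
        raise ValueError("phase durations must be positive")
    if not 0 <= assimilated_fraction < 1:
        raise ValueError("assimilated_fraction must be in [0, 1)")
    rng = np.random.default_rng([seed, 3])
    m0 = _lognormal(rng, initial_mass_mean, initial_mass_sd, n_cells)
    floors = floor_fraction * m0
    caps = _lognormal(rng, capacity_mean, capacity_sd, n_cells)
    caps = np.maximum(caps, floors)
    if np.any(caps < floors):
        raise ValueError("capacity below floor")

    times = np.arange(0.0, anaerobic_h + aerobic_h + 1e-9, sample_interval_h)
    masses = np.empty((times.size, n_cells))
    an = times <= anaerobic_h
    t_an = times[an][:, None]
    # convex-combination form: exact fixed point when a rate constant is 0
    e_an = np.exp(-release_rate * t_an)
    masses[an] = m0 * e_an + floors * (1.0 - e_an)
    m_end = masses[an][-1]
    t_ae = (times[~an] - anaerobic_h)[:, None]
    e_ae = np.exp(-uptake_rate * t_ae)
    masses[~an] = m_end * e_ae + caps * (1.0 - e_ae)

    mean_mass = masses.mean(axis=1)
    intra = mean_mass * cell_density * 1e6  # mg P per l
    # During aerobic uptake a fraction f of bulk-P removal is assimilated:
    # d(assim) = f/(1-f) * d(intra) while intra is rising.
    d_intra = np.diff(intra, prepend=intra[0])
    assim = np.cumsum(
        np.where(d_intra > 0, assimilated_fraction / (1 - assimilated_fraction), 0.0)
        * d_intra
    )
    total0 = initial_bulk_p + intra[0]
    bulk = total0 - intra - assim
    if np.any(bulk < 0):
        raise ValueError("parameters drive bulk ortho-P negative")
    return BatchTrajectoryTruth(
        times_h=times,
        cell_masses=masses,
        bulk_p=bulk,
        assimilated_p=assim,
        cell_density=cell_density,
        anaerobic_h=anaerobic_h,
        aerobic_h=aerobic_h,
    )
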