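"""Data model and preprocessing for single-cell Raman spectra.

A :class:`Spectrum` is one acquisition on a CaF₂ window: a strictly
increasing wavenumber grid (cm⁻¹, typically 200–1850) and CCD counts.
Preprocessing follows the conventional chain for quantitative Raman work:

1. :func:`despike` — remove cosmic-ray impulses (single/double channel
   outliers) by robust detection on first differences and linear
   interpolation from unflagged neighbours;
2. :func:`baseline_correct` — subtract a peak-excluding sixth-order
   polynomial baseline fitted by iterative clipping;
3. :func:`reference_check` — verify the CaF₂ internal reference band
   (321 cm⁻¹) sits where it should;
4. :func:`band_signal` — read the analyte marker-band signal (counts)
   used downstream for calibration and absolute quantification.

Marker bands: poly-P 1170 cm⁻¹ (PO₂⁻ stretch, confirmed by the P–O–P
stretch at 690 cm⁻¹), PHA 1726 cm⁻¹ (C=O stretch), glycogen 481 cm⁻¹
(C–C skeletal deformation, secondary band 840–860 cm⁻¹).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "RamanMap",
    "AnalyteDefinition",
    "BandSignal",
    "POLY_P",
    "PHA",
    "GLYCOGEN",
    "ANALYTES",
    "CalibrationWarning",
    "ReferenceBandMissingError",
    "baseline_correct",
    "despike",
    "find_spikes",
    "reference_check",
    "band_signal",
    "preprocess",
]

MIN_CHANNELS = 50


class CalibrationWarning(UserWarning):
    """Wavenumber calibration drift beyond tolerance."""


class ReferenceBandMissingError(ValueError):
    """No internal reference band found where one is required."""


@dataclass
class Spectrum:
    """One Raman acquisition: wavenumber grid + CCD counts + metadata.

    Intensities are raw CCD counts (non-negative as acquired; slightly
    negative values are legal after baseline subtraction).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError("wavenumbers and intensities differ in length")
        if self.wavenumbers.size < MIN_CHANNELS:
            raise ValueError(f"need at least {MIN_CHANNELS} channels")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    def window(self, center: float, halfwidth: float) -> np.ndarray:
        """Boolean mask of channels within ``center +/- halfwidth``."""
        return np.abs(self.wavenumbers - center) <= halfwidth

    def copy_with(self, intensities: np.ndarray, **meta) -> "Spectrum":
        new_meta = {**self.meta, **meta}
        return Spectrum(self.wavenumbers, np.asarray(intensities, float), new_meta)


@dataclass
class RamanMap:
    """Raster of spectra over a droplet or field of view.

    All pixels share one wavenumber grid; ``intensities`` is
    ``(n_pixels, n_channels)`` and ``coords`` is ``(n_pixels, 2)`` in µm.
    ``pixel_area`` is the raster step_x × step_y in µm².
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    coords: np.ndarray
    pixel_area: float
    map_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.intensities.shape != (self.coords.shape[0], self.wavenumbers.size):
            raise ValueError("intensities shape must be (n_pixels, n_channels)")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise ValueError("pixel coordinates must be unique")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        x, y = self.coords[i]
        return Spectrum(
            self.wavenumbers,
            self.intensities[i],
            {"map_id": self.map_id, "x_um": float(x), "y_um": float(y)},
        )

    def __iter__(self) -> Iterator[Spectrum]:
        return (self.spectrum(i) for i in range(self.n_pixels))


@dataclass(frozen=True)
class AnalyteDefinition:
    """A quantifiable storage polymer and its Raman signature.

    ``k`` is the calibration coefficient in g µm⁻² count⁻¹ on the
    element basis (g P for poly-P, g C for PHA and glycogen).
    """

    name: str
    marker_wavenumber: float
    confirmation_wavenumbers: tuple[float, ...]
    element_basis: str
    band_window_halfwidth: float = 5.0
    confirmation_halfwidth: float = 10.0
    k: float | None = None
    require_confirmation: bool = False

    def __post_init__(self) -> None:
        if self.element_basis not in ("P", "C"):
            raise ValueError("element_basis must be 'P' or 'C'")
        if self.band_window_halfwidth <= 0:
            raise ValueError("band_window_halfwidth must be positive")


# Bundled analyte definitions. Calibration coefficients are the droplet-map
# derived constants for sodium poly-P, PHB-co-HV and oyster glycogen
# standards (g analyte-element per um^2 per CCD count). Confirmation gating
# is on for poly-P only: the PHA and glycogen secondary bands overlap each
# other near 840 cm^-1 and cannot discriminate.
POLY_P = AnalyteDefinition(
    "poly-P", 1170.0, (690.0,), "P", k=4.98e-16, require_confirmation=True
)
PHA = AnalyteDefinition("PHA", 1726.0, (432.0, 840.0), "C", k=1.04e-14)
GLYCOGEN = AnalyteDefinition(
    "glycogen", 481.0, (850.0,), "C", confirmation_halfwidth=10.0, k=2.37e-15
)
ANALYTES = {a.name: a for a in (POLY_P, PHA, GLYCOGEN)}


class BandSignal(NamedTuple):
    """Marker-band signal in counts plus the confirmation flag."""

    value: float
    confirmed: bool


def baseline_correct(
    spectrum: Spectrum,
    order: int = 6,
    clip_sd: float = 2.0,
    max_iter: int = 20,
) -> Spectrum:
    """Subtract an iteratively clipped polynomial baseline.

    A polynomial of the given order is least-squares fitted to the
    spectrum, channels lying more than ``clip_sd`` residual standard
    deviations *above* the fit are dropped (Raman bands only add
    intensity), and the fit is repeated until the kept set stabilises.
    The final fit, evaluated on the full grid, is subtracted, so analyte
    bands do not drag the baseline upward.

    Parameters
    ----------
    order
        Polynomial order (default 6, the standard choice for
        fluorescence-dominated backgrounds in the fingerprint region).
    clip_sd
        Clipping threshold in residual SD units.
    max_iter
        Iteration cap; the kept set almost always stabilises in < 10.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    y = spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    if spectrum.n_channels <= order + 1:
        raise ValueError("too few points for the requested polynomial order")

    w = spectrum.wavenumbers
    scale = max(np.max(np.abs(y)), 1.0)
    keep = np.ones(y.size, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(max_iter):
        poly = Polynomial.fit(w[keep], y[keep], order)
        fit = poly(w)
        resid = y - fit
        sd = float(np.std(resid[keep]))
        new_keep = resid <= clip_sd * sd + 1e-12 * scale
        if new_keep.sum() <= order + 1:
            break
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep
    return spectrum.copy_with(y - fit, baseline_corrected=True)


def _robust_noise_sd(intensities: np.ndarray) -> float:
    """Robust per-channel noise SD from the MAD of first differences.

    For i.i.d. noise of SD sigma the first differences have SD sigma*sqrt(2),
    so sigma = 1.4826 * MAD(diff) / sqrt(2). A floor of 2e-3 of the intensity
    range keeps smooth noiseless bands (FWHM >= ~15 cm^-1) below the spike
    threshold.
    """
    d = np.diff(intensities)
    mad = float(np.median(np.abs(d - np.median(d))))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    span = float(np.ptp(intensities))
    return max(sigma, 2e-3 * span, 1e-300)


def find_spikes(spectrum: Spectrum, z_threshold: float = 8.0) -> np.ndarray:
    """Indices of channels flagged as cosmic-ray impulses.

    The impulse amplitude at channel ``i`` is estimated as
    ``A_i = x_i - (x_{i-1} + x_{i+1}) / 2`` (the matched statistic for a
    one-channel spike; first differences at the boundaries), and a channel
    is flagged when the robust z-score ``A_i / sigma_hat`` exceeds
    ``z_threshold``, with ``sigma_hat`` the MAD-based per-channel noise
    scale from the first differences. Cosmic rays are positive, so only
    positive excursions are flagged. One detect/repair pass is followed by
    a re-scan so that large spikes cannot mask neighbours.
    """
    x = spectrum.intensities.astype(float)
    flagged = np.zeros(x.size, dtype=bool)
    for _ in range(2):
        sigma = _robust_noise_sd(x)
        amp = np.empty_like(x)
        amp[1:-1] = x[1:-1] - 0.5 * (x[:-2] + x[2:])
        amp[0] = x[0] - x[1]
        amp[-1] = x[-1] - x[-2]
        new = (amp > z_threshold * sigma) & ~flagged
        if not new.any():
            break
        flagged |= new
        x = _interpolate_flagged(spectrum.wavenumbers, x, flagged)
    return np.flatnonzero(flagged)


def _interpolate_flagged(
    wavenumbers: np.ndarray, intensities: np.ndarray, flagged: np.ndarray
) -> np.ndarray:
    out = intensities.copy()
    good = ~flagged
    if not good.any():
        return out
    out[flagged] = np.interp(
        wavenumbers[flagged], wavenumbers[good], intensities[good]
    )
    return out


def despike(spectrum: Spectrum, z_threshold: float = 8.0) -> Spectrum:
    """Replace cosmic-ray channels by interpolation of unflagged neighbours.

    Channels not flagged are returned bit-for-bit unchanged. Spikes at the
    grid boundary are replaced by nearest-value extension (``np.interp``
    clamps outside the unflagged support).
    """
    idx = find_spikes(spectrum, z_threshold=z_threshold)
    if idx.size == 0:
        return spectrum.copy_with(spectrum.intensities, spikes_removed=0)
    flagged = np.zeros(spectrum.n_channels, dtype=bool)
    flagged[idx] = True
    cleaned = _interpolate_flagged(
        spectrum.wavenumbers, spectrum.intensities, flagged
    )
    return spectrum.copy_with(cleaned, spikes_removed=int(idx.size))


def reference_check(
    spectrum: Spectrum,
    reference_wavenumber: float = 321.0,
    tolerance: float = 2.0,
    search_halfwidth: float = 10.0,
) -> float:
    """Offset (cm⁻¹) of the CaF₂ internal reference band from nominal.

    Looks for a local maximum within ``+/- search_halfwidth`` of the
    nominal position; raises :class:`ReferenceBandMissingError` when no
    prominent peak is found and emits a :class:`CalibrationWarning` when
    the detected offset exceeds ``tolerance``.
    """
    mask = spectrum.window(reference_wavenumber, search_halfwidth)
    if mask.sum() < 3:
        raise ReferenceBandMissingError(
            "reference window outside the spectral range"
        )
    w = spectrum.wavenumbers[mask]
    y = spectrum.intensities[mask]
    noise = _robust_noise_sd(spectrum.intensities)
    prominence = max(5.0 * noise, 1e-9)
    peaks, _ = find_peaks(y, prominence=prominence)
    if peaks.size == 0:
        raise ReferenceBandMissingError(
            f"no reference band near {reference_wavenumber:g} cm^-1"
        )
    best = peaks[np.argmax(y[peaks])]
    offset = float(w[best] - reference_wavenumber)
    if abs(offset) > tolerance:
        warnings.warn(
            f"reference band offset {offset:+.2f} cm^-1 exceeds "
            f"tolerance {tolerance:g} cm^-1",
            CalibrationWarning,
            stacklevel=2,
        )
    return offset


def band_signal(
    spectrum: Spectrum,
    analyte: AnalyteDefinition,
    require_confirmation: bool | None = None,
    detection_threshold: float = 0.0,
    mode: str = "height",
) -> BandSignal:
    """Analyte marker-band signal in counts on a preprocessed spectrum.

    The signal is the maximum baseline-corrected intensity within
    ``marker +/- band_window_halfwidth`` (peak height, matching the count
    units of the calibration coefficients); ``mode="area"`` integrates
    the window instead (counts·cm⁻¹) for sensitivity analyses.

    When confirmation is required (default: the analyte's own setting),
    every confirmation band must exceed ``detection_threshold``; otherwise
    the signal is censored to 0 and flagged unconfirmed. For poly-P this
    enforces that the 1170 and 690 cm⁻¹ bands are observed
    simultaneously, which discriminates poly-P from ATP/AMP (strongest
    bands at 1125 and 990 cm⁻¹).
    """
    if require_confirmation is None:
        require_confirmation = analyte.require_confirmation
    mask = spectrum.window(analyte.marker_wavenumber, analyte.band_window_halfwidth)
    if not mask.any():
        raise ValueError(
            f"marker window {analyte.marker_wavenumber:g} cm^-1 outside grid"
        )
    y = spectrum.intensities
    if mode == "height":
        value = float(np.max(y[mask]))
    elif mode == "area":
        w = spectrum.wavenumbers
        value = float(np.trapezoid(np.clip(y[mask], 0.0, None), w[mask]))
    else:
        raise ValueError("mode must be 'height' or 'area'")
    value = max(value, 0.0)

    confirmed = True
    if require_confirmation:
        for conf in analyte.confirmation_wavenumbers:
            cmask = spectrum.window(conf, analyte.confirmation_halfwidth)
            if not cmask.any() or np.max(y[cmask]) <= detection_threshold:
                confirmed = False
                break
        if not confirmed:
            value = 0.0
    return BandSignal(value, confirmed)


def preprocess(
    spectrum: Spectrum,
    order: int = 6,
    z_threshold: float = 8.0,
    check_reference: bool = False,
) -> Spectrum:
    """Standard chain: despike, then baseline-correct (optionally check
    the CaF₂ reference first)."""
    if check_reference:
        reference_check(spectrum)
    return baseline_correct(despike(spectrum, z_threshold=z_threshold), order=order)


def preprocess_map(rmap: RamanMap, order: int = 6, z_threshold: float = 8.0) -> RamanMap:
    """Apply the preprocessing chain to every pixel of a map."""
    out = np.empty_like(rmap.intensities)
    for i in range(rmap.n_pixels):
        out[i] = preprocess(rmap.spectrum(i), order=order, z_threshold=z_threshold).intensities
    return RamanMap(
        rmap.wavenumbers,
        out,
        rmap.coords,
        rmap.pixel_area,
        rmap.map_id,
        {**rmap.meta, "preprocessed": True},
    )
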