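# Methods

`ramanfish` implements absolute quantification of intracellular storage
polymers — polyphosphate (poly-P), polyhydroxyalkanoates (PHA) and
glycogen — from single-cell Raman microspectra of FISH-identified
bacteria, and the downstream population and plant-level phosphorus
accounting used to resolve the contributions of *Ca*. Accumulibacter and
*Tetrasphaera* to enhanced biological phosphorus removal (EBPR).

## Quantification model

The core assumption is linearity of the Raman band signal in the amount
of analyte per illuminated surface area, with the specimen (a dried cell
monolayer on a CaF₂ window) optically thin so absorption is negligible.
For a standard droplet of deposited mass *m* (g) dried over area *A*
(µm²) and raster-mapped at *N* sampling points whose marker-band signals
(counts) sum to ΣS, the surface material density is

    d = m / A = k · ΣS / N        ⇒        k = (m/A) · (N/ΣS)

with *k* the calibration coefficient in g µm⁻² count⁻¹. A single cell of
projected area *a* (µm²) with marker signal *S* then carries mass
`k·S·a`, divided by `1 − loss` to correct for polymer leached during
fixation and FISH (defaults: 12% for poly-P, 8% for PHA, applied as the
single species-averaged fractions; whether a per-sample correction would
be more appropriate cannot be decided from the available data).

Marker bands and element bases:

| analyte  | marker (cm⁻¹) | confirmation (cm⁻¹) | basis | default k (g µm⁻² count⁻¹) |
|----------|---------------|----------------------|-------|------------------------------|
| poly-P   | 1170 (PO₂⁻)   | 690 (P–O–P)          | P     | 4.98×10⁻¹⁶ |
| PHA      | 1726 (C=O)    | 432, 840             | C     | 1.04×10⁻¹⁴ |
| glycogen | 481 (C–C)     | 840–860              | C     | 2.37×10⁻¹⁵ |

The bundled poly-P coefficient is reproducible from its droplet worked
example; the PHA and glycogen coefficients are shipped as constants
because their droplet maps are not published. Confirmation gating is on
by default only for poly-P (both the 1170 and 690 cm⁻¹ bands must be
present), which discriminates poly-P from ATP/AMP whose strongest bands
sit at 1125 and 990 cm⁻¹; the PHA and glycogen secondary bands overlap
near 840 cm⁻¹ and cannot gate each other.

**Signal definition.** The marker signal is the baseline-corrected peak
*height* (counts) within ±5 cm⁻¹ of the marker, not the integrated area:
height carries the same units (counts) as the published calibration
coefficients. An integrated-area mode (`band_signal(..., mode="area")`)
is exposed for sensitivity analysis but is not the calibrated path.

**Droplet segmentation.** Pixels above 5% of the maximum band signal
form the droplet; *N* and ΣS are taken over exactly that pixel set, the
same set whose extent defines *A* — the self-consistent reading of the
calibration equation. A `whole_map` switch sums every raster pixel
instead, for sensitivity analysis.

## Preprocessing

**Baseline.** A sixth-order polynomial is fitted by iterative clipping:
fit, drop channels more than 2.0 residual-SD *above* the fit (bands only
add intensity), refit until the kept set stabilises (cap 20 iterations),
then subtract the final fit on the full grid. Naive least squares on a
peak-bearing spectrum drags the baseline into the bands and
underestimates heights; clipping removes that bias. A pure polynomial
background is removed to < 10⁻⁶ relative residual, and the procedure is
idempotent to the same tolerance.

**Despiking.** Cosmic rays are one-to-two-channel impulses. The
per-channel noise scale is estimated robustly from the first differences
(σ̂ = 1.4826·MAD/√2, i.e. the modified-z machinery applied to the
differenced spectrum), and channel *i* is flagged when its impulse
amplitude `x_i − (x_{i−1}+x_{i+1})/2` exceeds `z_threshold·σ̂`
(default 8). Flagged channels are repaired by linear interpolation from
the nearest unflagged neighbours (nearest-value extension at the grid
boundary), and a second detect/repair pass prevents large spikes from
masking neighbours. A floor of 2×10⁻³ of the intensity range on σ̂ keeps
genuine Raman bands (FWHM ≳ 15 cm⁻¹) from being flagged in effectively
noiseless spectra; very narrow bands (FWHM ≲ 12 cm⁻¹) in zero-noise data
could still be touched, a regime real CCD data does not enter. Detection
power at the default threshold is ≈95% for a spike of exactly 10 noise
SD and ≈100% above 12; non-flagged channels are returned bit-for-bit
unchanged.

**Wavenumber integrity.** Every spectrum acquired on CaF₂ carries a
single strong band at 321 cm⁻¹; `reference_check` locates the local
maximum within ±10 cm⁻¹ and warns when the offset exceeds 2 cm⁻¹
(grid-limited precision: ±1 cm⁻¹ on the default 1 cm⁻¹ grid).

**Detection limit.** LOD = blank mean + 3·SD over ≥ 10 blank band
signals (the conventional rule; the multiplier is configurable). Cells
below the LOD are censored to zero *and kept* in population averages,
matching the "no measurable poly-P" bins of published per-cell
histograms; the censored count is reported.

## Synthetic data

The generators define the conditions every recovery test runs under;
they emulate the statistical structure the analysis assumes, not the
instrument physics (no optics, no spot convolution, no photobleaching).

* **Spectra** — 200–1850 cm⁻¹ on a 1 cm⁻¹ grid; sixth-order polynomial
  background; Gaussian bands of FWHM 15 cm⁻¹ (typical condensed-phase
  width) with marker height = density / k_true and fixed
  confirmation-band height ratios; CaF₂ band (2000 counts) at 321 cm⁻¹;
  additive Gaussian CCD noise (read-noise regime); Poisson-count cosmic
  rays of 500–3000 counts. All draws flow from one seed; identical seed
  and parameters give byte-identical output.
* **Droplet maps** — a disk rasterised at √pixel_area steps; in-droplet
  density is the deposited mass over the *pixelated* disk area, so the
  map conserves mass to machine precision; optional radial
  (coffee-ring) modulation renormalised to conserve mass. The default
  acceptance geometry (324,473 µm² droplet, 225 µm² pixels) yields
  ~1444 in-droplet sampling points, matching the scale of the published
  worked example (1452).
* **Cell populations** — per-cell true mass lognormal in real-space
  mean/SD (right-skewed heterogeneity, the shape seen in per-cell
  poly-P histograms; the published histograms do not constrain the
  parameters quantitatively, so the defaults are conventions); cell
  areas lognormal around 3.79 µm² (mean *T. elongata* footprint); the
  measured density is `mass·(1−loss)/area`, so the loss-correction
  round trip is testable exactly.
* **Batch trajectories** — first-order anaerobic decay toward a
  per-cell floor and first-order aerobic rise toward a per-cell
  capacity, written in convex-combination form so zero rate constants
  (heat-killed controls) are exactly flat; sampling every 30 min over
  4 h + 8 h. Defaults reproduce the pure-culture scale (aerobic mean
  1.1×10⁻¹³ g P/cell at 7.9×10⁷ cells ml⁻¹ ⇒ an 8.7 mg P l⁻¹
  bulk-equivalent pool). Bulk ortho-P closes the balance exactly, with
  a fixed fraction (default 15%) of aerobic P removal routed to
  assimilated biomass rather than poly-P. The kinetic form is a
  modelling convenience — downstream statistics test conservation and
  phase ordering, not the rate law.

Passing recovery tests on these generators demonstrates correctness of
the computational chain under its own assumptions (linearity, additive
noise, isolated bands); they cannot vouch for matrix effects,
autofluorescence shapes outside a sixth-order polynomial, or band
overlap in real sludge spectra.

## Population statistics

Population summaries are arithmetic mean ± sample SD over all cells
(censored zeros included), with histograms on 0.25×10⁻¹³ g bins.
Cell-specific release/uptake rates are endpoint differences of phase
means over the phase duration (the averaging windows behind some
published rates are not stated; endpoint means over the full phase are
used, and a regression-based alternative can be built from the
trajectory table). The glycogen-formed / PHA-degraded stoichiometry is
reported as a C/C ratio; both deltas being on the elemental-carbon
basis, the mass ratio equals the molar ratio.

## Plant-level accounting

qFISH biovolume fractions are pooled ratios (100·Σtarget/Σeub over all
fields of view) — robust to sparse fields — with per-field percentages
retained for dispersion. Cells per g SS are
`(fraction/100)·biovolume_per_gSS / cell_volume`; the default
biovolume conversion, 3.4×10¹² µm³ g SS⁻¹ (≈ 0.3 g dry solids per cm³
of biovolume), is consistent with the bundled survey's published genus
fractions to within a few percent across plants, and the default cell
volumes are 9.2 µm³ (*Ca*. Accumulibacter) and 2.9 µm³
(*Tetrasphaera*). The four-pool balance per g SS is

    total P = poly-P(Acc) + poly-P(Tet) + assimilated-biomass P + remainder

with the remainder (chemical precipitates + unknown PAO, not separable
without speciation data) defined by subtraction, floored at zero with a
warning if the named pools overshoot. The assimilated-biomass
coefficient defaults to 3.0 mg P g SS⁻¹ (~1.5% P of dry biomass × ~20%
active-biomass share of SS) — an explicit assumption, configurable per
plant. The genus *percentage contributions* need neither conversion
factor: they are genus fraction ÷ total P, which is why the bundled
survey's published fractions reproduce the published percentages to
rounding precision.

## Numerical choices and degenerate inputs

* Polynomial fits use `numpy.polynomial.Polynomial.fit` (domain-scaled,
  well-conditioned at order 6 over 1651 channels).
* Baseline clipping stops if fewer than order+2 channels remain.
* `band_signal` clamps at zero (noise can drive a corrected maximum
  slightly negative) and uses nearest-grid-point windows; empty marker
  windows raise.
* Lognormal draws are parameterised by real-space mean/SD and degenerate
  cleanly to a point mass at SD = 0.
* Mean/SD use ddof = 1, with SD defined as 0 for n = 1.
* Known scale: one full-size droplet map (≈2,500 spectra × 1,651
  channels) preprocesses in ~10 s; the test suite and the acceptance
  script each complete in well under a minute on one core. Recovery
  checks use one droplet map per noise level and populations of 100
  cells — the same n as the study design they emulate.

## Known limitations

* Peak-height readout is biased upward when the band-to-noise ratio
  drops below ~20 (maximum over a window of noisy channels); the
  calibrated path assumes the ~1%-noise regime of averaged acquisitions.
* No spectral unmixing: overlapping analyte bands (e.g. PHA and
  glycogen near 840 cm⁻¹) are handled by marker choice, not
  deconvolution.
* No self-absorption or matrix correction; thick or pigmented specimens
  violate the linearity assumption.
* The published *Tetrasphaera* volumetric maximum (0.68×10⁻¹³ g P µm⁻³)
  is not reproducible from the published per-cell mean and volume
  (1.77×10⁻¹³ / 2.9 = 0.61×10⁻¹³); the package computes the division and
  reports it as such.
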