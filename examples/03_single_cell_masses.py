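"""Absolute poly-P mass in FISH-identified single cells.

Simulates 100 Tetrasphaera-like cells (lognormal poly-P content, mean
1.77e-13 g P/cell; 12% of the polymer lost during fixation + FISH),
derives a limit of detection from blank spectra, quantifies each cell
with loss correction, and summarizes the population.
"""

import ramanfish as rf
from ramanfish.synthetic import SyntheticTruth, generate_cell_population, generate_spectrum

truth = SyntheticTruth(seed=5, noise_sd=0.9)
loss = 0.12  # fraction of poly-P leached before measurement

spectra, truth_table = generate_cell_population(
    100, mass_mean=1.77e-13, mass_sd=0.6e-13, loss_fraction=loss, truth=truth
)

blanks = [
    rf.band_signal(rf.preprocess(generate_spectrum(truth, {}, salt=900 + i)),
                   rf.POLY_P, require_confirmation=False).value
    for i in range(15)
]
lod = rf.detection_limit(blanks)
print(f"limit of detection (blank mean + 3 SD): {lod:.1f} counts")

signals = [rf.band_signal(rf.preprocess(s), rf.POLY_P).value for s in spectra]
cells = rf.quantify_cells(
    signals, truth_table.area_um2.to_numpy(), truth.k_true["poly-P"],
    loss=loss, lod=lod, taxon="Tetrasphaera", condition="aerobic",
)
summary = rf.summarize_population(cells)
true_mean = truth_table.true_mass_g.mean()
print(f"population mean: {summary.mean_mass:.3e} g P/cell "
      f"(truth {true_mean:.3e}; SD {summary.sd_mass:.2e}; "
      f"{summary.fraction_below_lod:.0%} below LOD)")
print(f"volumetric content at 2.9 um^3/cell: "
      f"{rf.volumetric_content(summary.mean_mass, 2.9):.2e} g P/um^3")
print("Loss correction divides each mass by (1 - 0.12), so the reported "
      "mean matches the pre-fixation truth despite the leakage.")
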