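"""Plant-level phosphorus accounting for full-scale EBPR systems.

Combines qFISH biovolume fractions with per-cell poly-P measured in the
aerobic (nitrifying) tank to resolve each genus's share of the sludge
phosphorus, then closes a four-pool mass balance per gram of suspended
solids (SS):

* poly-P in *Ca*. Accumulibacter,
* poly-P in *Tetrasphaera*,
* P assimilated into biomass (nucleic acids, membranes, ...),
* remainder — chemically bound P plus poly-P in unknown PAO, obtained
  by subtraction so the pools always sum to the measured total P.

A survey of eight Danish full-scale EBPR plants (recirculating and
alternating designs) with qFISH fractions, per-cell poly-P, ortho-P and
normalized total P is bundled; see :func:`load_plant_survey`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantAccount",
    "QfishEstimate",
    "qfish_fraction",
    "cells_per_gss",
    "genus_p_fraction",
    "contribution_percent",
    "mass_balance",
    "load_plant_survey",
    "survey_contributions",
    "accounts_from_survey",
]

# Biovolume of FISH-detectable biomass per g SS (um^3 / gSS). Equivalent to
# ~0.3 g dry solids per cm^3 of biovolume; consistent across the bundled
# survey's printed genus fractions to within a few percent.
DEFAULT_BIOVOLUME_PER_GSS = 3.4e12
# P assimilated into biomass, mg P per g SS (~1.5% P of dry biomass times
# ~20% active biomass share of SS). A documented assumption, not a
# measured constant.
DEFAULT_ASSIMILATED_P = 3.0
# Mean single-cell biovolumes (um^3) of the two PAO genera.
DEFAULT_CELL_VOLUMES = {"accumulibacter": 9.2, "tetrasphaera": 2.9}


class QfishEstimate(NamedTuple):
    """Pooled-ratio biovolume fraction (%) with per-field dispersion."""

    percent: float
    field_percents: np.ndarray
    sd: float


def qfish_fraction(
    field_areas: Sequence[tuple[float, float]],
) -> QfishEstimate:
    """Biovolume fraction of a probe-targeted taxon over fields of view.

    Each item is (target_area, eub_area) in pixels for one microscope
    field; the estimate is the pooled ratio 100·Σtarget/Σeub (robust to
    sparse fields), with per-field percentages retained for the SD.
    """
    if not field_areas:
        raise ValueError("need at least one field of view")
    target = np.array([t for t, _ in field_areas], float)
    eub = np.array([e for _, e in field_areas], float)
    if np.any(eub <= 0):
        raise ValueError("every field needs positive EUB-stained area")
    per_field = 100.0 * target / eub
    pooled = 100.0 * target.sum() / eub.sum()
    sd = float(per_field.std(ddof=1)) if per_field.size > 1 else 0.0
    return QfishEstimate(float(pooled), per_field, sd)


def cells_per_gss(
    qfish_pct: float,
    biovolume_per_gss: float = DEFAULT_BIOVOLUME_PER_GSS,
    cell_volume: float = 2.9,
) -> float:
    """Cells of the taxon per gram SS from its biovolume fraction."""
    if qfish_pct < 0 or qfish_pct > 100:
        raise ValueError("qfish_pct must be within [0, 100]")
    if biovolume_per_gss <= 0 or cell_volume <= 0:
        raise ValueError("biovolume and cell volume must be positive")
    return (qfish_pct / 100.0) * biovolume_per_gss / cell_volume


def genus_p_fraction(mass_per_cell: float, cells_per_gss_: float) -> float:
    """Genus-bound P per gram SS (mg P g SS⁻¹) from per-cell poly-P (g)."""
    if mass_per_cell < 0 or cells_per_gss_ < 0:
        raise ValueError("inputs must be non-negative")
    return mass_per_cell * cells_per_gss_ * 1e3  # g -> mg


def contribution_percent(genus_fraction: float, total_p: float) -> float:
    """Percentage of the plant's total P held by the genus."""
    if total_p <= 0:
        raise ValueError("total P must be positive")
    if genus_fraction < 0:
        raise ValueError("genus fraction must be non-negative")
    return 100.0 * genus_fraction / total_p


@dataclass
class PlantAccount:
    """Inputs for one plant's P mass balance.

    ``qfish_pct`` and ``polyp_per_cell`` (g P cell⁻¹, aerobic-tank
    population mean) are keyed by taxon ('accumulibacter',
    'tetrasphaera'). ``genus_fractions`` may be supplied directly (mg P
    g SS⁻¹, e.g. from a published survey); otherwise they are derived
    from qFISH, biovolume conversion and per-cell poly-P.
    """

    name: str
    total_p: float  # mg P / g SS
    design: str = ""
    qfish_pct: Mapping[str, float] = field(default_factory=dict)
    polyp_per_cell: Mapping[str, float] = field(default_factory=dict)
    ortho_p_n_tank: float | None = None  # mg P / l
    cell_volumes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_VOLUMES)
    )
    biovolume_per_gss: float = DEFAULT_BIOVOLUME_PER_GSS
    assimilated_p: float = DEFAULT_ASSIMILATED_P
    genus_fractions: Mapping[str, float] | None = None

    def derived_genus_fractions(self) -> dict[str, float]:
        if self.genus_fractions is not None:
            return dict(self.genus_fractions)
        out = {}
        for taxon, pct in self.qfish_pct.items():
            cells = cells_per_gss(
                pct, self.biovolume_per_gss, self.cell_volumes[taxon]
            )
            out[taxon] = genus_p_fraction(self.polyp_per_cell[taxon], cells)
        return out


def mass_balance(account: PlantAccount) -> pd.DataFrame:
    """Four-pool P balance for one plant (mg P g SS⁻¹ and % of total).

    The remainder (chemically bound P + unknown PAO) is defined by
    subtraction so the pools sum to the total exactly; a negative
    remainder is floored at zero with a warning (the named pools then
    overshoot the measured total and percentages are renormalised).
    """
    if account.total_p < 0:
        raise ValueError("total P must be non-negative")
    fractions = account.derived_genus_fractions()
    pools = {f"polyP_{taxon}": val for taxon, val in fractions.items()}
    pools["assimilated_biomass_P"] = account.assimilated_p
    named = sum(pools.values())
    remainder = account.total_p - named
    if remainder < 0:
        warnings.warn(
            f"{account.name}: named P pools ({named:.2f}) exceed total P "
            f"({account.total_p:.2f} mg P/gSS); remainder floored at 0",
            stacklevel=2,
        )
        remainder = 0.0
    pools["chemical_and_unknown_PAO"] = remainder
    total = sum(pools.values())
    df = pd.DataFrame(
        {
            "pool": list(pools),
            "mgP_per_gSS": list(pools.values()),
            "percent": [100.0 * v / total if total > 0 else 0.0 for v in pools.values()],
        }
    )
    df.insert(0, "plant", account.name)
    return df


def load_plant_survey() -> pd.DataFrame:
    """Bundled survey of eight Danish full-scale EBPR plants.

    Columns: qFISH biovolume fractions (% of EUBmix biovolume), per-cell
    poly-P in the nitrifying tank (10⁻¹³ g P cell⁻¹), ortho-P in the N
    tank (mg P l⁻¹), normalized total P (mg P g SS⁻¹), and the published
    genus P fractions (mg P g SS⁻¹) with their percentage contributions.
    """
    with resources.files("ramanfish.data").joinpath(
        "fullscale_plants.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def survey_contributions(survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute per-genus contribution percentages from the survey.

    Uses only the factor-free step (genus fraction ÷ total P × 100) so
    the result is directly comparable with the published parenthetical
    percentages; also reports the combined PAO share per plant.
    """
    df = load_plant_survey() if survey is None else survey.copy()
    df["contrib_acc_recomputed"] = [
        contribution_percent(f, t) for f, t in zip(df.frac_acc_mgpgss, df.totalp_mgpgss)
    ]
    df["contrib_tet_recomputed"] = [
        contribution_percent(f, t) for f, t in zip(df.frac_tet_mgpgss, df.totalp_mgpgss)
    ]
    df["contrib_combined"] = df.contrib_acc_recomputed + df.contrib_tet_recomputed
    return df


def accounts_from_survey(
    survey: pd.DataFrame | None = None,
    assimilated_p: float = DEFAULT_ASSIMILATED_P,
) -> list[PlantAccount]:
    """Build a PlantAccount per survey row using the published genus
    fractions (factor-free route)."""
    df = load_plant_survey() if survey is None else survey
    accounts = []
    for row in df.itertuples():
        accounts.append(
            PlantAccount(
                name=row.plant,
                design=row.design,
                total_p=row.totalp_mgpgss,
                ortho_p_n_tank=row.orthop_n_mgl,
                qfish_pct={
                    "accumulibacter": row.qfish_acc_pct,
                    "tetrasphaera": row.qfish_tet_pct,
                },
                polyp_per_cell={
                    "accumulibacter": row.polyp_acc_e13g * 1e-13,
                    "tetrasphaera": row.polyp_tet_e13g * 1e-13,
                },
                assimilated_p=assimilated_p,
                genus_fractions={
                    "accumulibacter": row.frac_acc_mgpgss,
                    "tetrasphaera": row.frac_tet_mgpgss,
                },
            )
        )
    return accounts
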