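"""Beverage volume deltas -> net daily energy-intake change (kJ/person/day)."""

from __future__ import annotations

import pandas as pd

from .params import BEVERAGES, MODEL_BANDS, EnergyDensityTable, decade_band_for


def beverage_energy_change(volume_delta: float, density: float) -> float:
    """Energy change (kJ/day) for a volume change (l/day) at a density (kJ/l)."""
    if density < 0:
        raise ValueError("density must be >= 0")
    return volume_delta * density


def net_energy_change(
    volume_deltas: pd.DataFrame,
    densities: EnergyDensityTable = EnergyDensityTable(),
) -> pd.DataFrame:
    """Per-band energy decomposition and net change.

    Parameters
    ----------
    volume_deltas
        Tidy frame (band, beverage, delta) in litres/day; all four
        beverages required per band.

    Returns
    -------
    Wide frame indexed by band with one kJ/day column per beverage and a
    ``net`` column equal to their sum. Substitution toward milk and juice
    enters positive, the SSB (and usually diet) term negative.
    """
    wide = volume_deltas.pivot(index="band", columns="beverage", values="delta")
    missing = [b for b in BEVERAGES if b not in wide.columns or wide[b].isna().any()]
    if missing:
        raise ValueError(f"missing beverage deltas: {missing}")
    energy = pd.DataFrame(
        {b: wide[b] * densities.value(b) for b in BEVERAGES}, index=wide.index
    )
    energy["net"] = energy[list(BEVERAGES)].sum(axis=1)
    energy.index.name = "band"
    # preserve the caller's band order
    return energy.loc[volume_deltas["band"].unique()]


def to_model_bands(decade_table: pd.DataFrame) -> pd.DataFrame:
    """Expand a 10-year-band table to the 13 5-year model bands.

    Each model band inherits its containing decade's row (the published
    model estimates consumption on survey decades but shifts BMI on
    5-year bands).
    """
    rows = decade_table.loc[[decade_band_for(b) for b in MODEL_BANDS]]
    rows.index = pd.Index(MODEL_BANDS, name="band")
    return rows
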