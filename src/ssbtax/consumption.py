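"""Categorical survey responses -> daily beverage volumes.

Milk and unsweetened fruit juice were surveyed as cups per day in ranges;
SSBs as times drunk in the last week. Range responses are converted with
the midpoint rule, capped at 500 ml (more than two cups counts as exactly
two) and 125 ml (less than half a cup counts as exactly half) so that a
per-person daily average is computable. One cup is 250 ml; one SSB serving
defaults to 330 ml, the size of a can.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CONSUMPTION_BANDS, DIET_FRACTION_OF_SSB, age_to_band

MILK_JUICE_CATEGORIES: tuple[str, ...] = (
    ">2 cups", "1-2 cups", "0.5-1 cup", "<0.5 cup", "none", "don't know",
)
#: Survey wording varies; "less than one cup" is treated as the capped
#: bottom category.
_MILK_JUICE_ALIASES = {"<1 cup": "<0.5 cup", "less than one cup": "<0.5 cup"}

SSB_CATEGORIES: tuple[str, ...] = (
    "none", "1-3 times last week", "4-6 times last week", "every day",
)

#: Cups consumed per category after midpoint/capping (x cup volume = ml/day).
_CUPS_PER_CATEGORY = {
    ">2 cups": 2.0,
    "1-2 cups": 1.5,
    "0.5-1 cup": 0.75,
    "<0.5 cup": 0.5,
    "none": 0.0,
}

#: Servings per day per weekly-frequency category (midpoint of the range;
#: "every day" is one serving per day).
_SERVINGS_PER_DAY = {
    "none": 0.0,
    "1-3 times last week": 2.0 / 7.0,
    "4-6 times last week": 5.0 / 7.0,
    "every day": 1.0,
}

VALID_SERVING_VOLUMES = (200.0, 250.0, 330.0, 500.0)


@dataclass(frozen=True)
class CategoryVolumeMap:
    """Volume conventions for converting categorical responses to ml/day."""

    cup_volume: float = 250.0
    serving_volume: float = 330.0

    def __post_init__(self) -> None:
        if self.cup_volume <= 0 or self.serving_volume <= 0:
            raise ValueError("cup and serving volumes must be positive")


def midpoint_volume(category: str, vmap: CategoryVolumeMap = CategoryVolumeMap()) -> float:
    """Daily milk/juice volume (ml) for a cups-per-day category.

    "don't know" maps to NaN (missing, excluded from estimation).
    """
    category = _MILK_JUICE_ALIASES.get(category, category)
    if category == "don't know":
        return math.nan
    try:
        return _CUPS_PER_CATEGORY[category] * vmap.cup_volume
    except KeyError:
        raise ValueError(f"unknown milk/juice category: {category!r}") from None


def ssb_daily_volume(frequency: str, vmap: CategoryVolumeMap = CategoryVolumeMap()) -> float:
    """Daily SSB volume (ml) for a times-last-week category."""
    try:
        return _SERVINGS_PER_DAY[frequency] * vmap.serving_volume
    except KeyError:
        raise ValueError(f"unknown SSB frequency category: {frequency!r}") from None


def _weighted_mean_se(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    mean = float((weights * values).sum() / wsum)
    # SE of the weighted mean under independent responses
    se = float(np.sqrt((weights**2 * (values - mean) ** 2).sum()) / wsum)
    return mean, se


def estimate_consumption(
    records: pd.DataFrame,
    vmap: CategoryVolumeMap = CategoryVolumeMap(),
    bands: tuple[str, ...] = CONSUMPTION_BANDS,
    diet_fraction: float = DIET_FRACTION_OF_SSB,
) -> pd.DataFrame:
    """Per-band mean daily consumption with standard errors, litres/day.

    Parameters
    ----------
    records
        Consumption survey frame with columns ``age``, ``milk_category``,
        ``juice_category``, ``ssb_frequency`` and optionally
        ``survey_weight`` (defaults to 1).
    vmap
        Volume conventions (cup and serving size).
    bands
        10-year band labels; each record is assigned by age.
    diet_fraction
        Diet-drink consumption as a fraction of SSB consumption.

    Returns
    -------
    Tidy frame (band, beverage, mean, se) covering ssb, milk, juice and
    diet for every band. Missing ("don't know") responses are excluded
    from both numerator and denominator. Raises ``ValueError`` if a band
    has no usable response for some beverage.
    """
    if records.empty:
        raise ValueError("no survey records supplied")
    weights = records.get("survey_weight")
    weights = (np.ones(len(records)) if weights is None
               else np.asarray(weights, dtype=float))
    band_of = records["age"].map(lambda a: age_to_band(a, bands))

    vols = pd.DataFrame({
        "ssb": records["ssb_frequency"].map(lambda c: ssb_daily_volume(c, vmap)),
        "milk": records["milk_category"].map(lambda c: midpoint_volume(c, vmap)),
        "juice": records["juice_category"].map(lambda c: midpoint_volume(c, vmap)),
    })

    rows = []
    for band in bands:
        in_band = (band_of == band).to_numpy()
        for bev in ("ssb", "milk", "juice"):
            v = vols[bev].to_numpy(dtype=float)[in_band]
            w = weights[in_band]
            ok = ~np.isnan(v)
            if not ok.any():
                raise ValueError(f"no usable {bev} responses in band {band}")
            mean, se = _weighted_mean_se(v[ok] / 1000.0, w[ok])
            rows.append((band, bev, mean, se))
    est = pd.DataFrame(rows, columns=["band", "beverage", "mean", "se"])
    diet = derive_diet_consumption(est[est["beverage"] == "ssb"], diet_fraction)
    return pd.concat([est, diet], ignore_index=True)


def derive_diet_consumption(ssb: pd.DataFrame, fraction: float = DIET_FRACTION_OF_SSB) -> pd.DataFrame:
    """Diet-drink consumption as a fixed fraction of SSB consumption.

    Means and SEs scale by the same fraction.
    """
    if fraction < 0:
        raise ValueError("diet fraction must be >= 0")
    diet = ssb.copy()
    diet["beverage"] = "diet"
    diet["mean"] = fraction * ssb["mean"].to_numpy()
    diet["se"] = fraction * ssb["se"].to_numpy()
    return diet
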