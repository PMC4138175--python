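"""Built-in model parameters.

All defaults mirror the published South African SSB-tax model inputs:
a meta-analytic price-elasticity matrix, beverage energy densities,
the Swinburn equilibrium energy-to-weight conversion factor, and the
SANHANES-1 baseline beverage consumption table (means with standard
errors of the mean, by 10-year age band).

Consumption means are stored at the precision of the published
consumption table (ml, three significant figures); standard errors are
derived from its 95% confidence intervals as (upper - lower) / 3.92,
except diet drinks, whose SEs are printed directly at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 5-year model age bands (BMI shift and prevalence are computed per band).
MODEL_BANDS: tuple[str, ...] = (
    "20-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: 10-year bands on which beverage consumption is estimated (survey scale).
CONSUMPTION_BANDS: tuple[str, ...] = (
    "15-24", "25-34", "35-44", "45-54", "55-64", "65+",
)

BEVERAGES: tuple[str, ...] = ("ssb", "milk", "juice", "diet")

SEXES: tuple[str, ...] = ("male", "female")

#: Obesity and overweight BMI thresholds (kg/m^2).
OBESITY_THRESHOLD = 30.0
OVERWEIGHT_THRESHOLD = 25.0

# Each 5-year model band inherits the consumption estimate of the 10-year
# band that contains it (65+ covers everything from 65 up).
_DECADE_OF_MODEL_BAND = {
    "20-24": "15-24",
    "25-29": "25-34", "30-34": "25-34",
    "35-39": "35-44", "40-44": "35-44",
    "45-49": "45-54", "50-54": "45-54",
    "55-59": "55-64", "60-64": "55-64",
    "65-69": "65+", "70-74": "65+", "75-79": "65+", "80+": "65+",
}


def decade_band_for(model_band: str) -> str:
    """Return the 10-year consumption band containing a 5-year model band."""
    try:
        return _DECADE_OF_MODEL_BAND[model_band]
    except KeyError:
        raise ValueError(f"unknown model band: {model_band!r}") from None


def band_midpoint(band: str) -> float:
    """Midpoint age of a band label like '25-29'; open bands use start + 2.5."""
    if band.endswith("+"):
        return float(band[:-1]) + 2.5
    lo, hi = band.split("-")
    return (float(lo) + float(hi) + 1) / 2.0


def age_to_band(age: float, bands: tuple[str, ...]) -> str | None:
    """Assign an age in years to a band label, or None if below all bands."""
    chosen = None
    for b in bands:
        start = float(b[:-1]) if b.endswith("+") else float(b.split("-")[0])
        if age >= start:
            chosen = b
    return chosen


@dataclass(frozen=True)
class ElasticityMatrix:
    """Own- and cross-price elasticities of demand with their SDs.

    A 10% SSB price rise moves SSB demand by ``ssb_own`` x 10%, milk by
    ``milk_cross`` x 10%, and so on. The same matrix applies to every age
    and sex group.
    """

    ssb_own: float = -1.299
    milk_cross: float = 0.129
    juice_cross: float = 0.388
    diet_cross: float = -0.423
    ssb_own_sd: float = 0.11
    milk_cross_sd: float = 0.10
    juice_cross_sd: float = 0.19
    diet_cross_sd: float = 0.10

    def value(self, beverage: str) -> float:
        return {"ssb": self.ssb_own, "milk": self.milk_cross,
                "juice": self.juice_cross, "diet": self.diet_cross}[beverage]

    def sd(self, beverage: str) -> float:
        return {"ssb": self.ssb_own_sd, "milk": self.milk_cross_sd,
                "juice": self.juice_cross_sd, "diet": self.diet_cross_sd}[beverage]

    def __post_init__(self) -> None:
        for b in BEVERAGES:
            if not np.isfinite(self.value(b)):
                raise ValueError(f"{b} elasticity must be finite")
            if self.sd(b) < 0:
                raise ValueError(f"{b} elasticity SD must be >= 0")


@dataclass(frozen=True)
class EnergyDensityTable:
    """Beverage energy densities in kJ per litre (milk taken as full cream)."""

    ssb: float = 1800.0
    juice: float = 1340.0
    milk: float = 2540.0
    diet: float = 4.0

    def value(self, beverage: str) -> float:
        return getattr(self, beverage)

    def __post_init__(self) -> None:
        for b in BEVERAGES:
            if self.value(b) < 0:
                raise ValueError("energy densities must be >= 0")


@dataclass(frozen=True)
class EnergyToWeight:
    """Sustained daily energy-intake change per 1 kg equilibrium weight change."""

    kj_per_kg_day: float = 94.0
    sd: float = 2.96

    def __post_init__(self) -> None:
        if self.kj_per_kg_day <= 0:
            raise ValueError("kj_per_kg_day must be strictly positive")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# Published baseline consumption, ml/person/day: mean (95% CI).
# Diet drinks are 4% of SSB with directly printed SEs (l/day).
_CONSUMPTION_ML = {
    # band: (ssb mean, lo, hi), (juice mean, lo, hi), (milk mean, lo, hi), diet SE (l/day)
    "15-24": ((209, 183, 238), (211, 189, 236), (205, 182, 232), 5.58e-4),
    "25-34": ((199, 171, 231), (205, 179, 233), (199, 197, 227), 6.11e-4),
    "35-44": ((181, 154, 212), (210, 182, 241), (205, 179, 235), 5.91e-4),
    "45-54": ((171, 144, 188), (193, 159, 233), (211, 180, 246), 4.50e-4),
    "55-64": ((149, 119, 200), (171, 142, 207), (195, 161, 235), 8.27e-4),
    "65+": ((120, 92, 158), (166, 132, 208), (217, 174, 270), 6.73e-4),
}

DIET_FRACTION_OF_SSB = 0.04


def baseline_consumption() -> pd.DataFrame:
    """Baseline beverage consumption by 10-year band, litres/person/day.

    Returns a tidy frame with columns ``band``, ``beverage``, ``mean``,
    ``se`` (standard error of the mean).
    """
    rows = []
    for band, (ssb, juice, milk, diet_se) in _CONSUMPTION_ML.items():
        for bev, (mean, lo, hi) in zip(("ssb", "juice", "milk"), (ssb, juice, milk)):
            rows.append((band, bev, mean / 1000.0, (hi - lo) / 3.92 / 1000.0))
        rows.append((band, "diet", DIET_FRACTION_OF_SSB * ssb[0] / 1000.0, diet_se))
    return pd.DataFrame(rows, columns=["band", "beverage", "mean", "se"])


def default_heights() -> pd.DataFrame:
    """Mean standing height (m) per model band and sex.

    The source survey's height table is not published; these flat values
    are back-solved from the paired male/female BMI shifts the model
    reports for a common energy change, and can be overridden from any
    microdata via :func:`ssbtax.bmi.mean_heights`.
    """
    rows = [(band, sex, 1.693 if sex == "male" else 1.601)
            for band in MODEL_BANDS for sex in SEXES]
    return pd.DataFrame(rows, columns=["band", "sex", "height"])


# Default BMI distribution table: arithmetic mean and SD (kg/m^2) per model
# band and sex. Chosen to match the broad South African pattern: women carry
# substantially higher mean BMI than men at every age, both rising to middle
# age then easing, with national obesity prevalence near 40% (women) and
# 13% (men).
_BMI_MALE_MEAN = (22.0, 23.0, 23.8, 24.4, 24.9, 25.3, 25.5,
                  25.6, 25.5, 25.2, 24.8, 24.4, 24.0)
_BMI_FEMALE_MEAN = (24.5, 26.0, 27.2, 28.2, 29.0, 29.6, 30.0,
                    30.2, 30.1, 29.8, 29.4, 28.9, 28.4)
_BMI_MALE_SD = (4.0, 4.2, 4.4, 4.6, 4.7, 4.8, 4.9, 5.0, 5.0, 5.0, 5.0, 4.9, 4.8)
_BMI_FEMALE_SD = (5.5, 5.8, 6.0, 6.2, 6.3, 6.4, 6.5, 6.5, 6.5, 6.4, 6.3, 6.2, 6.1)


def default_bmi_params() -> pd.DataFrame:
    """Default fitted-BMI table: columns band, sex, mean, sd (kg/m^2)."""
    rows = []
    for i, band in enumerate(MODEL_BANDS):
        rows.append((band, "male", _BMI_MALE_MEAN[i], _BMI_MALE_SD[i]))
        rows.append((band, "female", _BMI_FEMALE_MEAN[i], _BMI_FEMALE_SD[i]))
    return pd.DataFrame(rows, columns=["band", "sex", "mean", "sd"])


# Adult population counts (thousands) per 5-year band and sex, shaped like
# the South African 2012 mid-year pyramid: large young-adult cohorts
# declining monotonically with age.
_PYRAMID_THOUSANDS = {
    "20-24": (2560, 2520), "25-29": (2350, 2320), "30-34": (2070, 2050),
    "35-39": (1720, 1740), "40-44": (1400, 1480), "45-49": (1170, 1300),
    "50-54": (980, 1140), "55-59": (800, 980), "60-64": (620, 800),
    "65-69": (440, 620), "70-74": (300, 470), "75-79": (180, 330),
    "80+": (120, 280),
}


def default_pyramid() -> pd.DataFrame:
    """Population counts per model band and sex (persons)."""
    rows = []
    for band, (m, f) in _PYRAMID_THOUSANDS.items():
        rows.append((band, "male", m * 1000))
        rows.append((band, "female", f * 1000))
    return pd.DataFrame(rows, columns=["band", "sex", "count"])


@dataclass(frozen=True)
class ModelInputs:
    """Everything a deterministic model run consumes.

    consumption : tidy frame (band, beverage, mean, se), litres/day,
        on the 10-year consumption bands.
    bmi_params : tidy frame (band, sex, mean, sd) on the 13 model bands.
    heights : tidy frame (band, sex, height) in metres.
    pyramid : tidy frame (band, sex, count) in persons.
    """

    consumption: pd.DataFrame = field(default_factory=baseline_consumption)
    elasticities: ElasticityMatrix = field(default_factory=ElasticityMatrix)
    densities: EnergyDensityTable = field(default_factory=EnergyDensityTable)
    conversion: EnergyToWeight = field(default_factory=EnergyToWeight)
    heights: pd.DataFrame = field(default_factory=default_heights)
    bmi_params: pd.DataFrame = field(default_factory=default_bmi_params)
    pyramid: pd.DataFrame = field(default_factory=default_pyramid)
    threshold: float = OBESITY_THRESHOLD
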