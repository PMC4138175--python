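"""Synthetic survey inputs with the statistical structure the model assumes.

The real model inputs are two national surveys (measured BMI microdata;
categorical beverage-consumption items) and an official population
pyramid, none of which ship with the package. These generators emulate
exactly the marginal structure the downstream stages consume: age/sex
cells of lognormal BMI with survey weights, categorical consumption
responses with configurable per-decade probabilities, and counts by sex
and 5-year band. They make every stage testable end to end without a
download; they do not reproduce the surveys' cluster sampling designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import consumption as cons
from .params import (CONSUMPTION_BANDS, MODEL_BANDS, SEXES, default_bmi_params,
                     default_pyramid)

_BAND_AGE_SPAN = {"80+": (80, 95), "65+": (65, 90)}


def _age_range(band: str) -> tuple[float, float]:
    if band in _BAND_AGE_SPAN:
        return _BAND_AGE_SPAN[band]
    lo, hi = band.split("-")
    return float(lo), float(hi) + 1


def ssb_probs_for_mean(target_ml: float, serving_volume: float = 330.0,
                       interior: float = 0.25) -> dict[str, float]:
    """Category probabilities whose implied mean SSB volume equals ``target_ml``.

    Holds the two mid-frequency categories at probability ``interior``
    each and solves the "every day" / "none" split for the target.
    """
    interior_ml = interior * (2 / 7 + 5 / 7) * serving_volume
    p_every = (target_ml - interior_ml) / serving_volume
    p_none = 1.0 - 2 * interior - p_every
    if not (0 <= p_every <= 1 and 0 <= p_none <= 1):
        raise ValueError(f"target {target_ml} ml unreachable with interior={interior}")
    return {"none": p_none, "1-3 times last week": interior,
            "4-6 times last week": interior, "every day": p_every}


def cups_probs_for_mean(target_ml: float, cup_volume: float = 250.0,
                        interior: float = 0.2, p_dont_know: float = 0.05) -> dict[str, float]:
    """Milk/juice category probabilities whose conditional mean is ``target_ml``.

    The three interior cup categories are held at ``interior`` each; the
    top-capped and "none" categories absorb the target. "don't know"
    mass is mixed in afterwards and does not move the conditional mean.
    """
    interior_ml = interior * (1.5 + 0.75 + 0.5) * cup_volume
    p_top = (target_ml - interior_ml) / (2.0 * cup_volume)
    p_none = 1.0 - 3 * interior - p_top
    if not (0 <= p_top <= 1 and 0 <= p_none <= 1):
        raise ValueError(f"target {target_ml} ml unreachable with interior={interior}")
    scale = 1.0 - p_dont_know
    return {">2 cups": p_top * scale, "1-2 cups": interior * scale,
            "0.5-1 cup": interior * scale, "<0.5 cup": interior * scale,
            "none": p_none * scale, "don't know": p_dont_know}


def default_consumption_probs() -> dict[str, dict[str, dict[str, float]]]:
    """Per-decade-band category probabilities calibrated to the published
    baseline consumption table (SSB 209 ml/day at 15-24 declining to 120
    at 65+, and so on)."""
    targets = {  # ml/day: (ssb, milk, juice)
        "15-24": (209, 205, 211), "25-34": (199, 199, 205),
        "35-44": (181, 205, 210), "45-54": (171, 211, 193),
        "55-64": (149, 195, 171), "65+": (120, 217, 166),
    }
    return {band: {"ssb": ssb_probs_for_mean(t[0]),
                   "milk": cups_probs_for_mean(t[1]),
                   "juice": cups_probs_for_mean(t[2])}
            for band, t in targets.items()}


#: Share of consumption-survey respondents per decade band (young-heavy,
#: matching the adult population pyramid's shape).
_CONSUMPTION_BAND_SHARES = (0.30, 0.25, 0.18, 0.12, 0.09, 0.06)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for all three generators; the seed fixes every output exactly."""

    seed: int = 0
    n_bmi_records: int = 50_000
    bmi_params: pd.DataFrame = field(default_factory=default_bmi_params)
    height_mean_by_sex: dict[str, float] = field(
        default_factory=lambda: {"male": 1.693, "female": 1.601})
    height_sd: float = 0.07
    survey_weight_dist: str = "ones"  # "ones" or "gamma" (mean 1)
    consumption_probs: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=default_consumption_probs)
    pyramid_counts: pd.DataFrame = field(default_factory=default_pyramid)

    def __post_init__(self) -> None:
        if self.n_bmi_records < 0:
            raise ValueError("n_bmi_records must be >= 0")
        if self.height_sd <= 0 or any(v <= 0 for v in self.height_mean_by_sex.values()):
            raise ValueError("height parameters must be strictly positive")
        if ((self.bmi_params["mean"] <= 0) | (self.bmi_params["sd"] <= 0)).any():
            raise ValueError("BMI means and SDs must be strictly positive")
        if self.survey_weight_dist not in ("ones", "gamma"):
            raise ValueError("survey_weight_dist must be 'ones' or 'gamma'")
        for band, per_bev in self.consumption_probs.items():
            for bev, probs in per_bev.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for ({band}, {bev}) sum to {total}, not 1")
                if any(p < 0 for p in probs.values()):
                    raise ValueError(f"negative probability in ({band}, {bev})")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_bmi_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Draw BMI survey microdata: age, sex, height, weight, survey_weight.

    BMI within each (5-year band, sex) cell is lognormal with the
    configured arithmetic mean and SD; heights are normal per sex and
    independent of BMI; weight is derived as BMI x height^2. Records are
    allocated to cells in proportion to the population pyramid.
    """
    rng = _rng(config, 1)
    cells = config.bmi_params.merge(config.pyramid_counts, on=["band", "sex"])
    if len(cells) < len(config.bmi_params):
        raise ValueError("pyramid does not cover every BMI parameter cell")
    shares = cells["count"].to_numpy(float)
    shares = shares / shares.sum()
    n_per_cell = rng.multinomial(config.n_bmi_records, shares)

    frames = []
    for (_, row), n in zip(cells.iterrows(), n_per_cell):
        if n == 0:
            continue
        mu, sigma = np.log(row["mean"]**2 / np.sqrt(row["mean"]**2 + row["sd"]**2)), \
            np.sqrt(np.log1p((row["sd"] / row["mean"]) ** 2))
        bmi = rng.lognormal(mu, sigma, n)
        lo, hi = _age_range(row["band"])
        height = rng.normal(config.height_mean_by_sex[row["sex"]], config.height_sd, n)
        height = np.clip(height, 1.2, 2.1)
        frames.append(pd.DataFrame({
            "age": rng.uniform(lo, hi, n),
            "sex": row["sex"],
            "height": height,
            "weight": bmi * height**2,
        }))
    if not frames:
        return pd.DataFrame(columns=["age", "sex", "height", "weight", "survey_weight"])
    out = pd.concat(frames, ignore_index=True)
    if config.survey_weight_dist == "gamma":
        out["survey_weight"] = rng.gamma(4.0, 0.25, len(out))
    else:
        out["survey_weight"] = 1.0
    return out


def generate_consumption_survey(config: SyntheticConfig, n: int) -> pd.DataFrame:
    """Draw categorical beverage-consumption responses for ``n`` adults 15+.

    Category frequencies converge to the configured per-decade
    probabilities; ages are uniform within each decade band.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(config, 2)
    missing = [b for b in CONSUMPTION_BANDS if b not in config.consumption_probs]
    if missing:
        raise ValueError(f"consumption_probs missing bands: {missing}")
    n_per_band = rng.multinomial(n, _CONSUMPTION_BAND_SHARES)

    frames = []
    for band, nb in zip(CONSUMPTION_BANDS, n_per_band):
        if nb == 0:
            continue
        probs = config.consumption_probs[band]
        lo, hi = _age_range(band)
        frames.append(pd.DataFrame({
            "age": rng.uniform(lo, hi, nb),
            "milk_category": rng.choice(list(probs["milk"]), nb,
                                        p=list(probs["milk"].values())),
            "juice_category": rng.choice(list(probs["juice"]), nb,
                                         p=list(probs["juice"].values())),
            "ssb_frequency": rng.choice(list(probs["ssb"]), nb,
                                        p=list(probs["ssb"].values())),
            "survey_weight": 1.0,
        }))
    if not frames:
        return pd.DataFrame(columns=["age", "milk_category", "juice_category",
                                     "ssb_frequency", "survey_weight"])
    for f in frames:  # enumerated labels only
        for col, valid in (("milk_category", cons.MILK_JUICE_CATEGORIES),
                           ("juice_category", cons.MILK_JUICE_CATEGORIES),
                           ("ssb_frequency", cons.SSB_CATEGORIES)):
            bad = set(f[col]) - set(valid)
            if bad:
                raise ValueError(f"configured categories not in survey scale: {bad}")
    return pd.concat(frames, ignore_index=True)


def generate_population_pyramid(config: SyntheticConfig) -> pd.DataFrame:
    """Population counts per (5-year band, sex), validated against the model bands."""
    pyr = config.pyramid_counts
    have = set(map(tuple, pyr[["band", "sex"]].itertuples(index=False)))
    missing = [(b, s) for b in MODEL_BANDS for s in SEXES if (b, s) not in have]
    if missing:
        raise ValueError(f"pyramid missing cells: {missing}")
    if (pyr["count"] < 0).any():
        raise ValueError("pyramid counts must be non-negative")
    return pyr.copy()
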