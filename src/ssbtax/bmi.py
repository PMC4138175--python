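"""Population BMI distributions and the obesity counterfactual.

The pipeline here is: clean survey BMI microdata (trim the 1st/99th
weighted percentiles), fit a two-parameter positively skewed family
(lognormal by default, gamma as a cross-check) to each age-band x sex
cell by least squares on the empirical density, smooth the fitted means
and SDs across age with low-order polynomials, then apply the
population-shift logic: a net energy-intake change moves mean body
weight (94 kJ/day per kg at equilibrium), hence mean BMI through mean
height, and the tail mass above the obesity threshold moves with the
mean while the spread is held fixed — the mean predicts the prevalence
of individuals beyond the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import MODEL_BANDS, OBESITY_THRESHOLD, SEXES, age_to_band, band_midpoint

FAMILIES = ("lognormal", "gamma")


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be strictly positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the gamma with given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be strictly positive")
    return (mean / sd) ** 2, sd**2 / mean


def _frozen(family: str, mean: float, sd: float):
    if family == "lognormal":
        mu, sigma = lognormal_from_moments(mean, sd)
        return stats.lognorm(s=sigma, scale=np.exp(mu))
    if family == "gamma":
        a, scale = gamma_from_moments(mean, sd)
        return stats.gamma(a, scale=scale)
    raise ValueError(f"unknown family: {family!r}")


def tail_probability(mean: float, sd: float, threshold: float, family: str = "lognormal") -> float:
    """Upper-tail mass above ``threshold`` for the moment-matched family."""
    return float(_frozen(family, mean, sd).sf(threshold))


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Quantile of a weighted sample (Hazen-style cumulative-weight positions)."""
    order = np.argsort(values)
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(q, cdf, v))


def compute_bmi(records: pd.DataFrame) -> pd.Series:
    """BMI = weight (kg) / height (m)^2, validated."""
    h = records["height"].to_numpy(float)
    wt = records["weight"].to_numpy(float)
    if np.any((h <= 0.5) | (h >= 2.5)):
        raise ValueError("height outside plausible range (0.5, 2.5) m")
    if np.any((wt <= 20) | (wt >= 350)):
        raise ValueError("weight outside plausible range (20, 350) kg")
    return records["weight"] / records["height"] ** 2


def clean_bmi(records: pd.DataFrame, lower: float = 0.01, upper: float = 0.99) -> pd.DataFrame:
    """Drop records with BMI strictly outside the [1st, 99th] weighted percentiles.

    Percentiles are computed on the full adult sample, not per cell. The
    returned frame carries a ``bmi`` column.
    """
    if records.empty:
        raise ValueError("no BMI records supplied")
    out = records.copy()
    out["bmi"] = compute_bmi(out)
    w = out.get("survey_weight")
    w = np.ones(len(out)) if w is None else w.to_numpy(float)
    lo = weighted_quantile(out["bmi"].to_numpy(), w, lower)
    hi = weighted_quantile(out["bmi"].to_numpy(), w, upper)
    return out[(out["bmi"] >= lo) & (out["bmi"] <= hi)].reset_index(drop=True)


@dataclass(frozen=True)
class BMIDistributionParams:
    """Fitted BMI distribution for one age-band x sex cell."""

    band: str
    sex: str
    mean: float  # arithmetic mean, kg/m^2
    sd: float  # arithmetic SD, kg/m^2
    family: str = "lognormal"
    residual: float = float("nan")  # sum of squared density deviations


def fit_distribution(
    bmi: np.ndarray,
    weights: np.ndarray | None = None,
    family: str = "lognormal",
    n_bins: int = 60,
    fit_range: tuple[float, float] = (10.0, 60.0),
    band: str = "", sex: str = "",
) -> BMIDistributionParams:
    """Least-squares fit of a density family to an empirical BMI histogram.

    The weighted empirical density on ``n_bins`` equal bins over
    ``fit_range`` is matched against the family's pdf at bin centres,
    optimising the arithmetic mean and SD. Initialised at the sample
    moments.
    """
    bmi = np.asarray(bmi, float)
    if len(bmi) < 30:
        raise ValueError(f"need >= 30 records to fit a cell, got {len(bmi)}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family: {family!r}")
    weights = np.ones(len(bmi)) if weights is None else np.asarray(weights, float)

    hist, edges = np.histogram(bmi, bins=n_bins, range=fit_range,
                               weights=weights, density=True)
    centres = (edges[:-1] + edges[1:]) / 2.0

    m0 = float((weights * bmi).sum() / weights.sum())
    s0 = float(np.sqrt((weights * (bmi - m0) ** 2).sum() / weights.sum()))
    s0 = max(s0, 1e-3)

    def resid(theta):
        return _frozen(family, theta[0], theta[1]).pdf(centres) - hist

    sol = optimize.least_squares(resid, x0=[m0, s0],
                                 bounds=([5.0, 0.1], [80.0, 30.0]))
    if not sol.success:
        raise RuntimeError(f"BMI fit failed for ({band}, {sex}, {family}): {sol.message}")
    return BMIDistributionParams(band, sex, float(sol.x[0]), float(sol.x[1]),
                                 family, float(2 * sol.cost))


def smooth_across_ages(values, midpoints, degree: int):
    """Polynomial least-squares smooth of per-band values against band age.

    Fits one polynomial of ``degree`` in the band-midpoint ages and
    evaluates it back at the midpoints.
    """
    values = np.asarray(values, float)
    midpoints = np.asarray(midpoints, float)
    if degree >= len(values):
        raise ValueError("polynomial degree must be below the number of bands")
    poly = np.polynomial.Polynomial.fit(midpoints, values, degree)
    return poly(midpoints)


def fit_bmi_table(
    records: pd.DataFrame,
    family: str = "lognormal",
    smooth_degrees: tuple[int, int] = (3, 2),
    bands: tuple[str, ...] = MODEL_BANDS,
    clean: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Cleaned microdata -> smoothed per-(band, sex) BMI parameter table.

    Fits each cell separately, then smooths means (degree
    ``smooth_degrees[0]``) and SDs (degree ``smooth_degrees[1]``)
    across age within sex.

    Returns a tidy frame (band, sex, mean, sd, residual).
    """
    df = clean_bmi(records) if clean else records.assign(bmi=compute_bmi(records))
    w = df.get("survey_weight")
    w = np.ones(len(df)) if w is None else w.to_numpy(float)
    df = df.assign(_w=w, _band=df["age"].map(lambda a: age_to_band(a, bands)))

    rows = []
    for sex in SEXES:
        fits = []
        for band in bands:
            cell = df[(df["_band"] == band) & (df["sex"] == sex)]
            fits.append(fit_distribution(cell["bmi"].to_numpy(), cell["_w"].to_numpy(),
                                         family=family, band=band, sex=sex, **fit_kwargs))
        mids = [band_midpoint(b) for b in bands]
        means = smooth_across_ages([f.mean for f in fits], mids, smooth_degrees[0])
        sds = smooth_across_ages([f.sd for f in fits], mids, smooth_degrees[1])
        for band, f, m, s in zip(bands, fits, means, sds):
            rows.append((band, sex, float(m), float(s), f.residual))
    return pd.DataFrame(rows, columns=["band", "sex", "mean", "sd", "residual"])


def mean_heights(records: pd.DataFrame, bands: tuple[str, ...] = MODEL_BANDS) -> pd.DataFrame:
    """Weighted mean height (m) per band and sex from BMI microdata."""
    w = records.get("survey_weight")
    w = np.ones(len(records)) if w is None else w.to_numpy(float)
    df = records.assign(_w=w, _band=records["age"].map(lambda a: age_to_band(a, bands)))
    rows = []
    for band in bands:
        for sex in SEXES:
            cell = df[(df["_band"] == band) & (df["sex"] == sex)]
            if cell.empty:
                raise ValueError(f"no height data for ({band}, {sex})")
            rows.append((band, sex,
                         float((cell["height"] * cell["_w"]).sum() / cell["_w"].sum())))
    return pd.DataFrame(rows, columns=["band", "sex", "height"])


def delta_weight(energy_delta: float, kj_per_kg_day: float = 94.0) -> float:
    """Equilibrium body-weight change (kg) for a daily energy-intake change (kJ/day)."""
    if kj_per_kg_day <= 0:
        raise ValueError("conversion factor must be strictly positive")
    return energy_delta / kj_per_kg_day


def delta_bmi(weight_delta: float, height: float) -> float:
    """BMI change (kg/m^2) for a weight change (kg) at a mean height (m)."""
    if height <= 0:
        raise ValueError("height must be strictly positive")
    return weight_delta / height**2


def shift_and_prevalence(
    mean: float,
    sd: float,
    bmi_delta: float,
    threshold: float = OBESITY_THRESHOLD,
    family: str = "lognormal",
    hold: str = "arithmetic_sd",
) -> tuple[float, float]:
    """Baseline and counterfactual prevalence above a BMI threshold.

    The counterfactual shifts the arithmetic mean by ``bmi_delta`` while
    holding either the arithmetic SD fixed (``hold="arithmetic_sd"``,
    default) or, for the lognormal, the log-scale sigma fixed
    (``hold="sigma"``).
    """
    shifted_mean = mean + bmi_delta
    if shifted_mean <= 0:
        raise ValueError("shifted mean must remain strictly positive")
    base = tail_probability(mean, sd, threshold, family)
    if hold == "arithmetic_sd":
        shifted = tail_probability(shifted_mean, sd, threshold, family)
    elif hold == "sigma":
        if family != "lognormal":
            raise ValueError("hold='sigma' applies to the lognormal family only")
        _, sigma = lognormal_from_moments(mean, sd)
        mu = np.log(shifted_mean) - sigma**2 / 2.0
        shifted = float(stats.lognorm(s=sigma, scale=np.exp(mu)).sf(threshold))
    else:
        raise ValueError(f"unknown hold mode: {hold!r}")
    return base, shifted


def obesity_headcount(prevalence: pd.DataFrame, pyramid: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Prevalence shifts x population counts -> obesity head-count changes.

    Parameters
    ----------
    prevalence
        Tidy frame (band, sex, baseline, shifted) of prevalences in [0, 1].
    pyramid
        Tidy frame (band, sex, count) of population counts.

    Returns
    -------
    dict with ``per_band`` (the merged per-cell table with ``pp_change``,
    ``relative_change`` and ``count_change``) and ``by_sex`` (aggregates
    per sex plus a national "all" row; relative change is the
    population-weighted prevalence change over the baseline prevalence).
    """
    merged = prevalence.merge(pyramid, on=["band", "sex"], how="left", validate="1:1")
    if merged["count"].isna().any():
        missing = merged.loc[merged["count"].isna(), ["band", "sex"]]
        raise ValueError(f"pyramid missing cells:\n{missing}")
    merged["pp_change"] = merged["shifted"] - merged["baseline"]
    merged["relative_change"] = merged["pp_change"] / merged["baseline"]
    merged["count_change"] = merged["pp_change"] * merged["count"]

    rows = []
    groups = [(sex, merged[merged["sex"] == sex]) for sex in SEXES] + [("all", merged)]
    for label, g in groups:
        pop = g["count"].sum()
        if pop > 0:
            base = (g["baseline"] * g["count"]).sum() / pop
            shifted = (g["shifted"] * g["count"]).sum() / pop
            rel = (shifted - base) / base if base > 0 else np.nan
        else:
            base = shifted = rel = np.nan
        rows.append((label, base, shifted, shifted - base, rel,
                     g["count_change"].sum()))
    by_sex = pd.DataFrame(rows, columns=["sex", "baseline", "shifted", "pp_change",
                                         "relative_change", "count_change"])
    return {"per_band": merged, "by_sex": by_sex}
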