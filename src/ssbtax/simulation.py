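"""Orchestration: deterministic runs, Monte Carlo uncertainty, sensitivity.

The deterministic chain is: tax scenario -> price change -> per-beverage
volume deltas on the 10-year consumption bands -> energy deltas mapped
to the 13 5-year model bands -> mean weight and BMI shifts -> lognormal
tail prevalence per band and sex -> population head counts.

Monte Carlo propagation redraws the four elasticities, the
energy-to-weight conversion factor, and the per-band per-beverage
consumption means from independent normals and reruns the chain per
draw, fully vectorised across draws. Draws are not truncated: sampled
elasticities may cross zero, which is what lets upper interval bounds
cross zero in the older bands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import consumption as cons
from .bmi import gamma_from_moments, lognormal_from_moments, obesity_headcount
from .demand import TaxScenario, consumption_change_fraction, effective_price_change, shift_consumption
from .energy import net_energy_change, to_model_bands
from .params import (BEVERAGES, CONSUMPTION_BANDS, MODEL_BANDS, SEXES,
                     ModelInputs, decade_band_for)

_DECADE_INDEX = np.array([CONSUMPTION_BANDS.index(decade_band_for(b))
                          for b in MODEL_BANDS])


def _tail_vectorised(mean, sd, threshold, family="lognormal"):
    """Upper-tail mass for moment-matched lognormal/gamma; broadcasts."""
    mean, sd = np.asarray(mean, float), np.asarray(sd, float)
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return special.ndtr((mu - np.log(threshold)) / np.sqrt(sigma2))
    if family == "gamma":
        a = (mean / sd) ** 2
        return special.gammaincc(a, threshold / (sd**2 / mean))
    raise ValueError(f"unknown family: {family!r}")


def _static_tables(inputs: ModelInputs):
    """Pivot the tidy input frames into (band x sex) arrays in fixed order."""
    def pivot(df, value):
        w = df.pivot(index="band", columns="sex", values=value)
        return w.loc[list(MODEL_BANDS), list(SEXES)].to_numpy(float)

    heights = pivot(inputs.heights, "height")
    bmi_mean = pivot(inputs.bmi_params, "mean")
    bmi_sd = pivot(inputs.bmi_params, "sd")
    return heights, bmi_mean, bmi_sd


def _consumption_matrix(consumption: pd.DataFrame) -> np.ndarray:
    """(6 decade bands x 4 beverages) matrix of mean volumes, litres/day."""
    w = consumption.pivot(index="band", columns="beverage", values="mean")
    return w.loc[list(CONSUMPTION_BANDS), list(BEVERAGES)].to_numpy(float)


@dataclass(frozen=True)
class SimulationResult:
    """Outputs of one deterministic model run."""

    volume_deltas: pd.DataFrame  # (band, beverage, delta), decade bands, l/day
    energy: pd.DataFrame  # model bands x (per-beverage, net), kJ/person/day
    bmi_deltas: pd.DataFrame  # (band, sex, delta_bmi), kg/m^2
    prevalence: pd.DataFrame  # (band, sex, baseline, shifted)
    obesity_per_band: pd.DataFrame
    obesity_by_sex: pd.DataFrame


def run_deterministic(
    inputs: ModelInputs,
    scenario: TaxScenario = TaxScenario(),
    family: str = "lognormal",
) -> SimulationResult:
    """Run the full chain once at the input point estimates."""
    deltas = shift_consumption(inputs.consumption, scenario, inputs.elasticities)
    energy_decade = net_energy_change(deltas, inputs.densities)
    energy = to_model_bands(energy_decade)

    heights, bmi_mean, bmi_sd = _static_tables(inputs)
    net = energy["net"].to_numpy(float)  # (13,)
    weight_delta = net / inputs.conversion.kj_per_kg_day
    bmi_delta = weight_delta[:, None] / heights**2  # (13, 2)

    baseline = _tail_vectorised(bmi_mean, bmi_sd, inputs.threshold, family)
    shifted = _tail_vectorised(bmi_mean + bmi_delta, bmi_sd, inputs.threshold, family)

    bmi_rows, prev_rows = [], []
    for i, band in enumerate(MODEL_BANDS):
        for j, sex in enumerate(SEXES):
            bmi_rows.append((band, sex, bmi_delta[i, j]))
            prev_rows.append((band, sex, baseline[i, j], shifted[i, j]))
    bmi_df = pd.DataFrame(bmi_rows, columns=["band", "sex", "delta_bmi"])
    prev_df = pd.DataFrame(prev_rows, columns=["band", "sex", "baseline", "shifted"])
    counts = obesity_headcount(prev_df, inputs.pyramid)
    return SimulationResult(deltas, energy, bmi_df, prev_df,
                            counts["per_band"], counts["by_sex"])


@dataclass(frozen=True)
class MonteCarloConfig:
    """Draw count, seed, and the order in which quantity groups are sampled."""

    n_draws: int = 10_000
    seed: int = 0
    sample_order: tuple[str, ...] = ("elasticities", "conversion", "consumption")

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if sorted(self.sample_order) != ["consumption", "conversion", "elasticities"]:
            raise ValueError("sample_order must permute the three quantity groups")


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimates with Monte Carlo means and percentile intervals."""

    energy: pd.DataFrame  # per model band: point, mc_mean, lo, hi (net kJ/day)
    bmi: pd.DataFrame  # per (band, sex): point, mc_mean, lo, hi (kg/m^2)
    obesity: pd.DataFrame  # per sex (+ "all"): relative change point/mean/lo/hi
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _sample(inputs: ModelInputs, mc: MonteCarloConfig):
    rng = np.random.default_rng(np.random.SeedSequence([mc.seed, 3]))
    n = mc.n_draws
    cons_w = inputs.consumption.pivot(index="band", columns="beverage", values="mean") \
        .loc[list(CONSUMPTION_BANDS), list(BEVERAGES)].to_numpy(float)
    cons_se = inputs.consumption.pivot(index="band", columns="beverage", values="se") \
        .loc[list(CONSUMPTION_BANDS), list(BEVERAGES)].to_numpy(float)
    e = inputs.elasticities
    draws = {}
    for group in mc.sample_order:
        if group == "elasticities":
            draws["elasticities"] = rng.normal(
                [e.value(b) for b in BEVERAGES],
                [e.sd(b) for b in BEVERAGES], size=(n, 4))
        elif group == "conversion":
            draws["conversion"] = rng.normal(
                inputs.conversion.kj_per_kg_day, inputs.conversion.sd, size=n)
        else:
            draws["consumption"] = rng.normal(cons_w, cons_se, size=(n, 6, 4))
    return draws


def run_monte_carlo(
    inputs: ModelInputs,
    scenario: TaxScenario = TaxScenario(),
    mc: MonteCarloConfig = MonteCarloConfig(),
    family: str = "lognormal",
) -> UncertaintyResult:
    """Propagate parameter uncertainty through the chain by simulation.

    Every draw samples all quantities independently from their normals
    (sign changes allowed), reruns the deterministic chain, and the 2.5th
    and 97.5th percentiles of each output are reported alongside the
    point estimate and the Monte Carlo mean.
    """
    point = run_deterministic(inputs, scenario, family)
    draws = _sample(inputs, mc)
    p = effective_price_change(scenario)

    frac = consumption_change_fraction(p, draws["elasticities"],
                                       scenario.elasticity_form)  # (n, 4)
    vol_delta = draws["consumption"] * frac[:, None, :]  # (n, 6, 4)
    density = np.array([inputs.densities.value(b) for b in BEVERAGES])
    energy_decade = vol_delta @ density  # (n, 6)
    energy_model = energy_decade[:, _DECADE_INDEX]  # (n, 13)

    heights, bmi_mean, bmi_sd = _static_tables(inputs)
    weight_delta = energy_model / draws["conversion"][:, None]
    bmi_delta = weight_delta[:, :, None] / heights[None, :, :]**2  # (n, 13, 2)

    baseline = _tail_vectorised(bmi_mean, bmi_sd, inputs.threshold, family)  # (13, 2)
    shifted = _tail_vectorised(bmi_mean[None] + bmi_delta, bmi_sd[None],
                               inputs.threshold, family)  # (n, 13, 2)

    pop = inputs.pyramid.pivot(index="band", columns="sex", values="count") \
        .loc[list(MODEL_BANDS), list(SEXES)].to_numpy(float)  # (13, 2)
    base_pop = (baseline * pop).sum(axis=0)  # obese persons by sex
    shift_pop = (shifted * pop[None]).sum(axis=1)  # (n, 2)
    rel_change = (shift_pop - base_pop[None]) / base_pop[None]  # (n, 2)
    pp_change = (shift_pop - base_pop[None]) / pop.sum(axis=0)[None]
    rel_all = (shift_pop.sum(axis=1) - base_pop.sum()) / base_pop.sum()

    def summarise(arr, axis=0):
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=axis)
        return arr.mean(axis=axis), lo, hi

    e_mean, e_lo, e_hi = summarise(energy_model)
    energy_df = pd.DataFrame({
        "band": MODEL_BANDS, "point": point.energy["net"].to_numpy(),
        "mc_mean": e_mean, "lo": e_lo, "hi": e_hi})

    b_mean, b_lo, b_hi = summarise(bmi_delta)
    bmi_rows = []
    pt = point.bmi_deltas.pivot(index="band", columns="sex", values="delta_bmi") \
        .loc[list(MODEL_BANDS), list(SEXES)].to_numpy(float)
    for i, band in enumerate(MODEL_BANDS):
        for j, sex in enumerate(SEXES):
            bmi_rows.append((band, sex, pt[i, j], b_mean[i, j], b_lo[i, j], b_hi[i, j]))
    bmi_df = pd.DataFrame(bmi_rows, columns=["band", "sex", "point", "mc_mean", "lo", "hi"])

    ob_rows = []
    point_rel = point.obesity_by_sex.set_index("sex")["relative_change"]
    for j, sex in enumerate(SEXES):
        m, lo, hi = summarise(rel_change[:, j])
        ob_rows.append((sex, point_rel[sex], m, lo, hi))
    m, lo, hi = summarise(rel_all)
    ob_rows.append(("all", point_rel["all"], m, lo, hi))
    obesity_df = pd.DataFrame(ob_rows, columns=["sex", "point", "mc_mean", "lo", "hi"])

    raw = {"net_energy": energy_model, "bmi_delta": bmi_delta,
           "relative_change": rel_change, "pp_change": pp_change}
    return UncertaintyResult(energy_df, bmi_df, obesity_df, raw)


def two_way_sensitivity(
    inputs: ModelInputs,
    tax_rates: tuple[float, ...] = (0.10, 0.20, 0.30),
    pass_on_rates: tuple[float, ...] = (0.80, 0.90, 1.00, 1.10, 1.20),
    elasticity_form: str = "power",
) -> pd.DataFrame:
    """Deterministic grid over tax and pass-on rates.

    Returns a tidy frame (tax_rate, pass_on_rate, sex, relative_change,
    pp_change) of the obesity change per cell.
    """
    if not tax_rates or not pass_on_rates:
        raise ValueError("sensitivity grid must be non-empty")
    rows = []
    for tax in tax_rates:
        for po in pass_on_rates:
            res = run_deterministic(inputs, TaxScenario(tax, po, elasticity_form))
            for _, r in res.obesity_by_sex.iterrows():
                rows.append((tax, po, r["sex"], r["relative_change"], r["pp_change"]))
    return pd.DataFrame(rows, columns=["tax_rate", "pass_on_rate", "sex",
                                       "relative_change", "pp_change"])


def serving_size_tornado(
    records: pd.DataFrame,
    inputs: ModelInputs,
    scenario: TaxScenario = TaxScenario(),
    serving_volumes: tuple[float, ...] = cons.VALID_SERVING_VOLUMES,
) -> pd.DataFrame:
    """One-way sensitivity of the obesity change to the SSB serving volume.

    Re-derives the consumption estimates from the raw categorical survey
    ``records`` under each serving volume and reruns the full chain.
    Rows are ordered by the magnitude of the male relative change for
    tornado plotting.
    """
    if any(s <= 0 for s in serving_volumes):
        raise ValueError("serving volumes must be positive")
    rows = []
    for size in serving_volumes:
        vmap = cons.CategoryVolumeMap(serving_volume=float(size))
        est = cons.estimate_consumption(records, vmap)
        res = run_deterministic(dataclasses.replace(inputs, consumption=est), scenario)
        for _, r in res.obesity_by_sex.iterrows():
            rows.append((float(size), r["sex"], r["relative_change"], r["pp_change"]))
    df = pd.DataFrame(rows, columns=["serving_volume", "sex",
                                     "relative_change", "pp_change"])
    male = df[df["sex"] == "male"].set_index("serving_volume")["relative_change"].abs()
    df["order"] = df["serving_volume"].map(male.rank(ascending=False))
    return df.sort_values(["order", "serving_volume", "sex"]).drop(columns="order") \
        .reset_index(drop=True)
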