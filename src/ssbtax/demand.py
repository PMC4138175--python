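"""Tax scenario -> price change -> consumption change via price elasticities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import BEVERAGES, ElasticityMatrix

ELASTICITY_FORMS = ("power", "linear")


@dataclass(frozen=True)
class TaxScenario:
    """An ad valorem SSB tax and how much of it reaches the shelf price.

    ``elasticity_form`` selects the demand response: "power" is the
    constant-elasticity form (quantity scales as (1+p)^e), "linear" the
    first-order approximation (e x p).
    """

    tax_rate: float = 0.20
    pass_on_rate: float = 1.00
    elasticity_form: str = "power"

    def __post_init__(self) -> None:
        if self.tax_rate < 0:
            raise ValueError("tax_rate must be >= 0")
        if self.pass_on_rate < 0:
            raise ValueError("pass_on_rate must be >= 0")
        if self.elasticity_form not in ELASTICITY_FORMS:
            raise ValueError(f"elasticity_form must be one of {ELASTICITY_FORMS}")


def effective_price_change(scenario: TaxScenario) -> float:
    """Fractional consumer price rise: tax rate x pass-on rate."""
    return scenario.tax_rate * scenario.pass_on_rate


def consumption_change_fraction(price_change, elasticity, form: str = "power"):
    """Fractional change in consumption for a fractional price change.

    Accepts scalars or arrays (broadcast elementwise).
    """
    price_change = np.asarray(price_change, dtype=float)
    elasticity = np.asarray(elasticity, dtype=float)
    if form == "linear":
        out = elasticity * price_change
    elif form == "power":
        if np.any(price_change <= -1):
            raise ValueError("power form requires 1 + price_change > 0")
        out = (1.0 + price_change) ** elasticity - 1.0
    else:
        raise ValueError(f"unknown elasticity form: {form!r}")
    return out if out.ndim else float(out)


def shift_consumption(
    baseline: pd.DataFrame,
    scenario: TaxScenario,
    elasticities: ElasticityMatrix = ElasticityMatrix(),
) -> pd.DataFrame:
    """Per-band, per-beverage consumption deltas (litres/person/day).

    The SSB delta uses the own-price elasticity; milk, juice and diet use
    their cross-price elasticities. The same elasticities apply to every
    band (and sex).

    Parameters
    ----------
    baseline
        Tidy frame (band, beverage, mean) in litres/day; all four
        beverages must be present for every band.

    Returns
    -------
    Tidy frame (band, beverage, delta).
    """
    present = set(map(tuple, baseline[["band", "beverage"]].itertuples(index=False)))
    for band in baseline["band"].unique():
        missing = [b for b in BEVERAGES if (band, b) not in present]
        if missing:
            raise ValueError(f"band {band} missing beverages: {missing}")

    p = effective_price_change(scenario)
    out = baseline[["band", "beverage"]].copy()
    elast = baseline["beverage"].map(elasticities.value).to_numpy()
    frac = consumption_change_fraction(np.full(len(baseline), p), elast,
                                       scenario.elasticity_form)
    out["delta"] = baseline["mean"].to_numpy() * frac
    return out
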