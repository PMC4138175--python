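"""End-to-end run assembly: inputs -> all stages -> CSV bundle + manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bmi import fit_bmi_table, mean_heights
from .consumption import CategoryVolumeMap, estimate_consumption
from .demand import TaxScenario
from .params import ModelInputs
from .simulation import (MonteCarloConfig, run_deterministic, run_monte_carlo,
                         serving_size_tornado, two_way_sensitivity)
from .synthetic import (SyntheticConfig, generate_bmi_survey,
                        generate_consumption_survey, generate_population_pyramid)

log = logging.getLogger("ssbtax")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run. The manifest written by :func:`run_pipeline`
    records every field, so a run can be repeated exactly from it."""

    output_dir: str = "ssbtax_out"
    seed: int = 0
    # inputs: CSV paths, or synthetic generation when left as None
    bmi_csv: str | None = None
    consumption_csv: str | None = None
    pyramid_csv: str | None = None
    n_bmi_records: int = 50_000
    n_consumption_records: int = 20_000
    # scenario
    tax_rate: float = 0.20
    pass_on_rate: float = 1.00
    elasticity_form: str = "power"
    serving_volume: float = 330.0
    # stages
    n_draws: int = 10_000
    with_monte_carlo: bool = True
    with_sensitivity: bool = True
    with_tornado: bool = True
    with_plots: bool = False
    smooth_degrees: tuple[int, int] = (3, 2)
    log_level: str = "INFO"

    def scenario(self) -> TaxScenario:
        return TaxScenario(self.tax_rate, self.pass_on_rate, self.elasticity_form)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "smooth_degrees" in raw:
            raw["smooth_degrees"] = tuple(raw["smooth_degrees"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _load_or_generate(config: RunConfig):
    syn = SyntheticConfig(seed=config.seed, n_bmi_records=config.n_bmi_records)
    bmi = (pd.read_csv(config.bmi_csv) if config.bmi_csv
           else generate_bmi_survey(syn))
    consumption = (pd.read_csv(config.consumption_csv) if config.consumption_csv
                   else generate_consumption_survey(syn, config.n_consumption_records))
    pyramid = (pd.read_csv(config.pyramid_csv) if config.pyramid_csv
               else generate_population_pyramid(syn))
    return bmi, consumption, pyramid


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write the output bundle.

    Writes per-stage CSVs, a JSON manifest sufficient to reproduce the
    run, and a human-readable summary. On a stage failure the partial
    outputs are kept next to a ``FAILED`` marker naming the stage, and a
    :class:`StageError` is raised.
    """
    config.scenario()  # validate scenario before any stage runs
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    written: dict[str, object] = {}
    t0 = time.time()
    stage = "setup"
    try:
        stage = "inputs"
        bmi_records, cons_records, pyramid = _load_or_generate(config)
        log.info("inputs ready: %d BMI records, %d consumption records (%.1fs)",
                 len(bmi_records), len(cons_records), time.time() - t0)

        stage = "consumption"
        vmap = CategoryVolumeMap(serving_volume=config.serving_volume)
        consumption = estimate_consumption(cons_records, vmap)
        consumption.to_csv(out / "consumption_estimates.csv", index=False)

        stage = "bmi_fit"
        bmi_params = fit_bmi_table(bmi_records, smooth_degrees=config.smooth_degrees)
        heights = mean_heights(bmi_records)
        bmi_params.to_csv(out / "bmi_params.csv", index=False)
        heights.to_csv(out / "heights.csv", index=False)

        inputs = ModelInputs(consumption=consumption,
                             bmi_params=bmi_params[["band", "sex", "mean", "sd"]],
                             heights=heights, pyramid=pyramid)

        stage = "deterministic"
        result = run_deterministic(inputs, config.scenario())
        result.energy.to_csv(out / "energy_table.csv")
        result.bmi_deltas.to_csv(out / "bmi_deltas.csv", index=False)
        result.obesity_per_band.to_csv(out / "obesity_per_band.csv", index=False)
        result.obesity_by_sex.to_csv(out / "obesity_by_sex.csv", index=False)
        written["deterministic"] = result

        if config.with_monte_carlo:
            stage = "monte_carlo"
            mc = run_monte_carlo(inputs, config.scenario(),
                                 MonteCarloConfig(config.n_draws, config.seed))
            mc.energy.to_csv(out / "energy_intervals.csv", index=False)
            mc.bmi.to_csv(out / "bmi_intervals.csv", index=False)
            mc.obesity.to_csv(out / "obesity_intervals.csv", index=False)
            written["monte_carlo"] = mc

        if config.with_sensitivity:
            stage = "sensitivity"
            grid = two_way_sensitivity(inputs, elasticity_form=config.elasticity_form)
            grid.to_csv(out / "sensitivity_grid.csv", index=False)
            written["sensitivity"] = grid

        if config.with_tornado:
            stage = "tornado"
            tornado = serving_size_tornado(cons_records, inputs, config.scenario())
            tornado.to_csv(out / "serving_size_tornado.csv", index=False)
            written["tornado"] = tornado

        if config.with_plots:
            stage = "plots"
            _write_plots(out, inputs, written)

        stage = "report"
        _write_manifest(out, config)
        _write_summary(out, config, written)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return written


def _write_manifest(out: Path, config: RunConfig) -> None:
    manifest = {"ssbtax_version": __version__,
                "config": dataclasses.asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")


def _write_summary(out: Path, config: RunConfig, written: dict) -> None:
    res = written["deterministic"]
    lines = [
        f"SSB tax simulation (tax {config.tax_rate:.0%}, pass-on {config.pass_on_rate:.0%}, "
        f"{config.elasticity_form} elasticity form, serving {config.serving_volume:.0f} ml)",
        "",
        "Net energy-intake change (kJ/person/day) by age band:",
        res.energy["net"].round(2).to_string(),
        "",
        "Obesity change by sex:",
        res.obesity_by_sex.round(4).to_string(index=False),
        "",
    ]
    if "monte_carlo" in written:
        lines += ["95% uncertainty intervals, net energy change:",
                  written["monte_carlo"].energy.round(2).to_string(index=False), ""]
    (out / "summary.txt").write_text("\n".join(lines))


def _write_plots(out: Path, inputs: ModelInputs, written: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = written["deterministic"]
    fig, ax = plt.subplots(figsize=(7, 4))
    merged = inputs.bmi_params.merge(res.bmi_deltas, on=["band", "sex"])
    for sex, style in (("male", "o-"), ("female", "s-")):
        g = merged[merged["sex"] == sex]
        ax.plot(g["band"], g["mean"], style, label=f"{sex} reference")
        ax.plot(g["band"], g["mean"] + g["delta_bmi"], style, mfc="none",
                label=f"{sex} intervention")
    ax.set_ylabel("mean BMI (kg/m$^2$)")
    ax.tick_params(axis="x", rotation=60)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "mean_bmi_by_band.png", dpi=120)
    plt.close(fig)

    if "tornado" in written:
        t = written["tornado"]
        fig, ax = plt.subplots(figsize=(6, 3))
        for sex, colour in (("male", "tab:blue"), ("female", "tab:orange")):
            g = t[t["sex"] == sex]
            ax.barh([f"{v:.0f} ml ({sex})" for v in g["serving_volume"]],
                    100 * g["relative_change"], color=colour)
        ax.set_xlabel("relative obesity change (%)")
        fig.tight_layout()
        fig.savefig(out / "serving_size_tornado.png", dpi=120)
        plt.close(fig)
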