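"""BMI distributions: cleaning, fitting, smoothing, the prevalence shift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

import ssbtax as st
from ssbtax.bmi import (fit_distribution, gamma_from_moments,
                        lognormal_from_moments, mean_heights, weighted_quantile)


def _records(bmi, height=1.7, age=30.0, sex="male"):
    bmi = np.asarray(bmi, float)
    return pd.DataFrame({"age": age, "sex": sex, "height": height,
                         "weight": bmi * height**2})


class TestCleaning:
    def test_percentile_trim_keeps_98_percent(self):
        rng = np.random.default_rng(0)
        rec = _records(rng.uniform(18, 35, 1000))
        assert abs(len(st.clean_bmi(rec)) - 980) <= 1

    def test_identical_values_all_retained(self):
        rec = _records(np.full(200, 27.0))
        assert len(st.clean_bmi(rec)) == 200

    def test_trim_is_weighted(self):
        rng = np.random.default_rng(1)
        bmi = np.concatenate([rng.normal(25, 3, 500), [60.0]])
        rec = _records(bmi)
        rec["survey_weight"] = 1.0
        rec.loc[len(rec) - 1, "survey_weight"] = 1e-9  # outlier nearly weightless
        cleaned = st.clean_bmi(rec)
        assert 60.0 not in cleaned["bmi"].values

    def test_implausible_measurements_rejected(self):
        with pytest.raises(ValueError):
            st.clean_bmi(pd.DataFrame({"age": [30], "sex": ["male"],
                                       "height": [0.2], "weight": [70]}))
        with pytest.raises(ValueError):
            st.clean_bmi(pd.DataFrame(columns=["age", "sex", "height", "weight"]))


class TestFitting:
    @pytest.mark.parametrize("family", ["lognormal", "gamma"])
    def test_parameter_recovery_on_simulated_cell(self, family):
        rng = np.random.default_rng(2)
        if family == "lognormal":
            bmi = rng.lognormal(*lognormal_from_moments(27.0, 6.0), 50_000)
        else:
            a, scale = gamma_from_moments(27.0, 6.0)
            bmi = rng.gamma(a, scale, 50_000)
        fit = fit_distribution(bmi, family=family)
        assert abs(fit.mean / 27.0 - 1) < 0.01
        assert np.isfinite(fit.residual)

    def test_gamma_fit_on_same_cell_is_comparable(self):
        # both skewed families fitted to the same lognormal cell: the
        # gamma residual stays the same order of magnitude, the baseline
        # prevalences of the SA-typical cells stay within one percentage
        # point, and the tax-relevant prevalence *change* under a mean
        # shift agrees to a few hundredths of a point
        rng = np.random.default_rng(3)
        for mean, sd in [(22.0, 4.0), (30.2, 6.5)]:
            mu, sigma = lognormal_from_moments(mean, sd)
            bmi = rng.lognormal(mu, sigma, 50_000)
            fits = {fam: fit_distribution(bmi, family=fam)
                    for fam in ("lognormal", "gamma")}
            assert fits["gamma"].residual < 20 * fits["lognormal"].residual
            prev, change = {}, {}
            for fam, f in fits.items():
                base, shifted = st.shift_and_prevalence(f.mean, f.sd, -0.19,
                                                        family=fam)
                prev[fam], change[fam] = base, shifted - base
            assert abs(prev["lognormal"] - prev["gamma"]) < 0.01
            assert abs(change["lognormal"] - change["gamma"]) < 5e-4

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="30"):
            fit_distribution(np.full(10, 25.0))

    def test_moment_conversions_roundtrip(self):
        mu, sigma = lognormal_from_moments(27.0, 6.0)
        d = stats.lognorm(s=sigma, scale=np.exp(mu))
        assert d.mean() == pytest.approx(27.0)
        assert d.std() == pytest.approx(6.0)
        a, scale = gamma_from_moments(27.0, 6.0)
        assert a * scale == pytest.approx(27.0)


class TestSmoothing:
    MIDS = np.arange(22.0, 22.0 + 5 * 13, 5.0)

    def test_exact_quadratic_unchanged_at_degree_two(self):
        vals = 0.01 * self.MIDS**2 - 0.5 * self.MIDS + 30
        out = st.smooth_across_ages(vals, self.MIDS, 2)
        np.testing.assert_allclose(out, vals, atol=1e-9)

    def test_degree_zero_is_grand_mean(self):
        vals = np.linspace(22, 30, 13)
        out = st.smooth_across_ages(vals, self.MIDS, 0)
        np.testing.assert_allclose(out, vals.mean(), atol=1e-12)

    def test_nested_degrees_reduce_residual(self):
        rng = np.random.default_rng(4)
        vals = 25 + 0.1 * self.MIDS + rng.normal(0, 0.5, 13)
        r2 = ((st.smooth_across_ages(vals, self.MIDS, 2) - vals) ** 2).sum()
        r3 = ((st.smooth_across_ages(vals, self.MIDS, 3) - vals) ** 2).sum()
        assert r3 <= r2

    def test_excessive_degree_rejected(self):
        with pytest.raises(ValueError):
            st.smooth_across_ages(np.ones(5), self.MIDS[:5], 5)


class TestEnergyToBMI:
    @pytest.mark.parametrize("energy, conv, expected", [
        (-94.0, 94.0, -1.0),
        (-45.78, 94.0, -0.487),
        (0.0, 94.0, 0.0),
    ])
    def test_delta_weight(self, energy, conv, expected):
        assert st.delta_weight(energy, conv) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("wdelta, height, expected", [
        (-0.487, 1.601, -0.19),  # female mean height
        (-0.487, 1.693, -0.17),  # male mean height
        (0.0, 1.65, 0.0),
    ])
    def test_delta_bmi(self, wdelta, height, expected):
        assert st.delta_bmi(wdelta, height) == pytest.approx(expected, abs=5e-3)

    def test_degenerate_arguments_rejected(self):
        with pytest.raises(ValueError):
            st.delta_weight(-10, 0.0)
        with pytest.raises(ValueError):
            st.delta_bmi(-0.5, 0.0)


class TestPrevalenceShift:
    def test_matches_closed_form_lognormal_tail(self):
        base, shifted = st.shift_and_prevalence(27.0, 6.0, -0.19, 30.0)
        sigma2 = np.log1p((6.0 / 27.0) ** 2)
        oracle_base = stats.norm.sf(
            (np.log(30.0) - (np.log(27.0) - sigma2 / 2)) / np.sqrt(sigma2))
        assert base == pytest.approx(oracle_base, abs=1e-12)
        assert base == pytest.approx(0.2777, abs=5e-5)
        assert shifted == pytest.approx(0.26793, abs=5e-5)
        assert (shifted - base) / base == pytest.approx(-0.0352, abs=5e-4)

    def test_zero_shift_is_identity(self):
        base, shifted = st.shift_and_prevalence(27.0, 6.0, 0.0)
        assert shifted == base

    def test_shifted_mean_must_stay_positive(self):
        with pytest.raises(ValueError):
            st.shift_and_prevalence(27.0, 6.0, -27.0)

    def test_sigma_hold_mode_also_shifts_downward(self):
        base, shifted = st.shift_and_prevalence(27.0, 6.0, -0.19, hold="sigma")
        assert shifted < base

    @given(mean=hst.floats(20.0, 35.0), sd=hst.floats(2.0, 9.0),
           drop=hst.floats(0.01, 1.0),
           family=hst.sampled_from(["lognormal", "gamma"]))
    @settings(max_examples=100, derandomize=True)
    def test_rose_monotonicity(self, mean, sd, drop, family):
        # prevalence strictly decreases when the mean falls, both families
        base, shifted = st.shift_and_prevalence(mean, sd, -drop, family=family)
        assert shifted < base


class TestHeadcount:
    def _prev(self, baseline, shifted):
        rows = [(b, s, baseline, shifted)
                for b in st.params.MODEL_BANDS for s in st.params.SEXES]
        return pd.DataFrame(rows, columns=["band", "sex", "baseline", "shifted"])

    def test_count_change_arithmetic(self):
        pyr = st.default_pyramid()
        pyr["count"] = 1_000_000 // 26
        res = st.obesity_headcount(self._prev(0.10, 0.095), pyr)
        total = res["by_sex"].set_index("sex").loc["all", "count_change"]
        assert total == pytest.approx(-0.005 * (1_000_000 // 26) * 26)

    def test_zero_population_zero_counts(self):
        pyr = st.default_pyramid()
        pyr["count"] = 0
        res = st.obesity_headcount(self._prev(0.10, 0.095), pyr)
        assert (res["per_band"]["count_change"] == 0).all()

    def test_calibrated_relative_change(self):
        # baseline prevalence 13.2% with a -0.5 point shift is a 3.8% fall
        res = st.obesity_headcount(self._prev(0.132, 0.127), st.default_pyramid())
        rel = res["by_sex"].set_index("sex").loc["male", "relative_change"]
        assert rel == pytest.approx(-0.005 / 0.132, abs=1e-12)
        assert round(100 * rel, 1) == -3.8

    def test_band_mismatch_rejected(self):
        pyr = st.default_pyramid().iloc[:-2]
        with pytest.raises(ValueError, match="missing"):
            st.obesity_headcount(self._prev(0.1, 0.09), pyr)


def test_fit_bmi_table_recovers_generator_parameters(bmi_survey):
    table = st.fit_bmi_table(bmi_survey)
    merged = table.merge(st.default_bmi_params(), on=["band", "sex"],
                         suffixes=("_fit", "_true"))
    # smoothing + trimming + fitting keep cells close to the generating values
    assert (np.abs(merged["mean_fit"] / merged["mean_true"] - 1) < 0.03).all()
    assert (np.abs(merged["sd_fit"] / merged["sd_true"] - 1) < 0.12).all()


def test_mean_heights_recovers_configuration(bmi_survey):
    h = mean_heights(bmi_survey)
    assert h.query("sex=='male'")["height"].mean() == pytest.approx(1.693, abs=0.01)
    assert h.query("sex=='female'")["height"].mean() == pytest.approx(1.601, abs=0.01)


def test_weighted_quantile_matches_numpy_for_equal_weights():
    rng = np.random.default_rng(5)
    x = rng.normal(size=501)
    w = np.ones_like(x)
    assert weighted_quantile(x, w, 0.5) == pytest.approx(np.median(x), abs=1e-9)
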