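"""Synthetic generators: determinism, noiseless exactness, consumer round-trips."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from seedphys.anova import anova3
from seedphys.exceptions import InvalidInputError
from seedphys.growth import fit_logistic
from seedphys.netsig import rank_nodes
from seedphys.phototherm import cumulative_ptp, validate_weather
from seedphys.simulate import (
    BiochemParams,
    GrowthParams,
    SyntheticScenario,
    WeatherParams,
    YieldParams,
    gen_biochem,
    gen_growth,
    gen_plots,
    gen_weather,
    write_all,
)
from seedphys.yields import PlotHarvest, compare_treatments, cottonseed_yield, treatment_means


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self, scenario):
        other = SyntheticScenario(seed=scenario.seed + 1)
        for gen in (
            lambda s: gen_weather(s, 2012),
            gen_growth,
            gen_plots,
            gen_biochem,
        ):
            a, b = gen(scenario), gen(SyntheticScenario(seed=scenario.seed))
            pd.testing.assert_frame_equal(a, b)
            assert not gen(other).equals(a)

    def test_csv_output_hash_stable(self, tmp_path, scenario):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_all(scenario, d1)
        write_all(scenario, d2)
        for name in ("weather", "growth", "plots", "biochem"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()
            truth = json.loads((d1 / f"{name}.truth.json").read_text())
            assert truth["seed"] == scenario.seed


class TestWeatherGenerator:
    def test_zero_noise_exact_sinusoid(self, noiseless_scenario):
        w = gen_weather(noiseless_scenario, 2012)
        p = noiseless_scenario.weather
        assert len(w) == 365
        np.testing.assert_allclose(w["tmax"] - w["tmin"], p.diurnal_range)
        np.testing.assert_allclose(w["tavg"], (w["tmax"] + w["tmin"]) / 2)
        doy = np.arange(1, 366)
        expected = p.mean_temp + p.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - p.peak_doy) / 365
        )
        np.testing.assert_allclose(w["tavg"], expected)
        assert (w["srad"] >= 0).all()

    def test_output_feeds_ptp_without_warnings(self, scenario):
        w = gen_weather(scenario, 2013)
        validate_weather(w)
        s = cumulative_ptp(w, "2013-06-15", "2013-07-30")
        assert s.cumulative > 0


class TestGrowthGenerator:
    def test_zero_noise_points_on_logistic(self, noiseless_scenario):
        g = gen_growth(noiseless_scenario)
        w, k, tm = noiseless_scenario.growth.groups["default"]
        expected = w / (1 + np.exp(-k * (g["daa"] - tm)))
        np.testing.assert_allclose(g["weight_g_per_100"], expected)

    def test_round_trip_recovery_noiseless(self, noiseless_scenario):
        g = gen_growth(noiseless_scenario)
        fit = fit_logistic(g["daa"], g["weight_g_per_100"])
        w, k, tm = noiseless_scenario.growth.groups["default"]
        assert fit.w_asym == pytest.approx(w, abs=1e-6)
        assert fit.k == pytest.approx(k, abs=1e-6)
        assert fit.t_m == pytest.approx(tm, abs=1e-6)

    def test_unknown_group_rejected(self, scenario):
        with pytest.raises(InvalidInputError):
            gen_growth(scenario, "nope")

    def test_parameter_recovery_monte_carlo(self):
        """Median relative error of the recovered asymptote stays under 5% at
        5%-of-asymptote noise (50 replicates; the acceptance suite runs 200)."""
        errs = []
        for seed in range(50):
            sc = SyntheticScenario(seed=seed)
            g = gen_growth(sc)
            fit = fit_logistic(g["daa"], g["weight_g_per_100"])
            errs.append(abs(fit.w_asym - 6.0) / 6.0)
        assert np.median(errs) < 0.05


class TestPlotsGenerator:
    def test_zero_cv_reproduces_configured_means(self, noiseless_scenario):
        plots = gen_plots(noiseless_scenario)
        plots["y"] = [
            cottonseed_yield(PlotHarvest(r.boll_density, r.seeds_per_boll, r.seed_weight_100))
            for r in plots.itertuples()
        ]
        means = treatment_means(plots, ["year", "fertility", "management"], ["y"]).set_index(
            ["year", "fertility", "management"]
        )
        from seedphys.datasets import cottonseed_yields

        for r in cottonseed_yields().itertuples():
            assert means.loc[(r.year, r.fertility, r.management), "y"] == pytest.approx(
                r.yield_kg_ha
            )

    def test_noiseless_output_reproduces_published_increases(self, noiseless_scenario):
        plots = gen_plots(noiseless_scenario)
        plots["y"] = [
            cottonseed_yield(PlotHarvest(r.boll_density, r.seeds_per_boll, r.seed_weight_100))
            for r in plots.itertuples()
        ]
        m = treatment_means(plots, ["year", "fertility", "management"], ["y"]).set_index(
            ["year", "fertility", "management"]
        )["y"]
        assert compare_treatments(
            m[(2012, "LF", "CM")], m[(2012, "LF", "IMS1")]
        ).increase_over_cm == pytest.approx(26.34, abs=0.005)
        assert compare_treatments(
            m[(2013, "LF", "CM")], m[(2013, "LF", "IMS1")]
        ).increase_over_cm == pytest.approx(19.00, abs=0.005)

    def test_full_factorial_shape_and_validity(self, scenario):
        plots = gen_plots(scenario)
        assert len(plots) == 2 * 2 * 3 * 3
        assert (plots["boll_density"] > 0).all()
        # every record passes the consumer's validation
        for r in plots.itertuples():
            PlotHarvest(r.boll_density, r.seeds_per_boll, r.seed_weight_100)

    def test_management_effect_power(self):
        """A configured management effect is detected at alpha=0.01 in nearly
        all replicates (20 seeds here; the acceptance suite covers more)."""
        hits = 0
        for seed in range(20):
            plots = gen_plots(SyntheticScenario(seed=seed))
            plots["y"] = [
                cottonseed_yield(
                    PlotHarvest(r.boll_density, r.seeds_per_boll, r.seed_weight_100)
                )
                for r in plots.itertuples()
            ]
            res = anova3(plots, "y")
            hits += res.table.loc["management", "p"] < 0.01
        assert hits >= 19


class TestBiochemGenerator:
    def test_shape_and_balance(self, scenario):
        b = gen_biochem(scenario)
        assert len(b) == 96
        assert list(b.columns) == ["seed_weight_100", *BiochemParams().nodes]
        assert (b[list(BiochemParams().nodes)] > 0).all().all()

    def test_zero_weights_yield_no_signal(self):
        params = BiochemParams(target_weights=(0.0,) * 8, target_noise_sd=1.0)
        b = gen_biochem(SyntheticScenario(seed=3, biochem=params))
        out = rank_nodes(b)
        # no node should look strongly informative about pure noise
        assert out["nmi_pct"].max() < 15.0

    def test_single_weight_puts_that_node_first(self):
        params = BiochemParams(target_weights=(0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0))
        b = gen_biochem(SyntheticScenario(seed=3, biochem=params))
        assert rank_nodes(b)["node"].iloc[0] == "c_inv"

    def test_ladder_must_be_strictly_ordered(self):
        with pytest.raises(InvalidInputError):
            BiochemParams(fidelity=(1.0, 0.9, 0.9, 0.7, 0.6, 0.5, 0.4, 0.0))

    def test_effect_order_recovered(self, scenario):
        out = rank_nodes(gen_biochem(scenario))
        assert list(out["node"]) == list(BiochemParams().nodes)


class TestScenarioIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "seed: 9\nweather:\n  mean_temp: 17.0\ngrowth:\n  noise_sd: 0.1\n"
        )
        sc = SyntheticScenario.from_yaml(cfg)
        assert sc.seed == 9
        assert sc.weather.mean_temp == 17.0
        assert sc.growth.noise_sd == 0.1

    def test_write_all_files_and_sidecars(self, tmp_path, scenario):
        written = write_all(scenario, tmp_path / "out")
        for name, path in written.items():
            assert path.exists()
            assert path.with_suffix("").with_suffix(".truth.json").exists() or (
                path.parent / f"{name}.truth.json"
            ).exists()
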