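import dataclasses

import numpy as np
import pandas as pd
import pytest

import fertisim as fs
from fertisim.config import config_from_mapping, dump_config, load_config
from fertisim.errors import ConfigurationError


def water_ledger_residual(config, result):
    sw = result.soil_water
    dep0 = (config.soil.fc - config.soil.swc_init) * 10.0 * config.roots.initial_depth
    return (
        dep0
        + sw.cum_new_soil_deficit
        + sw.cum_eta
        - sw.cum_rain
        - sw.cum_irrigation
        + sw.cum_drainage
        - sw.depletion
    )


class TestRunSeason:
    def test_reaches_maturity_with_plausible_cycle(self, baseline_season):
        assert baseline_season.mature
        assert 90 <= baseline_season.cycle_length <= 120

    def test_thermal_sum_in_maturity_window(self, baseline_season, default_config):
        g = default_config.growth
        assert g.ts_min <= baseline_season.crop.tt_cum <= g.ts_max + 25

    def test_deterministic(self, med_weather, default_config, baseline_season):
        again = fs.run_season(default_config, med_weather)
        pd.testing.assert_frame_equal(again.daily, baseline_season.daily)
        assert again.final_sdw == baseline_season.final_sdw
        assert again.tfy == baseline_season.tfy

    def test_water_and_n_ledgers_close(self, default_config, baseline_season):
        assert abs(water_ledger_residual(default_config, baseline_season)) < 1e-6
        assert abs(baseline_season.soil_n.ledger_residual()) < 1e-6

    def test_totals_match_daily_table(self, baseline_season):
        d = baseline_season.daily
        assert baseline_season.n_input == pytest.approx(d.n_fertilized.sum())
        assert baseline_season.n_uptake == pytest.approx(d.n_uptake.sum())
        assert baseline_season.water_applied == pytest.approx(d.irrigation.sum())
        assert baseline_season.final_sdw == pytest.approx(d.sdw.iloc[-1])
        assert baseline_season.n_input == pytest.approx(baseline_season.plan.total_n)

    def test_non_nvz_demand_always_met(self, baseline_season):
        assert (baseline_season.daily.n_factor >= 1.0 - 1e-9).all()

    def test_stress_free_after_refill_days(self, baseline_season):
        d = baseline_season.daily
        refill_days = d.index[d.irrigation > 0]
        for i in refill_days:
            if i + 1 in d.index:
                assert d.loc[i + 1, "ks"] == pytest.approx(1.0)

    def test_rainfed_season_grows_less(self, med_weather, default_config,
                                       baseline_season):
        dry = fs.run_season(
            dataclasses.replace(default_config, irrigation_enabled=False),
            med_weather,
        )
        assert dry.final_sdw < baseline_season.final_sdw

    def test_nvz_cap_and_reduced_growth(self, med_weather, default_config,
                                        baseline_season):
        nvz_cfg = dataclasses.replace(
            default_config,
            soil_n=dataclasses.replace(default_config.soil_n, nvz=True),
        )
        res = fs.run_season(nvz_cfg, med_weather)
        assert res.n_input <= 170.0 + 1e-9
        assert res.plan.total_n <= 170.0 + 1e-9
        assert res.final_sdw <= baseline_season.final_sdw
        assert abs(res.soil_n.ledger_residual()) < 1e-6

    def test_swc_stays_within_physical_bounds(self, baseline_season, default_config):
        swc = baseline_season.daily.swc_10_30
        assert (swc >= default_config.soil.wp - 1e-12).all()
        assert (swc <= default_config.soil.fc + 1e-12).all()

    def test_empty_weather_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            fs.run_season(default_config, [])


class TestSdwCheckInjection:
    def test_matching_observation_leaves_run_unchanged(
        self, med_weather, default_config, baseline_season,
        self_consistent_check_params,
    ):
        obs = float(baseline_season.daily.loc[
            baseline_season.daily.dat == 40, "sdw"].iloc[0])
        cfg = dataclasses.replace(
            default_config, sdw_checks=((40, obs),),
            sdwcheck_params=self_consistent_check_params,
        )
        res = fs.run_season(cfg, med_weather)
        assert res.final_sdw == pytest.approx(baseline_season.final_sdw, rel=0.01)

    def test_higher_observation_raises_final_biomass(
        self, med_weather, default_config, baseline_season, recovery_check_params
    ):
        obs = 1.25 * float(baseline_season.daily.loc[
            baseline_season.daily.dat == 40, "sdw"].iloc[0])
        cfg = dataclasses.replace(
            default_config, sdw_checks=((40, obs),),
            sdwcheck_params=recovery_check_params,
        )
        res = fs.run_season(cfg, med_weather)
        assert res.final_sdw > baseline_season.final_sdw

    def test_second_identity_check_is_idempotent(
        self, med_weather, default_config, baseline_season,
        self_consistent_check_params,
    ):
        d = baseline_season.daily
        obs40 = float(d.loc[d.dat == 40, "sdw"].iloc[0])
        obs50 = float(d.loc[d.dat == 50, "sdw"].iloc[0])
        cfg = dataclasses.replace(
            default_config, sdw_checks=((40, obs40), (50, obs50)),
            sdwcheck_params=self_consistent_check_params,
        )
        res = fs.run_season(cfg, med_weather)
        assert res.final_sdw == pytest.approx(baseline_season.final_sdw, rel=0.01)


@pytest.fixture(scope="module")
def grid(med_weather):
    return fs.run_scenarios(fs.SimulationConfig(), med_weather)


class TestScenarioGrid:

    def test_non_nvz_yield_invariant_to_som(self, grid):
        results, _ = grid
        lo, hi = results[(1.4, False)], results[(2.8, False)]
        assert hi.final_sdw == pytest.approx(lo.final_sdw, rel=0.005)
        assert hi.tfy == pytest.approx(lo.tfy, rel=0.005)

    def test_fertilizer_input_decreases_with_som(self, grid):
        results, _ = grid
        assert results[(2.8, False)].n_input < results[(1.4, False)].n_input

    def test_nvz_cells_capped_and_below_non_nvz(self, grid):
        results, _ = grid
        for som in (1.4, 2.8):
            nvz, free = results[(som, True)], results[(som, False)]
            assert nvz.n_input <= 170.0 + 1e-9
            assert nvz.n_uptake <= free.n_uptake
            assert nvz.tfy <= free.tfy

    def test_nvz_outcomes_improve_with_som(self, grid):
        results, _ = grid
        assert results[(2.8, True)].n_uptake > results[(1.4, True)].n_uptake
        assert results[(2.8, True)].tfy > results[(1.4, True)].tfy

    def test_summary_table_shape(self, grid):
        _, table = grid
        assert set(table.columns) >= {"som", "nvz", "nupt", "ninp", "nsom", "tdw", "yld"}
        assert len(table) == 4


class TestConfigIO:
    def test_defaults_round_trip(self, tmp_path, default_config):
        path = tmp_path / "config.yaml"
        dump_config(default_config, path)
        loaded = load_config(path)
        assert loaded.growth == default_config.growth
        assert loaded.thermal == default_config.thermal
        assert loaded.stages == default_config.stages
        assert loaded.soil_n == default_config.soil_n

    def test_case_insensitive_crop_keys(self):
        cfg = config_from_mapping({"crop": {"Beta1": 10.0, "TSMin": 1200}})
        assert cfg.growth.beta1 == 10.0
        assert cfg.growth.ts_min == 1200

    def test_unknown_crop_key_listed(self):
        with pytest.raises(ConfigurationError, match="beta_one"):
            config_from_mapping({"crop": {"beta_one": 10.0}})

    def test_na_values_ignored(self):
        cfg = config_from_mapping({"crop": {"mulch_ke": "NA", "albedo_pt": "NA"}})
        assert cfg.mulch_ke_reduction == 0.0

    def test_raw_percent_conversion(self):
        cfg = config_from_mapping({"crop": {"raw": 40}})
        assert cfg.soil.raw_frac == pytest.approx(0.40)


class TestCli:
    def test_simulate_and_outputs(self, tmp_path):
        from click.testing import CliRunner

        from fertisim.cli import main

        daily = tmp_path / "daily.csv"
        schedule = tmp_path / "schedule.csv"
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["simulate", "--daily-out", str(daily), "--schedule-out", str(schedule)],
        )
        assert result.exit_code == 0, result.output
        assert "fresh yield" in result.output
        assert pd.read_csv(daily).shape[0] > 60
        sched = pd.read_csv(schedule)
        assert list(sched.columns) == ["dat", "n_kg_ha", "water_mm"]

    def test_evaluate_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from fertisim.cli import main

        pairs = tmp_path / "pairs.csv"
        pairs.write_text("observed,simulated\n2,3\n4,3\n")
        result = CliRunner().invoke(main, ["evaluate", str(pairs)])
        assert result.exit_code == 0, result.output
        assert "RMSE=1" in result.output
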