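"""Closed-loop daily season simulation wiring weather, soil water, nitrogen
and growth, with in-season growth-check injection and the SOM x NVZ scenario
runner.

The fixed daily update order is: reference ET -> thermal time -> stage and
root update -> irrigation scheduling and water balance -> potential growth ->
N demand -> fertigation planning, mineralization and uptake -> stress-limited
growth -> flowering heat-stress tally -> maturity check. A season stops at
crop maturity or when the weather series is exhausted.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import growth as gr
from . import nitrogen as ni
from . import soilwater as sw
from . import weather as wx
from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

#: Planning horizon of the fertigation scheduler (days of forecast demand).
FERTIGATION_HORIZON = 7
#: Documented seed for the bundled scenario weather.
SCENARIO_WEATHER_SEED = 20150710


@dataclass
class SimulationConfig:
    """Everything needed to simulate one season (weather comes separately)."""

    site: wx.Site = field(default_factory=lambda: wx.Site(latitude=41.53, altitude=75))
    thermal: wx.ThermalParams = field(default_factory=wx.ThermalParams)
    growth: gr.GrowthParams = field(default_factory=gr.GrowthParams)
    yields: gr.YieldParams = field(default_factory=gr.YieldParams)
    stages: sw.StageTable = field(default_factory=sw.StageTable)
    soil: sw.SoilProfile = field(default_factory=sw.SoilProfile)
    roots: sw.RootParams = field(default_factory=sw.RootParams)
    ncurve: ni.NCurveParams = field(default_factory=ni.NCurveParams)
    soil_n: ni.SoilNParams = field(default_factory=ni.SoilNParams)
    sdwcheck_params: gr.SdwCheckParams = field(default_factory=gr.SdwCheckParams)
    seedling_weight: float = 0.5  # g/plant at transplanting
    irrigation_enabled: bool = True
    fertigation_enabled: bool = True
    flowering_stress_coeff: float = 0.01  # fractional TFY loss per stress day
    mulch_ke_reduction: float = 0.0  # percent reduction of Ke under film mulch
    mulch_kcb_increase: float = 0.0  # percent increase of Kcb under film mulch
    sdw_checks: tuple[tuple[int, float], ...] = ()  # (dat, observed SDW t/ha)

    def __post_init__(self):
        if self.seedling_weight <= 0:
            raise ConfigurationError("seedling_weight must be > 0")


@dataclass
class SeasonResult:
    """Daily table plus season totals and the emitted fertigation plan."""

    daily: pd.DataFrame
    final_sdw: float
    tfy: float
    n_uptake: float
    n_input: float
    n_mineralized: float
    n_leached: float
    water_applied: float
    cycle_length: int
    mature: bool
    plan: ni.FertigationPlan
    crop: gr.CropState
    soil_water: sw.SoilWaterState
    soil_n: ni.SoilNState


def _phase(dat: int, stages: sw.StageTable) -> str:
    if dat <= stages.t1:
        return "initial"
    if dat <= stages.t3:
        return "mid"
    return "final"


def apply_sdw_check(
    crop: gr.CropState,
    thermal: wx.ThermalParams,
    observed_sdw: float,
    g: gr.GrowthParams,
    k: gr.SdwCheckParams,
) -> tuple[wx.ThermalParams, float]:
    """Apply the in-season growth check at the current simulated biomass.

    Returns the adjusted thermal parameters and the new expected final
    biomass (never below the crop's current biomass). Applying a check that
    matches the simulation (CheckPO = 1, self-calibrated polynomials) leaves
    the continuation unchanged up to polynomial anchoring tolerance.
    """
    new_t_m2, new_beta1 = gr.sdw_check(crop.sdw, observed_sdw, thermal, g, k)
    adjusted = wx.ThermalParams(
        tbase=thermal.tbase, t_m1=thermal.t_m1, t_m2=new_t_m2
    )
    return adjusted, max(new_beta1, crop.sdw)


def run_season(
    config: SimulationConfig, weather: Sequence[wx.DailyWeather]
) -> SeasonResult:
    """Simulate one season day by day; deterministic given inputs.

    If the weather series ends before the crop matures, the partial result
    is returned with ``mature=False`` so the caller can diagnose it; an
    empty series raises a configuration error.
    """
    if not weather:
        raise ConfigurationError("weather series is empty")
    g = config.growth
    thermal = config.thermal
    checks = dict(config.sdw_checks)

    crop = gr.CropState(
        sdw=config.seedling_weight * g.density * 0.01,
        expected_beta1=g.beta1,
    )
    beta1_checked = g.beta1  # asymptote after any growth-check adjustment
    soil_water = sw.SoilWaterState(
        depletion=(config.soil.fc - config.soil.swc_init)
        * 10.0
        * config.roots.initial_depth,
        root_depth=config.roots.initial_depth,
        swc_10_30=config.soil.swc_init,
    )
    soil_n = ni.SoilNState(
        mineral_n=config.soil_n.mineral_n_init,
        initial_mineral_n=config.soil_n.mineral_n_init,
    )
    plan = ni.FertigationPlan()
    wetted = config.roots.wetted_fraction(g.density)
    rows = []
    gdd_recent: list[float] = []

    for day in weather:
        dat = crop.dat + 1
        # growth check injected before the day's update, on yesterday's biomass
        if crop.dat in checks:
            thermal, new_b1 = apply_sdw_check(
                crop, thermal, checks[crop.dat], g, config.sdwcheck_params
            )
            beta1_checked = new_b1
            # the NVZ budget adjustment (below, daily) re-caps this if needed
            crop.expected_beta1 = max(crop.sdw, new_b1)
            logger.info(
                "DAT %d: growth check -> T_M2=%.2f, expected beta1=%.3f",
                crop.dat, thermal.t_m2, beta1_checked,
            )

        day_et0 = wx.et0(day, config.site)
        gdd = wx.thermal_time(day, thermal)
        gdd_recent.append(gdd)
        mean_gdd = sum(gdd_recent[-7:]) / len(gdd_recent[-7:])

        kcb = sw.stage_coefficient(dat, config.stages, "kcb")
        kc = sw.stage_coefficient(dat, config.stages, "kc")
        kcb *= 1.0 + config.mulch_kcb_increase / 100.0
        ke_base = max(0.0, kc - kcb) * (1.0 - config.mulch_ke_reduction / 100.0)

        irrigation = 0.0
        if config.irrigation_enabled:
            req = sw.irrigation_requirement(soil_water, config.soil, config.roots)
            if req > 0:
                irrigation = req * wetted
                logger.info("DAT %d: irrigation %.1f mm", dat, irrigation)
        soil_water, eta, etc, drainage, ks = sw.water_balance_step(
            soil_water, day.rain, irrigation, day_et0, kcb, ke_base,
            config.soil, config.roots, dat,
        )
        water_stress = gr.water_stress_multiplier(min(eta, etc), etc, g.kts)

        # potential (water-limited) growth increment drives today's N demand
        b1 = crop.expected_beta1
        pot_inc = (
            gr.potential_sdw(crop.tt_cum + gdd, g, b1)
            - gr.potential_sdw(crop.tt_cum, g, b1)
        )
        if crop.in_lag and pot_inc <= g.lag_increment:
            pot_inc = g.lag_increment
        pot_inc = max(0.0, min(pot_inc, b1 - crop.sdw))
        demand = max(
            0.0,
            ni.cumulative_n_demand(crop.sdw + pot_inc * water_stress, config.ncurve)
            - ni.cumulative_n_demand(crop.sdw, config.ncurve),
        )

        mineralized = ni.mineralization_step(
            config.soil_n, config.soil, soil_water.root_depth, day.tmean
        )
        phase = _phase(dat, config.stages)
        root_zone_water = max(
            config.soil.fc * 10.0 * soil_water.root_depth - soil_water.depletion,
            0.0,
        )
        fert = 0.0
        if config.fertigation_enabled:
            horizon_sdw = gr.potential_sdw(
                crop.tt_cum + FERTIGATION_HORIZON * mean_gdd, g, b1
            )
            forecast = max(
                0.0,
                ni.cumulative_n_demand(min(horizon_sdw, b1), config.ncurve)
                - ni.cumulative_n_demand(crop.sdw, config.ncurve),
            )
            # top up for same-day percolation losses so demand stays covered
            # through the storm (complete-mixing leach fraction)
            reserve = config.soil_n.reserve(phase)
            leach_frac = (
                min(1.0, drainage / root_zone_water)
                if drainage > 0 and root_zone_water > 0
                else 0.0
            )
            top_up = 1.0 / (1.0 - min(leach_frac, 0.9))
            forecast = (forecast + reserve) * top_up - reserve
            event = ni.plan_fertigation(soil_n, forecast, phase, config.soil_n)
            if event is not None:
                fert = event
                plan.add(dat, fert, irrigation)
                logger.info("DAT %d: fertigation %.1f kg N/ha", dat, fert)
        if config.soil_n.nvz:
            remaining_days = max(0.0, (g.ts_max - crop.tt_cum) / max(mean_gdd, 1.0))
            budget = (
                max(0.0, config.soil_n.nvz_cap - (soil_n.cum_fertilized + fert))
                + max(0.0, soil_n.mineral_n + fert - config.soil_n.reserve(phase))
                + mineralized * remaining_days
            )
            w_star = ni.adjust_potential_under_n_limit(
                budget, crop.sdw,
                dataclasses.replace(g, beta1=beta1_checked), config.ncurve,
            )
            crop.expected_beta1 = min(beta1_checked, max(crop.sdw, w_star))

        soil_n, uptake, n_factor = ni.soil_n_step(
            soil_n, mineralized, fert, demand, drainage,
            root_zone_water, config.soil_n.reserve(phase),
        )

        crop = gr.daily_growth(crop, gdd, water_stress, n_factor, g)
        crop = gr.flowering_stress_update(crop, day, g)
        rows.append(
            dict(
                dat=dat, date=day.date, et0=day_et0, eta=eta, ks=ks,
                gdd=gdd, tt_cum=crop.tt_cum, sdw=crop.sdw,
                expected_beta1=crop.expected_beta1,
                depletion=soil_water.depletion, swc_10_30=soil_water.swc_10_30,
                irrigation=irrigation, rain=day.rain, drainage=drainage,
                water_stress=water_stress, n_factor=n_factor,
                mineral_n=soil_n.mineral_n, n_demand=demand,
                n_uptake=uptake, n_fertilized=fert,
            )
        )
        if gr.maturity_check(crop, g):
            crop.mature = True
            break

    tfy = gr.fresh_yield(
        crop.sdw, config.yields, g.density,
        crop.flowering_stress_days, config.flowering_stress_coeff,
    )
    daily = pd.DataFrame(rows)
    return SeasonResult(
        daily=daily,
        final_sdw=crop.sdw,
        tfy=tfy,
        n_uptake=soil_n.cum_uptake,
        n_input=soil_n.cum_fertilized,
        n_mineralized=soil_n.cum_mineralized,
        n_leached=soil_n.cum_leached,
        water_applied=soil_water.cum_irrigation,
        cycle_length=crop.dat,
        mature=crop.mature,
        plan=plan,
        crop=crop,
        soil_water=soil_water,
        soil_n=soil_n,
    )


def run_scenarios(
    config: SimulationConfig, weather: Sequence[wx.DailyWeather]
) -> tuple[dict[tuple[float, bool], SeasonResult], pd.DataFrame]:
    """Run the 2x2 soil-organic-matter x NVZ scenario grid on one weather
    series and tabulate the summary quintuple (Nupt, Ninp, Nsom, TDW, Yld)
    per cell."""
    results: dict[tuple[float, bool], SeasonResult] = {}
    rows = []
    for som in (1.4, 2.8):
        for nvz in (False, True):
            cell = dataclasses.replace(
                config,
                soil_n=dataclasses.replace(config.soil_n, som=som, nvz=nvz),
            )
            res = run_season(cell, weather)
            results[(som, nvz)] = res
            rows.append(
                dict(
                    som=som, nvz=nvz,
                    nupt=res.n_uptake, ninp=res.n_input,
                    nsom=res.n_mineralized, tdw=res.final_sdw, yld=res.tfy,
                    cycle_length=res.cycle_length,
                )
            )
    return results, pd.DataFrame(rows)


def scenario_weather(n_days: int = 160, seed: int = SCENARIO_WEATHER_SEED) -> list[wx.DailyWeather]:
    """The bundled synthetic Mediterranean season used by the scenario
    runner (fixed documented seed)."""
    site = wx.Site(latitude=41.53, altitude=75)
    return wx.generate_synthetic_weather(
        site, wx.mediterranean_profile(), n_days, seed
    )
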