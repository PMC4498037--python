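"""Configuration-file handling.

The crop parameter file is a YAML mapping whose ``crop`` section uses the
field-standard parameter names (case-insensitive): the logistic betas, the
cardinal temperatures, stage boundaries and coefficients, rooting geometry,
maturity thermal sums, flowering window, critical-N curve, minimum reserves,
yield conversion and the Hargreaves coefficient. Unknown keys are rejected
with a listing, so typos never pass silently. Site, soil and simulation
sections carry the remaining inputs.
"""

from __future__ import annotations

import dataclasses

import yaml

from . import growth as gr
from . import nitrogen as ni
from . import soilwater as sw
from . import weather as wx
from .errors import ConfigurationError
from .simulator import SimulationConfig

# crop-section key -> (target dataclass attribute path)
_CROP_KEYS = {
    "yldsdw": ("yields", "yld_sdw"),
    "hi": ("yields", "hi"),
    "exp_yld": ("yields", "exp_yld"),
    "raw": ("soil", "raw_frac_percent"),  # percent of TAW, converted below
    "root_h_max": ("roots", "root_h_max"),
    "root_d_max": ("roots", "root_d_max"),
    "root_r_max": ("roots", "root_r_max"),
    "tbase": ("thermal", "tbase"),
    "t_m1": ("thermal", "t_m1"),
    "t_m2": ("thermal", "t_m2"),
    "kts": ("growth", "kts"),
    "e_h": ("site", "e_h"),
    "a": ("ncurve", "a"),
    "b": ("ncurve", "b"),
    "kc_ini": ("stages", "kc_ini"),
    "kc_mid": ("stages", "kc_mid"),
    "kc_end": ("stages", "kc_end"),
    "kcb_ini": ("stages", "kcb_ini"),
    "kcb_mid": ("stages", "kcb_mid"),
    "kcb_end": ("stages", "kcb_end"),
    "sc_ini": ("stages", "sc_ini"),
    "sc_mid": ("stages", "sc_mid"),
    "sc_end": ("stages", "sc_end"),
    "hp_ini": ("stages", "hp_ini"),
    "hp_mid": ("stages", "hp_mid"),
    "hp_end": ("stages", "hp_end"),
    "t_1": ("stages", "t1"),
    "t_2": ("stages", "t2"),
    "t_3": ("stages", "t3"),
    "t_4": ("stages", "t4"),
    "d_sdwstop": ("growth", "d_sdwstop"),
    "tsmin": ("growth", "ts_min"),
    "tsmax": ("growth", "ts_max"),
    "plts_ref": ("seedling", "weight"),
    "plts_gr": ("growth", "plts_gr"),
    "beta1": ("growth", "beta1"),
    "beta2": ("growth", "beta2"),
    "beta3": ("growth", "beta3"),
    "flw_beg": ("growth", "flw_beg"),
    "flw_dur": ("growth", "flw_dur"),
    "flw_tmax": ("growth", "flw_tmax"),
    "k_t1": ("legacy", "k_t1"),
    "k_t2": ("legacy", "k_t2"),
    "k_t3": ("legacy", "k_t3"),
    "k_sdw1": ("legacy", "k_sdw1"),
    "k_sdw2": ("legacy", "k_sdw2"),
    "n_min_res_1": ("soil_n", "n_min_res_1"),
    "n_min_res_2": ("soil_n", "n_min_res_2"),
    "n_min_res_3": ("soil_n", "n_min_res_3"),
    "mulch_ke": ("simulation", "mulch_ke_reduction"),
    "mulch_kcb": ("simulation", "mulch_kcb_increase"),
    "albedo_pt": ("ignored", None),  # Priestley-Taylor: accepted, unused
    "alpha_pt": ("ignored", None),
    "density": ("growth", "density"),
}

_SITE_KEYS = {"latitude", "altitude", "et0_model", "e_h"}
_SOIL_KEYS = {"fc", "wp", "bulk_density", "swc_init", "raw_frac"}
_NITROGEN_KEYS = {"som", "nvz", "nvz_cap", "mineralization_rate", "n_frac_som",
                  "q10", "mineral_n_init"}
_SIM_KEYS = {"seedling_weight", "irrigation_enabled", "fertigation_enabled",
             "flowering_stress_coeff"}


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file; unknown keys in
    any section raise a :class:`ConfigurationError` listing them."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> SimulationConfig:
    unknown_sections = set(raw) - {"crop", "site", "soil", "nitrogen", "simulation"}
    if unknown_sections:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown_sections)}")

    buckets: dict[str, dict] = {
        "growth": {}, "thermal": {}, "yields": {}, "stages": {}, "roots": {},
        "ncurve": {}, "soil_n": {}, "site": {}, "soil": {}, "simulation": {},
        "seedling": {}, "legacy": {}, "ignored": {},
    }
    crop = {str(k).lower(): v for k, v in (raw.get("crop") or {}).items()}
    unknown = sorted(set(crop) - set(_CROP_KEYS))
    if unknown:
        raise ConfigurationError(
            f"unknown crop parameters: {unknown}; accepted names: "
            f"{sorted(_CROP_KEYS)}"
        )
    for key, value in crop.items():
        bucket, attr = _CROP_KEYS[key]
        if value is None or str(value).upper() == "NA":
            continue
        if bucket == "ignored":
            continue
        if bucket == "soil" and attr == "raw_frac_percent":
            buckets["soil"]["raw_frac"] = float(value) / 100.0
        else:
            buckets[bucket][attr] = value

    for section, keys, bucket in (
        ("site", _SITE_KEYS, "site"),
        ("soil", _SOIL_KEYS, "soil"),
        ("nitrogen", _NITROGEN_KEYS, "soil_n"),
        ("simulation", _SIM_KEYS, "simulation"),
    ):
        data = {str(k).lower(): v for k, v in (raw.get(section) or {}).items()}
        bad = sorted(set(data) - keys)
        if bad:
            raise ConfigurationError(f"unknown keys in [{section}]: {bad}")
        buckets[bucket].update(data)

    seedling = buckets["seedling"].pop("weight", None)
    sim_kwargs = buckets["simulation"]
    if seedling is not None:
        sim_kwargs.setdefault("seedling_weight", float(seedling))
    return SimulationConfig(
        site=wx.Site(**{"latitude": 41.53, "altitude": 75, **buckets["site"]}),
        thermal=wx.ThermalParams(**buckets["thermal"]),
        growth=gr.GrowthParams(**buckets["growth"]),
        yields=gr.YieldParams(**buckets["yields"]),
        stages=sw.StageTable(**buckets["stages"]),
        soil=sw.SoilProfile(**buckets["soil"]),
        roots=sw.RootParams(**buckets["roots"]),
        ncurve=ni.NCurveParams(**buckets["ncurve"]),
        soil_n=ni.SoilNParams(**buckets["soil_n"]),
        **sim_kwargs,
    )


def dump_config(config: SimulationConfig, path) -> None:
    """Write a round-trippable YAML view of a configuration."""
    doc = {
        "crop": {
            "beta1": config.growth.beta1,
            "beta2": config.growth.beta2,
            "beta3": config.growth.beta3,
            "tbase": config.thermal.tbase,
            "t_m1": config.thermal.t_m1,
            "t_m2": config.thermal.t_m2,
            "tsmin": config.growth.ts_min,
            "tsmax": config.growth.ts_max,
            "d_sdwstop": config.growth.d_sdwstop,
            "plts_ref": config.seedling_weight,
            "plts_gr": config.growth.plts_gr,
            "density": config.growth.density,
            "kts": config.growth.kts,
            "flw_beg": config.growth.flw_beg,
            "flw_dur": config.growth.flw_dur,
            "flw_tmax": config.growth.flw_tmax,
            "hi": config.yields.hi,
            "yldsdw": config.yields.yld_sdw,
            "exp_yld": config.yields.exp_yld,
            "a": config.ncurve.a,
            "b": config.ncurve.b,
            "raw": config.soil.raw_frac * 100.0,
            "root_h_max": config.roots.root_h_max,
            "root_d_max": config.roots.root_d_max,
            "root_r_max": config.roots.root_r_max,
            "n_min_res_1": config.soil_n.n_min_res_1,
            "n_min_res_2": config.soil_n.n_min_res_2,
            "n_min_res_3": config.soil_n.n_min_res_3,
            **{
                k: getattr(config.stages, k)
                for k in ("kc_ini", "kc_mid", "kc_end", "kcb_ini", "kcb_mid",
                          "kcb_end", "sc_ini", "sc_mid", "sc_end", "hp_ini",
                          "hp_mid", "hp_end")
            },
            "t_1": config.stages.t1,
            "t_2": config.stages.t2,
            "t_3": config.stages.t3,
            "t_4": config.stages.t4,
        },
        "site": dataclasses.asdict(config.site),
        "soil": dataclasses.asdict(config.soil),
        "nitrogen": {
            k: getattr(config.soil_n, k)
            for k in ("som", "nvz", "nvz_cap", "mineralization_rate",
                      "n_frac_som", "q10", "mineral_n_init")
        },
        "simulation": {
            "seedling_weight": config.seedling_weight,
            "irrigation_enabled": config.irrigation_enabled,
            "fertigation_enabled": config.fertigation_enabled,
            "flowering_stress_coeff": config.flowering_stress_coeff,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
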