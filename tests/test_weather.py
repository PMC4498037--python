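import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fertisim as fs
from fertisim.errors import ConfigurationError, DomainError


def ra_oracle(lat_deg, doy):
    """Independent step-by-step transcription of the FAO-56 extraterrestrial
    radiation procedure, kept deliberately separate from the implementation."""
    phi = lat_deg * math.pi / 180.0
    inverse_distance = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    declination = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    sunset_angle = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(declination))))
    term = (
        sunset_angle * math.sin(phi) * math.sin(declination)
        + math.cos(phi) * math.cos(declination) * math.sin(sunset_angle)
    )
    return 24 * 60 / math.pi * 0.0820 * inverse_distance * term


class TestExtraterrestrialRadiation:
    def test_matches_independent_transcription(self):
        site = fs.Site(latitude=41.53)
        for doy in (1, 80, 172, 180, 266, 355):
            assert fs.extraterrestrial_radiation(site, doy) == pytest.approx(
                ra_oracle(41.53, doy), rel=1e-12
            )

    def test_equator_equinox_near_annual_maximum(self):
        site = fs.Site(latitude=0.0)
        annual = [fs.extraterrestrial_radiation(site, d) for d in range(1, 366)]
        equinox = fs.extraterrestrial_radiation(site, 80)
        assert equinox >= 0.98 * max(annual)

    def test_northern_winter_below_summer(self):
        site = fs.Site(latitude=41.53)
        assert fs.extraterrestrial_radiation(site, 355) < fs.extraterrestrial_radiation(
            site, 172
        )

    def test_doy_bounds(self):
        with pytest.raises(DomainError):
            fs.extraterrestrial_radiation(fs.Site(latitude=0.0), 0)

    def test_latitude_bounds(self):
        with pytest.raises(DomainError):
            fs.Site(latitude=95.0)


class TestHargreaves:
    def test_zero_temperature_range_gives_zero(self):
        w = fs.DailyWeather(dt.date(2005, 6, 1), tmin=20, tmax=20, rain=0)
        assert fs.et0_hargreaves(w, ra=30.0, e_h=0.5) == 0.0

    def test_direct_arithmetic(self):
        # 0.408*ra = 15 mm/day equivalent; tmean 20, range 10
        w = fs.DailyWeather(dt.date(2005, 6, 1), tmin=15, tmax=25, rain=0)
        ra = 15.0 / 0.408
        expected = 0.0023 * 15.0 * (20 + 17.8) * math.sqrt(10)
        assert fs.et0_hargreaves(w, ra, e_h=0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.12, abs=0.01)

    def test_smaller_exponent_reduces_et0(self):
        w = fs.DailyWeather(dt.date(2005, 6, 1), tmin=15, tmax=25, rain=0)
        assert fs.et0_hargreaves(w, 36.0, e_h=0.372) < fs.et0_hargreaves(
            w, 36.0, e_h=0.5
        )


def pm_oracle(tmin, tmax, rn, u2, rhmin, rhmax, altitude):
    """Worked-procedure transcription of the daily FAO-56 reference ET
    computation (soil heat flux zero), independent of the implementation."""
    tmean = (tmin + tmax) / 2
    svp = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    delta = 4098 * svp(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293 - 0.0065 * altitude) / 293) ** 5.26
    gamma = 0.000665 * pressure
    es = (svp(tmax) + svp(tmin)) / 2
    ea = (svp(tmin) * rhmax / 100 + svp(tmax) * rhmin / 100) / 2
    radiation_term = 0.408 * delta * rn
    aero_term = gamma * (900 / (tmean + 273)) * u2 * (es - ea)
    return (radiation_term + aero_term) / (delta + gamma * (1 + 0.34 * u2))


class TestPenmanMonteith:
    SITE = fs.Site(latitude=41.53, altitude=75, et0_model="penman_monteith")

    def day(self, **kw):
        base = dict(tmin=14.0, tmax=28.0, rain=0.0, rad_net=14.5, wind2=2.1,
                    rhmin=38.0, rhmax=82.0)
        base.update(kw)
        return fs.DailyWeather(dt.date(2005, 7, 1), **base)

    def test_matches_worked_procedure(self):
        w = self.day()
        assert fs.et0_penman_monteith(w, self.SITE) == pytest.approx(
            pm_oracle(14.0, 28.0, 14.5, 2.1, 38.0, 82.0, 75), abs=0.01
        )

    def test_deterministic_on_identical_days(self):
        assert fs.et0_penman_monteith(self.day(), self.SITE) == fs.et0_penman_monteith(
            self.day(), self.SITE
        )

    def test_monotone_in_net_radiation(self):
        low = fs.et0_penman_monteith(self.day(rad_net=10.0), self.SITE)
        high = fs.et0_penman_monteith(self.day(rad_net=16.0), self.SITE)
        assert high > low

    def test_missing_fields_instruct_fallback(self):
        with pytest.raises(ConfigurationError, match="Hargreaves"):
            fs.et0_penman_monteith(self.day(wind2=None), self.SITE)


class TestThermalTime:
    P = fs.ThermalParams(tbase=10, t_m1=33, t_m2=38)

    @pytest.mark.parametrize(
        "tmin,tmax,expected",
        [
            (15, 25, 10.0),  # mean 20, no caps active
            (5, 9, 0.0),  # below base
            (30, 40, 23.0),  # mean 35 capped at t_m1 = 33
            (36, 42, 0.0),  # mean 39 at/above cut-off
        ],
    )
    def test_rule_arithmetic(self, tmin, tmax, expected):
        w = fs.DailyWeather(dt.date(2005, 6, 1), tmin=tmin, tmax=tmax, rain=0)
        assert fs.thermal_time(w, self.P) == expected

    @given(
        tmean=st.floats(-20, 60),
        half_range=st.floats(0, 15),
        t_m2_extra=st.floats(0.1, 20),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_cutoff_monotonicity(self, tmean, half_range, t_m2_extra):
        """0 <= gdd <= t_m1 - tbase, and raising the cut-off temperature never
        decreases accrual (required by the in-season check semantics)."""
        w = fs.DailyWeather(
            dt.date(2005, 6, 1), tmin=tmean - half_range, tmax=tmean + half_range,
            rain=0,
        )
        gdd = fs.thermal_time(w, self.P)
        assert 0.0 <= gdd <= self.P.t_m1 - self.P.tbase
        raised = fs.ThermalParams(tbase=10, t_m1=33, t_m2=38 + t_m2_extra)
        assert fs.thermal_time(w, raised) >= gdd


class TestSyntheticWeather:
    SITE = fs.Site(latitude=41.53)

    def test_seeded_determinism(self):
        profile = fs.mediterranean_profile()
        a = fs.generate_synthetic_weather(self.SITE, profile, 120, seed=7)
        b = fs.generate_synthetic_weather(self.SITE, profile, 120, seed=7)
        assert a == b

    def test_degenerate_profile_is_pure_sinusoid(self):
        profile = fs.SeasonProfile(
            start=dt.date(2005, 5, 10), mean_temp=16.5, amplitude=9.5,
            noise_sd=0.0, rain_freq=0.0,
        )
        days = fs.generate_synthetic_weather(self.SITE, profile, 365, seed=1)
        assert all(d.rain == 0.0 for d in days)
        for d in days:
            doy = d.date.timetuple().tm_yday
            expected = 16.5 + 9.5 * math.cos(2 * math.pi * (doy - 197) / 365.25)
            assert d.tmean == pytest.approx(expected, abs=1e-9)

    def test_long_run_statistics(self):
        profile = fs.mediterranean_profile()
        days = fs.generate_synthetic_weather(self.SITE, profile, 10_000, seed=11)
        assert all(d.tmax >= d.tmin and d.rain >= 0 for d in days)
        tmeans = np.array([d.tmean for d in days])
        assert abs(tmeans.mean() - profile.mean_temp) < 1.0
        wet_freq = np.mean([d.rain > 0 for d in days])
        assert abs(wet_freq - profile.rain_freq) < 0.02

    def test_invalid_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.SeasonProfile(start=dt.date(2005, 5, 10), mean_temp=16, amplitude=9,
                             noise_sd=-1)


class TestWeatherIO:
    def test_roundtrip(self, tmp_path, med_weather):
        path = tmp_path / "weather.csv"
        fs.write_weather(med_weather[:30], path)
        back = fs.read_weather(path)
        assert len(back) == 30
        assert back[0].date == med_weather[0].date
        assert back[5].tmax == pytest.approx(med_weather[5].tmax)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,tmin\n2005-05-10,3\n")
        with pytest.raises(ConfigurationError, match="missing"):
            fs.read_weather(path)
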