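"""Daily shoot dry-weight accumulation, phenology and fresh-yield computation.

Potential shoot biomass follows a logistic in cumulative thermal time,
SDW(tt) = beta1 / (1 + exp(beta2 + beta3*tt)) with beta3 < 0, so beta1 is the
potential final shoot dry weight (t/ha). Daily growth is the logistic
increment scaled multiplicatively by same-day water- and nitrogen-stress
factors. An in-season check against an observed biomass sampling
(the predicted/observed ratio ``CheckPO``) adjusts the thermal cut-off
temperature and the expected final biomass through calibrated ratio
polynomials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, StateError
from .weather import DailyWeather, ThermalParams


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth, lag-phase, maturity and stress parameters.

    ``beta1`` t/ha; ``beta3`` per degC d; ``plts_ref`` g/plant seedling
    reference weight; ``plts_gr`` g/plant/day lag-phase growth rate;
    ``density`` plants/m2; ``ts_min``/``ts_max`` degC d thermal-sum window
    for maturity; ``d_sdwstop`` consecutive low-increment days that, past
    ``ts_min``, declare maturity; flowering window in thermal time with a
    critical maximum temperature; ``kts`` the biomass response factor to
    water stress.
    """

    beta1: float = 12.2874
    beta2: float = 6.0894
    beta3: float = -0.0096
    plts_ref: float = 0.5
    plts_gr: float = 0.015
    density: float = 2.9
    ts_min: float = 1300.0
    ts_max: float = 1660.0
    d_sdwstop: int = 10
    flw_beg: float = 250.0
    flw_dur: float = 250.0
    flw_tmax: float = 40.0
    kts: float = 0.49
    low_increment_frac: float = 0.01  # of beta1, per day

    def __post_init__(self):
        if self.beta1 <= 0:
            raise DomainError("beta1 must be > 0")
        if self.beta3 >= 0:
            raise DomainError("beta3 must be < 0")
        if not 0 < self.ts_min <= self.ts_max:
            raise DomainError("require 0 < ts_min <= ts_max")
        if not 0.0 <= self.kts <= 1.0:
            raise DomainError("kts must be in [0, 1]")
        if self.density <= 0:
            raise DomainError("density must be > 0")

    @property
    def lag_increment(self) -> float:
        """Lag-phase biomass increment, t/ha/day (g/plant/day x plants/m2)."""
        return self.plts_gr * self.density * 0.01


@dataclass(frozen=True)
class YieldParams:
    """Fresh-yield conversion: harvest index (fruit DW / aboveground DW),
    percent dry mass of the fresh yield, and the expected fresh yield cap
    in g/plant."""

    hi: float = 0.66
    yld_sdw: float = 5.5
    exp_yld: float = 5300.0

    def __post_init__(self):
        if not 0.0 < self.hi <= 1.0:
            raise DomainError("hi must be in (0, 1]")
        if not 0.0 < self.yld_sdw < 100.0:
            raise DomainError("yld_sdw must be in (0, 100)")


@dataclass
class CropState:
    """Evolving crop status during a season simulation."""

    dat: int = 0
    tt_cum: float = 0.0
    sdw: float = 0.0
    in_lag: bool = True
    flowering_stress_days: int = 0
    low_increment_days: int = 0
    mature: bool = False
    expected_beta1: float = 12.2874


def logistic_fraction(tt_cum: float, g: GrowthParams) -> float:
    """The dimensionless logistic kernel 1/(1+exp(beta2 + beta3*tt))."""
    return 1.0 / (1.0 + math.exp(g.beta2 + g.beta3 * tt_cum))


def potential_sdw(tt_cum: float, g: GrowthParams, beta1: float | None = None) -> float:
    """Potential shoot dry weight (t/ha) at a cumulative thermal time.

    ``beta1`` overrides the asymptote (used once the expected final biomass
    has been adjusted in season); the shape parameters are unchanged.
    """
    if tt_cum < 0:
        raise DomainError("tt_cum must be >= 0")
    b1 = g.beta1 if beta1 is None else beta1
    return b1 * logistic_fraction(tt_cum, g)


def water_stress_multiplier(eta: float, etc: float, kts: float) -> float:
    """Daily biomass reduction factor for water deficit:
    1 - kts*(1 - ETa/ETc), equal to 1 when there is no deficit."""
    if etc == 0:
        return 1.0
    if eta > etc + 1e-9:
        raise DomainError(f"eta {eta} exceeds etc {etc}")
    return 1.0 - kts * (1.0 - min(eta, etc) / etc)


def daily_growth(
    state: CropState,
    gdd: float,
    water_stress: float,
    n_factor: float,
    g: GrowthParams,
) -> CropState:
    """Advance the crop by one day (mutates and returns ``state``).

    During the lag phase the increment is the constant seedling growth rate
    per unit area; the crop leaves the lag on the first day the logistic
    increment exceeds it. Afterwards the increment is the logistic difference
    at the current expected asymptote, scaled by the water- and N-stress
    factors and capped so biomass never exceeds the expected final value.
    """
    if state.mature:
        raise StateError("daily_growth called on a mature crop")
    b1 = state.expected_beta1
    pot_now = potential_sdw(state.tt_cum, g, b1)
    pot_next = potential_sdw(state.tt_cum + gdd, g, b1)
    logistic_inc = pot_next - pot_now
    if state.in_lag and logistic_inc > g.lag_increment:
        state.in_lag = False
    base_inc = g.lag_increment if state.in_lag else logistic_inc
    inc = base_inc * water_stress * n_factor
    inc = max(0.0, min(inc, b1 - state.sdw))
    state.sdw += inc
    state.tt_cum += gdd
    state.dat += 1
    if inc < g.low_increment_frac * g.beta1:
        state.low_increment_days += 1
    else:
        state.low_increment_days = 0
    return state


def flowering_stress_update(
    state: CropState, w: DailyWeather, g: GrowthParams
) -> CropState:
    """Count heat-stress days during flowering: one day is counted when the
    thermal sum lies in [flw_beg, flw_beg + flw_dur) and tmax strictly
    exceeds the flowering maximum temperature."""
    if g.flw_beg <= state.tt_cum < g.flw_beg + g.flw_dur and w.tmax > g.flw_tmax:
        state.flowering_stress_days += 1
    return state


def maturity_check(
    state: CropState, g: GrowthParams, increment_threshold: float | None = None
) -> bool:
    """Maturity is reached at the maximum thermal sum, or past the minimum
    thermal sum after ``d_sdwstop`` consecutive days of low biomass
    increment."""
    if state.tt_cum >= g.ts_max:
        return True
    return state.tt_cum >= g.ts_min and state.low_increment_days >= g.d_sdwstop


def fresh_yield(
    sdw_final: float,
    y: YieldParams,
    density: float,
    flowering_stress_days: int = 0,
    stress_coeff: float = 0.01,
) -> float:
    """Total fresh fruit yield (t/ha) from final shoot dry weight.

    TFY = SDW * HI / (YldSDW/100), reduced by ``stress_coeff`` per
    flowering heat-stress day and capped at the expected per-plant yield
    times density.
    """
    if sdw_final <= 0:
        raise DomainError("sdw_final must be > 0")
    tfy = sdw_final * y.hi / (y.yld_sdw / 100.0)
    tfy *= max(0.0, 1.0 - stress_coeff * flowering_stress_days)
    cap = y.exp_yld * density * 1e-2  # g/plant * plants/m2 -> t/ha
    return min(tfy, cap)


# ---------------------------------------------------------------------------
# In-season growth check

#: Shape coefficients printed for a legacy implementation of the in-season
#: adjustment (K_T1, K_T2, K_T3 for the cut-off temperature; K_SDW1, K_SDW2
#: for the expected final biomass). Their parameterization (orientation,
#: normalization, intercepts) is not documented and cannot be reconstructed;
#: they are kept for reference only and never used in default runs.
LEGACY_SHAPE_COEFFICIENTS = {
    "k_t1": 3.8112,
    "k_t2": 3.4909,
    "k_t3": 1.7976,
    "k_sdw1": 0.9253,
    "k_sdw2": 0.3733,
}


@dataclass(frozen=True)
class SdwCheckParams:
    """Ratio polynomials of the in-season growth check.

    ``t_m2_coeffs``: 3rd-order polynomial (highest power first) giving
    newT_M2/T_M2 as a function of CheckPO; ``beta1_coeffs``: 2nd-order
    polynomial giving newBeta1/beta1 vs CheckPO. Both anchor at ratio 1 for
    CheckPO = 1 when produced by this package's calibrator.

    The defaults are mild first-principles corrections (beta1 scaled by
    ~1/CheckPO, cut-off temperature nudged by 15% of the miss): they anchor
    exactly at CheckPO = 1 and are replaced by calibrated polynomials when a
    trial collection is available.
    """

    t_m2_coeffs: tuple[float, ...] = (0.0, 0.0, -0.15, 1.15)
    beta1_coeffs: tuple[float, ...] = (1.0, -3.0, 3.0)  # quadratic ~ 1/CheckPO

    def t_m2_ratio(self, check_po: float) -> float:
        return float(np.polyval(self.t_m2_coeffs, check_po))

    def beta1_ratio(self, check_po: float) -> float:
        return float(np.polyval(self.beta1_coeffs, check_po))


def sdw_check(
    predicted_sdw: float,
    observed_sdw: float,
    thermal: ThermalParams,
    g: GrowthParams,
    k: SdwCheckParams,
) -> tuple[float, float]:
    """In-season adjustment from one observed biomass sampling.

    CheckPO = predicted/observed; returns ``(new_t_m2, new_beta1)`` obtained
    by scaling the cut-off temperature and the expected final biomass with
    the calibrated ratio polynomials. When the model under-predicts
    (CheckPO < 1) the expected final biomass never decreases, and vice versa;
    the adjusted cut-off stays above the maximum temperature.
    """
    if observed_sdw <= 0 or predicted_sdw <= 0:
        raise DomainError("predicted and observed SDW must both be > 0")
    check_po = predicted_sdw / observed_sdw
    new_t_m2 = thermal.t_m2 * max(0.1, k.t_m2_ratio(check_po))
    new_t_m2 = max(new_t_m2, thermal.t_m1 + 0.5)
    new_beta1 = g.beta1 * max(1e-6, k.beta1_ratio(check_po))
    if check_po < 1.0:
        new_beta1 = max(new_beta1, g.beta1)
    elif check_po > 1.0:
        new_beta1 = min(new_beta1, g.beta1)
    return new_t_m2, new_beta1
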