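"""Crop nitrogen demand from a critical-N dilution curve, soil mineral-N
bookkeeping, fertigation scheduling under a nitrate-vulnerable-zone (NVZ)
cap, and adaptive reduction of the potential growth asymptote under limited
N availability.

The critical N concentration (% of dry weight) declines with shoot biomass W
as Nc = a * W**b (b < 0), held constant at ``a`` below 1 t/ha to avoid the
power-law singularity. Cumulative crop N demand is W * 10 * Nc (kg/ha).
Soil mineral N is a single root-zone pool fed by fertigation and first-order
mineralization of soil organic matter (SOM) and depleted by leaching
(complete mixing with drainage) and crop uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import DomainError
from .growth import GrowthParams
from .soilwater import SoilProfile


@dataclass(frozen=True)
class NCurveParams:
    """Critical N dilution curve Nc = a * W**b; ``a`` is the percent N at
    1 t/ha of shoot biomass, ``b`` the (negative) dilution exponent."""

    a: float = 4.53
    b: float = -0.327

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError("critical-N parameter a must be > 0")
        if self.b >= 0:
            raise DomainError("critical-N parameter b must be < 0")


@dataclass(frozen=True)
class SoilNParams:
    """Soil nitrogen setting.

    ``som`` soil organic matter, g/100 g; ``n_min_res_1/2/3`` kg/ha minimum
    mineral-N reserves for the initial, middle and final phases (both an
    uptake floor and a scheduling target); ``nvz`` flags a nitrate vulnerable
    zone where cumulative fertilizer N is capped at ``nvz_cap`` kg/ha;
    mineralization releases ``mineralization_rate`` of SOM-N per year at the
    20 degC reference, with a Q10 temperature response, assuming SOM is
    ``n_frac_som`` nitrogen by mass.
    """

    som: float = 1.4
    n_min_res_1: float = 3.0
    n_min_res_2: float = 20.0
    n_min_res_3: float = 10.0
    nvz: bool = False
    nvz_cap: float = 170.0
    mineralization_rate: float = 0.02
    n_frac_som: float = 0.058
    q10: float = 2.0
    mineral_n_init: float = 30.0

    def __post_init__(self):
        if self.som < 0:
            raise DomainError("som must be >= 0")
        if min(self.n_min_res_1, self.n_min_res_2, self.n_min_res_3) < 0:
            raise DomainError("minimum reserves must be >= 0")
        if self.nvz_cap <= 0:
            raise DomainError("nvz_cap must be > 0")

    def reserve(self, phase: str) -> float:
        try:
            return {
                "initial": self.n_min_res_1,
                "mid": self.n_min_res_2,
                "final": self.n_min_res_3,
            }[phase]
        except KeyError:
            raise DomainError(f"unknown phase {phase!r}") from None


@dataclass
class SoilNState:
    """Root-zone mineral N pool with season ledgers (all kg/ha)."""

    mineral_n: float = 30.0
    initial_mineral_n: float = 30.0
    cum_fertilized: float = 0.0
    cum_mineralized: float = 0.0
    cum_leached: float = 0.0
    cum_uptake: float = 0.0

    def ledger_residual(self) -> float:
        """Deviation of the N mass balance from closure (should be ~0)."""
        return (
            self.initial_mineral_n
            + self.cum_mineralized
            + self.cum_fertilized
            - self.cum_uptake
            - self.cum_leached
            - self.mineral_n
        )


@dataclass
class FertigationPlan:
    """Ordered list of fertigation events ``(dat, n_kg_ha, water_mm)``."""

    events: list[tuple[int, float, float]] = field(default_factory=list)

    def add(self, dat: int, n_amount: float, water: float) -> None:
        if n_amount <= 0:
            raise DomainError("fertigation N amount must be > 0")
        if self.events and dat <= self.events[-1][0]:
            raise DomainError("fertigation event days must be strictly increasing")
        self.events.append((dat, n_amount, water))

    @property
    def total_n(self) -> float:
        return sum(e[1] for e in self.events)

    @property
    def total_water(self) -> float:
        return sum(e[2] for e in self.events)


def critical_n(sdw: float, p: NCurveParams) -> float:
    """Critical N concentration (% of DW) at a given shoot biomass (t/ha);
    constant at ``a`` below 1 t/ha, declining as a power law above."""
    if sdw <= 0:
        raise DomainError("sdw must be > 0")
    return p.a * max(sdw, 1.0) ** p.b


def cumulative_n_demand(sdw: float, p: NCurveParams) -> float:
    """Cumulative crop N demand (kg/ha) to have grown ``sdw`` t/ha of shoot
    biomass at the critical concentration."""
    if sdw < 0:
        raise DomainError("sdw must be >= 0")
    if sdw == 0:
        return 0.0
    return sdw * 10.0 * critical_n(sdw, p)


def mineralization_step(
    p: SoilNParams, soil: SoilProfile, layer_depth: float, tmean: float
) -> float:
    """Daily mineral N released from SOM (kg/ha/day).

    First-order release from the SOM-N stock of the layer at the annual base
    rate, modulated by a Q10 temperature factor (reference 20 degC) and zero
    at or below 0 degC.
    """
    if layer_depth <= 0:
        raise DomainError("layer_depth must be > 0")
    if tmean <= 0.0:
        return 0.0
    soil_mass = layer_depth * 100.0 * soil.bulk_density * 1000.0  # kg/ha
    som_n = soil_mass * (p.som / 100.0) * p.n_frac_som  # kg N /ha in SOM
    temp_factor = p.q10 ** ((tmean - 20.0) / 10.0)
    return som_n * p.mineralization_rate / 365.0 * temp_factor


def soil_n_step(
    state: SoilNState,
    mineralized: float,
    fertilized: float,
    demand: float,
    drainage: float,
    root_zone_water: float,
    min_reserve: float,
) -> tuple[SoilNState, float, float]:
    """Advance the mineral-N pool by one day.

    Inputs are added, a complete-mixing leaching loss proportional to
    drainage/root-zone water is removed, then the crop takes up the lesser
    of its demand and the pool above the phase reserve. Returns
    ``(state, actual_uptake, n_factor)`` with n_factor = uptake/demand
    (1 when demand is zero).
    """
    if min(mineralized, fertilized, demand, drainage) < 0 or root_zone_water < 0:
        raise DomainError("all nitrogen-step inputs must be >= 0")
    if drainage > 0 and root_zone_water == 0:
        raise DomainError("drainage without root-zone water")
    state.mineral_n += mineralized + fertilized
    state.cum_mineralized += mineralized
    state.cum_fertilized += fertilized
    leached = (
        state.mineral_n * min(1.0, drainage / root_zone_water) if drainage > 0 else 0.0
    )
    state.mineral_n -= leached
    state.cum_leached += leached
    uptake = min(demand, max(0.0, state.mineral_n - min_reserve))
    state.mineral_n -= uptake
    state.cum_uptake += uptake
    n_factor = 1.0 if demand == 0 else uptake / demand
    return state, uptake, n_factor


def plan_fertigation(
    state: SoilNState,
    forecast_demand: float,
    phase: str,
    p: SoilNParams,
) -> float | None:
    """Size today's fertigation N event (kg/ha) or return ``None``.

    The event covers the forecast demand over the planning horizon plus the
    phase reserve, net of the mineral N already in the pool; under NVZ rules
    it is truncated so cumulative fertilizer never exceeds the cap.
    """
    if forecast_demand < 0:
        raise DomainError("forecast_demand must be >= 0")
    need = forecast_demand + p.reserve(phase) - state.mineral_n
    if need <= 0:
        return None
    if p.nvz:
        need = min(need, p.nvz_cap - state.cum_fertilized)
        if need <= 1e-9:
            return None
    return need


def adjust_potential_under_n_limit(
    remaining_budget: float,
    current_sdw: float,
    g: GrowthParams,
    p: NCurveParams,
) -> float:
    """Largest final shoot biomass (t/ha) whose remaining N demand fits the
    remaining budget; capped at the unconstrained asymptote and never below
    the current biomass. Solved by monotone root finding on the cumulative
    demand curve."""
    if remaining_budget < 0:
        raise DomainError("remaining_budget must be >= 0")
    current = max(current_sdw, 0.0)
    target = cumulative_n_demand(current, p) + remaining_budget
    if cumulative_n_demand(g.beta1, p) <= target:
        return g.beta1
    if remaining_budget == 0:
        return current
    w_star = brentq(
        lambda w: cumulative_n_demand(w, p) - target,
        current,
        g.beta1,
        xtol=1e-9,
    )
    return min(g.beta1, max(current, float(w_star)))
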