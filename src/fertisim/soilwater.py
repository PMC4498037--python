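"""FAO-56-style dual-coefficient daily soil water balance over the effective
root zone, irrigation requirement, drainage and 10–30 cm soil-water-content
reporting.

The root zone is a single bucket whose capacity (TAW) grows with root depth.
Transpiration uses the basal coefficient Kcb reduced by a linear stress
factor Ks once depletion exceeds the readily available water (RAW); soil
evaporation uses a single-stage coefficient Ke = Kc − Kcb damped linearly by
bucket dryness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError


@dataclass(frozen=True)
class SoilProfile:
    """Root-zone soil hydraulic summary.

    ``fc``/``wp`` are volumetric water contents (m3/m3) at field capacity and
    wilting point; ``raw_frac`` the fraction of TAW that is readily available
    (depletion beyond it induces transpiration stress); ``swc_init`` the
    volumetric water content at transplanting.
    """

    fc: float = 0.32
    wp: float = 0.16
    bulk_density: float = 1.3
    raw_frac: float = 0.40
    swc_init: float = 0.32

    def __post_init__(self):
        if not 0.0 < self.wp < self.fc < 1.0:
            raise DomainError(f"require 0 < wp < fc < 1, got wp={self.wp}, fc={self.fc}")
        if not 0.0 < self.raw_frac <= 1.0:
            raise DomainError("raw_frac must be in (0, 1]")
        if self.bulk_density <= 0:
            raise DomainError("bulk_density must be > 0")


@dataclass(frozen=True)
class RootParams:
    """Effective rooting geometry: depth ramps linearly from ``initial_depth``
    at transplanting to ``root_h_max`` (cm) over ``root_d_max`` days;
    ``root_r_max`` (cm) is the radius of the most efficient wetted volume and
    scales the drip-refill fraction."""

    root_h_max: float = 40.0
    root_d_max: float = 45.0
    root_r_max: float = 30.0
    initial_depth: float = 5.0

    def __post_init__(self):
        if min(self.root_h_max, self.root_d_max, self.root_r_max) <= 0:
            raise DomainError("root parameters must be > 0")
        if not 0 < self.initial_depth <= self.root_h_max:
            raise DomainError("initial_depth must be in (0, root_h_max]")

    def wetted_fraction(self, density: float) -> float:
        """Fraction of the field surface wetted by drip emitters, from the
        wetted radius and planting density (plants/m2), capped at 1."""
        import math

        return min(1.0, density * math.pi * (self.root_r_max / 100.0) ** 2)


@dataclass(frozen=True)
class StageTable:
    """Piecewise crop-stage table (FAO-56 four-stage logic).

    Stage boundaries in days after transplanting: initial up to ``t1``,
    development ramp on [t1, t2], middle on [t2, t3], late-season ramp on
    [t3, t4], end value beyond ``t4``. Degenerate ramps (t1 == t2) step
    directly between values.
    """

    t1: float = 20.0
    t2: float = 20.0
    t3: float = 90.0
    t4: float = 115.0
    kc_ini: float = 0.6
    kc_mid: float = 1.15
    kc_end: float = 0.9
    kcb_ini: float = 0.15
    kcb_mid: float = 1.1
    kcb_end: float = 0.7
    sc_ini: float = 10.0
    sc_mid: float = 100.0
    sc_end: float = 80.0
    hp_ini: float = 20.0
    hp_mid: float = 60.0
    hp_end: float = 40.0

    def __post_init__(self):
        if not self.t1 <= self.t2 <= self.t3 <= self.t4:
            raise DomainError("stage boundaries must satisfy t1 <= t2 <= t3 <= t4")


@dataclass
class SoilWaterState:
    """Evolving root-zone water status.

    ``depletion`` is mm below field capacity of the current root zone;
    ``swc_10_30`` the reported volumetric water content of the 10–30 cm
    layer; cumulative fluxes are season ledgers (mm).
    """

    depletion: float = 0.0
    root_depth: float = 5.0
    swc_10_30: float = 0.32
    cum_drainage: float = 0.0
    cum_irrigation: float = 0.0
    cum_eta: float = 0.0
    cum_rain: float = 0.0
    cum_new_soil_deficit: float = field(default=0.0, repr=False)


def root_depth(dat: float, r: RootParams) -> float:
    """Effective root depth (cm) at a given day after transplanting:
    linear from the initial depth to the maximum, constant thereafter."""
    if dat < 0:
        raise DomainError("dat must be >= 0")
    if dat >= r.root_d_max:
        return r.root_h_max
    return r.initial_depth + (r.root_h_max - r.initial_depth) * dat / r.root_d_max


def stage_coefficient(dat: float, s: StageTable, which: str) -> float:
    """Stage-dependent coefficient (kcb, kc, sc or hp) at a given DAT."""
    try:
        ini, mid, end = {
            "kcb": (s.kcb_ini, s.kcb_mid, s.kcb_end),
            "kc": (s.kc_ini, s.kc_mid, s.kc_end),
            "sc": (s.sc_ini, s.sc_mid, s.sc_end),
            "hp": (s.hp_ini, s.hp_mid, s.hp_end),
        }[which]
    except KeyError:
        raise DomainError(f"unknown stage coefficient {which!r}") from None
    if dat < 0:
        raise DomainError("dat must be >= 0")
    if dat <= s.t1:
        return ini
    if dat < s.t2:
        return ini + (mid - ini) * (dat - s.t1) / (s.t2 - s.t1)
    if dat <= s.t3:
        return mid
    if dat < s.t4:
        return mid + (end - mid) * (dat - s.t3) / (s.t4 - s.t3)
    return end


def taw(profile: SoilProfile, depth_cm: float) -> tuple[float, float]:
    """Total and readily available water (mm) of a root zone of given depth."""
    if depth_cm <= 0:
        raise DomainError("root depth must be > 0")
    total = (profile.fc - profile.wp) * depth_cm * 10.0
    return total, profile.raw_frac * total


def water_balance_step(
    state: SoilWaterState,
    rain: float,
    irrigation: float,
    et0: float,
    kcb: float,
    ke_base: float,
    profile: SoilProfile,
    roots: RootParams,
    dat: float,
) -> tuple[SoilWaterState, float, float, float, float]:
    """Advance the root-zone bucket by one day.

    Returns ``(state, eta, etc, drainage, ks)`` where ``etc`` is the
    unstressed (Ks = 1) crop evapotranspiration against which the realized
    ``eta`` can be compared. Transpiration stress Ks is 1
    while depletion <= RAW, then declines linearly to 0 at TAW. Soil
    evaporation Ke is the base value damped by bucket dryness. Actual ET
    cannot overdraw the bucket; water pushed below zero depletion drains.
    Soil newly explored by root growth enters at the initial water content.
    """
    if min(rain, irrigation, et0) < 0:
        raise DomainError("rain, irrigation and et0 must all be >= 0")
    depth = root_depth(dat, roots)
    dep = state.depletion
    if depth > state.root_depth:
        added = (profile.fc - profile.swc_init) * 10.0 * (depth - state.root_depth)
        dep += added
        state.cum_new_soil_deficit += added
    total, raw = taw(profile, depth)
    dep = min(dep, total)

    # today's supply relieves stress the same day (daily-step convention)
    supplied = dep - rain - irrigation
    eff = max(supplied, 0.0)
    if eff <= raw or total == raw:
        ks = 1.0
    else:
        ks = min(1.0, max(0.0, (total - eff) / (total - raw)))
    dryness = max(0.0, 1.0 - eff / total) if total > 0 else 0.0
    ke = max(0.0, ke_base) * dryness
    etc = (kcb + ke) * et0
    eta_pot = (ks * kcb + ke) * et0
    # cap ET at what the bucket plus today's supply can deliver
    eta = max(0.0, min(eta_pot, total - supplied))
    dep_new = supplied + eta
    drainage = max(0.0, -dep_new)
    dep_new += drainage

    state.depletion = dep_new
    state.root_depth = depth
    state.swc_10_30 = min(
        profile.fc, max(profile.wp, profile.fc - dep_new / (10.0 * depth))
    )
    state.cum_drainage += drainage
    state.cum_irrigation += irrigation
    state.cum_eta += eta
    state.cum_rain += rain
    return state, eta, etc, drainage, ks


def irrigation_requirement(
    state: SoilWaterState, profile: SoilProfile, roots: RootParams
) -> float:
    """Refill-to-field-capacity requirement (mm): the current depletion when
    it has reached the readily-available-water trigger, else zero."""
    _, raw = taw(profile, max(state.root_depth, roots.initial_depth))
    return state.depletion if state.depletion >= raw else 0.0
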