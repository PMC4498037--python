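"""Calibration: nonlinear least-squares fit of the logistic growth curve to
observed shoot-dry-weight samplings, and calibration of the in-season
growth-check ratio polynomials from a collection of trials.

The growth-check calibration proceeds in two steps per trial: the
predicted/observed biomass ratio (CheckPO) is evaluated at the sampling
nearest one third of the cycle length (within the 30–50 days-after-
transplanting window); then trial-specific best-fit values of the thermal
cut-off temperature and of the expected final biomass are found against the
post-check samplings. Ratio polynomials (adjusted/original parameter vs
CheckPO) are finally fitted across trials, with the identity point
(CheckPO = 1, ratio = 1) included as a strongly weighted anchor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import ConfigurationError, DomainError, FitError
from .growth import GrowthParams, SdwCheckParams, potential_sdw
from .weather import DailyWeather, ThermalParams, thermal_time

logger = logging.getLogger(__name__)

CHECK_WINDOW = (30, 50)  # DAT window admissible for the in-season check


@dataclass(frozen=True)
class Sampling:
    """One destructive biomass sampling: day after transplanting, cumulative
    thermal time, observed shoot dry weight (t/ha), optional standard error."""

    dat: int
    tt_cum: float
    sdw_obs: float
    se: float | None = None


@dataclass
class TrialObservations:
    """Observed samplings of one field trial.

    ``weather`` (optional) is the trial's daily series from transplanting;
    when present the calibrator can re-accrue thermal time under candidate
    cut-off temperatures. ``n_uptake`` optionally holds (dat, kg/ha) N
    uptake samplings.
    """

    trial_id: str
    samplings: list[Sampling]
    weather: list[DailyWeather] | None = None
    n_uptake: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        dats = [s.dat for s in self.samplings]
        if any(b <= a for a, b in zip(dats, dats[1:])):
            raise DomainError(f"{self.trial_id}: sampling days must be strictly increasing")

    @property
    def cycle_length(self) -> int:
        return self.samplings[-1].dat


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters with diagnostics."""

    beta1: float
    beta2: float
    beta3: float
    converged: bool
    rss: float
    n_iter: int

    def as_growth_params(self, template: GrowthParams | None = None) -> GrowthParams:
        import dataclasses

        base = template or GrowthParams()
        return dataclasses.replace(
            base, beta1=self.beta1, beta2=self.beta2, beta3=self.beta3
        )


def _start_values(tt: np.ndarray, sdw: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starting values: beta1 just above the largest observation,
    beta2/beta3 from the log-linearized logistic."""
    b1 = 1.05 * float(sdw.max())
    frac = np.clip(sdw / b1, 1e-6, 1 - 1e-6)
    y = np.log(1.0 / frac - 1.0)
    slope, intercept = np.polyfit(tt, y, 1)
    return b1, float(intercept), min(float(slope), -1e-6)


def fit_logistic(obs: TrialObservations | Sequence, tol: float = 1e-8, max_iter: int = 200) -> LogisticFit:
    """Fit SDW(tt) = beta1/(1 + exp(beta2 + beta3*tt)) by iterative
    (Levenberg–Marquardt damped Gauss–Newton) nonlinear least squares.

    ``obs`` is a :class:`TrialObservations` or a sequence of
    ``(tt_cum, sdw_obs)`` pairs; at least 4 samplings with positive biomass
    are required. Deterministic given the data (starting values are
    data-driven heuristics).
    """
    if isinstance(obs, TrialObservations):
        pairs = [(s.tt_cum, s.sdw_obs) for s in obs.samplings]
    else:
        pairs = list(obs)
    if len(pairs) < 4:
        raise DomainError("logistic fit needs at least 4 samplings")
    tt = np.array([p[0] for p in pairs], dtype=float)
    sdw = np.array([p[1] for p in pairs], dtype=float)
    if np.any(sdw <= 0):
        raise DomainError("observed SDW values must be > 0")

    def resid(theta):
        b1, b2, b3 = theta
        return b1 / (1.0 + np.exp(np.clip(b2 + b3 * tt, -500, 500))) - sdw

    x0 = _start_values(tt, sdw)
    sol = least_squares(resid, x0, method="lm", xtol=tol, ftol=tol, gtol=tol,
                        max_nfev=max_iter * 4)
    rss = float(np.sum(sol.fun**2))
    if not sol.success:
        raise FitError(
            f"logistic fit did not converge: {sol.message}", last_iterate=sol.x
        )
    b1, b2, b3 = (float(v) for v in sol.x)
    return LogisticFit(beta1=b1, beta2=b2, beta3=b3, converged=True, rss=rss,
                       n_iter=int(sol.nfev))


# ---------------------------------------------------------------------------
# Growth-check (CheckPO) polynomial calibration


def _tt_at_dats(weather: Sequence[DailyWeather], thermal: ThermalParams,
                dats: Sequence[int]) -> np.ndarray:
    """Cumulative thermal time at the end of each requested DAT, re-accrued
    from daily weather under the given cardinal temperatures."""
    gdd = np.array([thermal_time(w, thermal) for w in weather])
    cum = np.concatenate([[0.0], np.cumsum(gdd)])
    return np.array([cum[min(d, len(weather))] for d in dats])


def _select_check(trial: TrialObservations) -> Sampling | None:
    """The sampling closest to one third of the cycle length, clamped to the
    admissible window; None when that sampling falls outside the window."""
    target = min(max(round(trial.cycle_length / 3), CHECK_WINDOW[0]), CHECK_WINDOW[1])
    best = min(trial.samplings, key=lambda s: abs(s.dat - target))
    if not CHECK_WINDOW[0] <= best.dat <= CHECK_WINDOW[1]:
        return None
    return best


def _best_beta1(kernel: np.ndarray, obs: np.ndarray) -> float:
    """Closed-form least-squares asymptote for fixed logistic kernel values."""
    return float(np.dot(kernel, obs) / np.dot(kernel, kernel))


def calibrate_sdwcheck(
    trials: Sequence[TrialObservations],
    growth: GrowthParams,
    thermal: ThermalParams,
) -> SdwCheckParams:
    """Calibrate the growth-check ratio polynomials from a trial collection.

    Per trial: CheckPO at the check sampling; then a 1-D search for the
    cut-off temperature (when the trial carries weather) nested over the
    closed-form best-fit asymptote against the post-check samplings. A
    3rd-order polynomial is fitted to the cut-off ratio vs CheckPO and a
    2nd-order polynomial to the asymptote ratio vs CheckPO, both anchored at
    (1, 1) with ten-fold weight. Trials without a sampling in the admissible
    window, or with fewer than two post-check samplings, are excluded with a
    warning; at least three usable trials are required.
    """
    check_pos: list[float] = []
    t_ratios: list[float] = []
    b_ratios: list[float] = []
    for trial in trials:
        check = _select_check(trial)
        if check is None:
            warnings.warn(
                f"{trial.trial_id}: no sampling in the {CHECK_WINDOW} DAT check "
                "window; trial excluded", stacklevel=2)
            continue
        post = [s for s in trial.samplings if s.dat > check.dat]
        if len(post) < 2:
            warnings.warn(
                f"{trial.trial_id}: fewer than 2 post-check samplings; trial "
                "excluded", stacklevel=2)
            continue
        predicted = potential_sdw(check.tt_cum, growth)
        check_po = predicted / check.sdw_obs
        obs = np.array([s.sdw_obs for s in post])
        dats = [s.dat for s in post]

        def sse_for(t_m2: float) -> tuple[float, float]:
            th = ThermalParams(tbase=thermal.tbase, t_m1=thermal.t_m1, t_m2=t_m2)
            if trial.weather is not None:
                tts = _tt_at_dats(trial.weather, th, dats)
            else:
                tts = np.array([s.tt_cum for s in post])
            kernel = 1.0 / (1.0 + np.exp(growth.beta2 + growth.beta3 * tts))
            b1 = _best_beta1(kernel, obs)
            return float(np.sum((b1 * kernel - obs) ** 2)), b1

        new_t_m2 = thermal.t_m2
        if trial.weather is not None:
            sse_base = sse_for(thermal.t_m2)[0]
            lo, hi = thermal.t_m1 + 0.5, thermal.t_m2 + 12.0
            res = minimize_scalar(lambda t: sse_for(t)[0], bounds=(lo, hi),
                                  method="bounded", options={"xatol": 1e-3})
            # keep the baseline cut-off when the search cannot genuinely
            # improve the fit (weather never reaching the cut-off leaves the
            # objective flat in t_m2)
            if res.fun < sse_base * (1.0 - 1e-9):
                new_t_m2 = float(res.x)
        _, new_beta1 = sse_for(new_t_m2)
        check_pos.append(check_po)
        t_ratios.append(new_t_m2 / thermal.t_m2)
        b_ratios.append(new_beta1 / growth.beta1)
        logger.info(
            "%s: CheckPO=%.3f newT_M2=%.2f newBeta1=%.3f",
            trial.trial_id, check_po, new_t_m2, new_beta1,
        )
    if len(check_pos) < 3:
        raise ConfigurationError(
            f"need >= 3 usable trials for growth-check calibration, got {len(check_pos)}"
        )
    # anchored weighted polynomial fits (identity point at 10x mean weight)
    x = np.array(check_pos + [1.0])
    w = np.array([1.0] * len(check_pos) + [10.0])
    if np.ptp(x) < 1e-3:
        # all trials already consistent with the baseline: constant ratios
        return SdwCheckParams(
            t_m2_coeffs=(float(np.mean(t_ratios + [1.0])),),
            beta1_coeffs=(float(np.mean(b_ratios + [1.0])),),
        )
    n_distinct = len(np.unique(np.round(x, 6)))
    deg_t = min(3, n_distinct - 1)
    deg_b = min(2, n_distinct - 1)
    t_coeffs = np.polyfit(x, np.array(t_ratios + [1.0]), deg_t, w=w)
    b_coeffs = np.polyfit(x, np.array(b_ratios + [1.0]), deg_b, w=w)
    return SdwCheckParams(
        t_m2_coeffs=tuple(float(c) for c in t_coeffs),
        beta1_coeffs=tuple(float(c) for c in b_coeffs),
    )


def read_observations(path) -> list[TrialObservations]:
    """Read a delimited observations file with header
    ``trial,dat,sdw_obs[,tt_cum][,se][,n_uptake]`` into per-trial objects.
    When ``tt_cum`` is absent it must be supplied later from weather."""
    frame = pd.read_csv(path)
    required = {"trial", "dat", "sdw_obs"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(f"observations file needs columns {sorted(required)}")
    trials = []
    for trial_id, grp in frame.groupby("trial", sort=False):
        grp = grp.sort_values("dat")
        samplings = [
            Sampling(
                dat=int(r.dat),
                tt_cum=float(getattr(r, "tt_cum", float("nan"))) if "tt_cum" in frame.columns else float("nan"),
                sdw_obs=float(r.sdw_obs),
                se=float(r.se) if "se" in frame.columns and pd.notna(r.se) else None,
            )
            for r in grp.itertuples(index=False)
        ]
        uptake = []
        if "n_uptake" in frame.columns:
            uptake = [
                (int(r.dat), float(r.n_uptake))
                for r in grp.itertuples(index=False)
                if pd.notna(r.n_uptake)
            ]
        trials.append(TrialObservations(str(trial_id), samplings, n_uptake=uptake))
    return trials
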