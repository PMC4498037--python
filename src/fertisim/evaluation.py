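"""Model-evaluation statistics for paired observed/simulated series.

The battery comprises RMSE, relative RMSE (% of the observed mean),
RSR (RMSE over the square root of the observed sum of squared deviations),
MAE, percent bias (PBIAS, positive = model underestimation) and the
Nash–Sutcliffe efficiency (NSE), plus the scalar percent deviation
(simulated − observed)/observed x 100 and the conventional RRMSE quality
classes (<10% excellent, 10–20% good, 20–30% fair, >=30% poor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class StatsReport:
    """The evaluation battery for one observed/simulated pairing.

    ``rmse`` and ``mae`` are in the units of the variable; ``rrmse`` and
    ``pbias`` in percent; ``rsr`` and ``nse`` dimensionless.
    """

    rmse: float
    rrmse: float
    rsr: float
    mae: float
    pbias: float
    nse: float
    rrmse_class: str
    n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"n={self.n}  RMSE={self.rmse:.4g}  RRMSE={self.rrmse:.2f}% "
            f"({self.rrmse_class})  RSR={self.rsr:.4g}  MAE={self.mae:.4g}  "
            f"PBIAS={self.pbias:.2f}%  NSE={self.nse:.4g}"
        )


def _validate(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise DomainError("obs and sim must be 1-D arrays of equal length")
    if obs.size < 2:
        raise DomainError("need at least 2 paired values")
    if np.ptp(obs) == 0:
        raise DomainError("observed values are constant; RSR and NSE undefined")
    return obs, sim


def evaluate(obs, sim) -> StatsReport:
    """Compute the full statistics battery for paired series."""
    obs, sim = _validate(obs, sim)
    n = obs.size
    obar = obs.mean()
    resid = sim - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    rrmse = rmse * 100.0 / obar
    ss_obs = float(np.sum((obs - obar) ** 2))
    rsr = rmse / np.sqrt(ss_obs)
    mae = float(np.mean(np.abs(resid)))
    pbias = float(np.sum(obs - sim) * 100.0 / np.sum(obs))
    nse = 1.0 - float(np.sum(resid**2)) / ss_obs
    return StatsReport(
        rmse=rmse,
        rrmse=float(rrmse),
        rsr=float(rsr),
        mae=mae,
        pbias=pbias,
        nse=float(nse),
        rrmse_class=classify_rrmse(float(rrmse)) if rrmse >= 0 else "poor",
        n=n,
    )


def mean_signed_error(obs, sim) -> float:
    """Signed mean error (1/n) * sum(S - O): the bias-style variant of MAE
    (positive when the model over-predicts on average)."""
    obs, sim = _validate(obs, sim)
    return float(np.mean(np.asarray(sim) - np.asarray(obs)))


def deviation(simulated: float, observed: float) -> float:
    """Percent deviation (simulated − observed)/observed x 100;
    positive = overestimation."""
    if observed == 0:
        raise DomainError("observed value must be non-zero")
    return (simulated - observed) / observed * 100.0


def classify_rrmse(rrmse: float) -> str:
    """Quality class of a relative RMSE: <10% excellent, [10, 20)% good,
    [20, 30)% fair, >=30% poor."""
    if rrmse < 0:
        raise DomainError("rrmse must be >= 0")
    if rrmse < 10.0:
        return "excellent"
    if rrmse < 20.0:
        return "good"
    if rrmse < 30.0:
        return "fair"
    return "poor"
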