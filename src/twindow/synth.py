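"""Synthetic audiovisual RT / TOJ studies with known ground truth.

The generator mirrors the experimental design the analysis assumes: 60
trials for each of 26 RT conditions (catch, two unisensory, 23 bisensory
SOAs) and 60 TOJ trials per bisensory SOA.  Unisensory reaction times are
ex-Gaussian (the standard RT family); a bisensory trial races an onset-
shifted correlated pair of unisensory draws (Gaussian copula, correlation
``rho``) and optionally subtracts a coactivation gain ``gamma`` from the
winner — gamma = 0 means the race model holds exactly, and gamma may vary
with SOA to confine coactivation to a window around simultaneity.  Misses
become infinite latencies; catch trials draw fast guesses at the configured
rate.  TOJ counts are binomial under the lapse-logistic psychometric
function.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import stats

from .datasets import (
    AUDITORY,
    CATCH,
    INFINITE,
    SOA_GRID,
    VISUAL,
    ConditionRTs,
    ParticipantData,
    StudyDataset,
    TOJTable,
)
from .psychometric import PsychometricParams, psi
from .race import onset_delays

__all__ = [
    "ExGaussian",
    "SynthConfig",
    "simulate_rt_participant",
    "simulate_toj_participant",
    "make_study",
    "make_malleable_study_config",
]


@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian RT family: Normal(mu, sigma) + Exponential(tau), in ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if min(self.mu, self.sigma, self.tau) <= 0:
            raise ValueError("ex-Gaussian parameters must be positive")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function via a dense tabulated inverse of the CDF.

        scipy's exponnorm.ppf inverts numerically per element; the copula
        sampler needs tens of thousands of evaluations, so the inverse is
        interpolated on an 8192-point grid spanning +/-8 sigma and 30 tau
        (absolute error well below 0.1 ms for the latency scales used).
        """
        grid, cdf = _inverse_table(self.mu, self.sigma, self.tau)
        return np.interp(u, cdf, grid)

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size) + rng.exponential(self.tau, size)


@lru_cache(maxsize=32)
def _inverse_table(mu: float, sigma: float, tau: float):
    lo = max(mu - 8.0 * sigma, 1e-3)
    hi = mu + 8.0 * sigma + 30.0 * tau
    grid = np.linspace(lo, hi, 8192)
    cdf = stats.exponnorm.cdf(grid, K=tau / sigma, loc=mu, scale=sigma)
    # enforce strict monotonicity for interpolation
    cdf = np.maximum.accumulate(cdf)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return grid[keep], cdf[keep]


#: Simple-RT defaults: auditory responses faster than visual, right-skewed.
DEFAULT_AUDITORY = ExGaussian(230.0, 30.0, 60.0)
DEFAULT_VISUAL = ExGaussian(280.0, 35.0, 70.0)

#: Default per-participant psychometric ground truth (moderate window).
DEFAULT_TOJ_PARAMS = PsychometricParams(0.0, 80.0, 0.04, 0.04)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and ground-truth parameters for the generator.

    ``gamma`` (coactivation gain, ms subtracted from the race minimum;
    0 = race model holds) may be a scalar applied at every SOA or a mapping
    SOA -> gain so coactivation can be confined to a temporal window.
    ``rho`` is the Gaussian-copula correlation between the unisensory draws
    within a bisensory trial.  ``toj_params`` may be a single parameter set
    (shared) or one per participant.
    """

    n_participants: int = 11
    soa_grid: tuple[int, ...] = SOA_GRID
    n_trials: int = 60
    auditory: ExGaussian = DEFAULT_AUDITORY
    visual: ExGaussian = DEFAULT_VISUAL
    rho: float = 0.0
    gamma: float | Mapping[int, float] = 0.0
    guess_rate: float = 0.0394
    miss_prob: float = 0.007
    toj_params: PsychometricParams | tuple[PsychometricParams, ...] = DEFAULT_TOJ_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        for rate, name in ((self.guess_rate, "guess_rate"), (self.miss_prob, "miss_prob")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        gams = (
            [float(self.gamma)]
            if np.isscalar(self.gamma)
            else [float(v) for v in self.gamma.values()]
        )
        if any(g < 0 for g in gams):
            raise ValueError("coactivation gain gamma must be >= 0")
        if self.n_participants < 0 or self.n_trials <= 0:
            raise ValueError("participant/trial counts must be positive")

    def gamma_at(self, soa: int) -> float:
        if np.isscalar(self.gamma):
            return float(self.gamma)
        return float(self.gamma.get(int(soa), 0.0))

    def toj_params_for(self, idx: int) -> PsychometricParams:
        if isinstance(self.toj_params, PsychometricParams):
            return self.toj_params
        return self.toj_params[idx]


def _correlated_uniform_pair(rho: float, size: int, rng: np.random.Generator):
    """Uniform pair coupled by a Gaussian copula with correlation rho."""
    if rho >= 1.0:
        u = rng.random(size)
        return u, u
    if rho <= -1.0:
        u = rng.random(size)
        return u, 1.0 - u
    z1 = rng.standard_normal(size)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(size)
    return stats.norm.cdf(z1), stats.norm.cdf(z2)


def simulate_rt_participant(
    cfg: SynthConfig, participant_idx: int, rng: np.random.Generator
) -> dict:
    """All 26 RT conditions for one participant (raw: twins not killed)."""
    n = cfg.n_trials
    conds: dict = {}

    def finish(lat: np.ndarray) -> np.ndarray:
        # An anticipatory guessing process races the true response in every
        # stimulus condition: with probability guess_rate the trial draws a
        # guess latency and keeps the faster of the two.  This is the same
        # process observed in isolation on catch trials, and it is what the
        # kill-the-twin correction is built to remove.
        if cfg.guess_rate > 0:
            guess = rng.random(lat.size) < cfg.guess_rate
            g = rng.uniform(100.0, 1000.0, lat.size)
            lat = np.where(guess, np.minimum(lat, g), lat)
        if cfg.miss_prob > 0:
            miss = rng.random(lat.size) < cfg.miss_prob
            lat = np.where(miss, INFINITE, lat)
        return lat

    conds[AUDITORY] = ConditionRTs(
        AUDITORY, None, finish(np.maximum(cfg.auditory.rvs(n, rng), 1.0))
    )
    conds[VISUAL] = ConditionRTs(
        VISUAL, None, finish(np.maximum(cfg.visual.rvs(n, rng), 1.0))
    )
    for soa in cfg.soa_grid:
        d_a, d_v = onset_delays(soa)
        u_a, u_v = _correlated_uniform_pair(cfg.rho, n, rng)
        a = cfg.auditory.ppf(u_a) + d_a
        v = cfg.visual.ppf(u_v) + d_v
        lat = np.maximum(np.minimum(a, v) - cfg.gamma_at(soa), 1.0)
        conds[int(soa)] = ConditionRTs("av", int(soa), finish(lat))
    guess = rng.random(n) < cfg.guess_rate
    catch_lat = np.where(guess, rng.uniform(100.0, 1000.0, n), INFINITE)
    conds[CATCH] = ConditionRTs(CATCH, None, catch_lat)
    return conds


def simulate_toj_participant(
    cfg: SynthConfig, params: PsychometricParams, rng: np.random.Generator
) -> TOJTable:
    """Binomial "visual first" counts per SOA under the lapse-logistic."""
    soas = np.array(cfg.soa_grid, dtype=int)
    p = np.asarray(psi(soas.astype(float), params))
    totals = np.full(soas.size, cfg.n_trials, dtype=int)
    counts = rng.binomial(totals, p)
    return TOJTable(soas, counts, totals)


def make_study(cfg: SynthConfig) -> StudyDataset:
    """Complete synthetic study; ground truth and seed go into metadata."""
    root = np.random.SeedSequence(cfg.seed)
    participants = []
    truth = []
    for idx, child in enumerate(root.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        conds = simulate_rt_participant(cfg, idx, rng)
        params = cfg.toj_params_for(idx)
        toj = simulate_toj_participant(cfg, params, rng)
        pid = f"S{idx + 1:02d}"
        participants.append(ParticipantData(pid, conds, toj))
        truth.append(
            {
                "id": pid,
                "toj_params": {
                    "mu": params.mu,
                    "sigma": params.sigma,
                    "lambda_a": params.lambda_a,
                    "lambda_v": params.lambda_v,
                },
                "gamma": {str(s): cfg.gamma_at(s) for s in cfg.soa_grid},
                "rho": cfg.rho,
            }
        )
    metadata = {
        "source": "synthetic",
        "seed": cfg.seed,
        "kill_the_twin_already_applied": False,
        "guess_rate": cfg.guess_rate,
        "miss_prob": cfg.miss_prob,
        "ground_truth": truth,
    }
    return StudyDataset(participants, metadata)


def make_malleable_study_config(
    seed: int = 0,
    n_malleable: int = 5,
    n_other: int = 6,
    coactivation_gain: float = 60.0,
    coactivation_halfwidth: int = 80,
) -> SynthConfig:
    """Study with a known malleable / non-malleable split.

    Malleable participants get a narrow true TOJ window (sigma 30 ms, order
    thresholds near +/-33 ms) while coactivation spans SOAs within
    ``coactivation_halfwidth`` of simultaneity, so their RT-defined window
    reaches SOAs they can still discriminate.  Non-malleable participants
    get a wide TOJ window (sigma 150 ms, thresholds near +/-165 ms) that
    covers every race-violating SOA.
    """
    narrow = PsychometricParams(0.0, 30.0, 0.03, 0.03)
    wide = PsychometricParams(0.0, 150.0, 0.03, 0.03)
    params = tuple([narrow] * n_malleable + [wide] * n_other)
    gamma = {s: coactivation_gain for s in SOA_GRID if abs(s) <= coactivation_halfwidth}
    return SynthConfig(
        n_participants=n_malleable + n_other,
        gamma=gamma,
        toj_params=params,
        seed=seed,
    )
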