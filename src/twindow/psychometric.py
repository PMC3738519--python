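"""Bayesian fitting of a lapse-aware logistic psychometric function.

The probability of a "visual first" report at SOA ``x`` is modelled as

    Psi(x; mu, sigma, lambda_A, lambda_V)
        = lambda_A + (1 - lambda_A - lambda_V) * F(x; mu, sigma)

with F the logistic CDF, mu the location (point of subjective simultaneity),
sigma the shape, and lambda_A / lambda_V the lapse rates on the auditory-
and visual-leading asymptotes.  The likelihood is binomial per SOA; priors
are Beta(2, 20) on each lapse rate, Normal(0, 200) on mu and Gamma(shape
1.05, scale 1000) on sigma.  The posterior is explored with a univariate
slice sampler applied coordinate-wise (burn-in 100, thinning 10, 2000
retained draws).

The thresholds for above-chance order discrimination solve
Psi(thr_A) = (lambda_A + 0.5)/2 and Psi(thr_V) = (0.5 + 1 - lambda_V)/2
(75% correct when there are no lapses).  The TOJ-defined temporal window of
integration takes the 5th percentile of the auditory-first threshold draws
and the 95th percentile of the visual-first threshold draws — deliberately
the widest plausible boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import betaln, expit, gammaln

from .datasets import TOJTable

__all__ = [
    "PsychometricParams",
    "PriorSpec",
    "PosteriorSamples",
    "TojTWI",
    "psi",
    "log_posterior_unnorm",
    "slice_sample_posterior",
    "thresholds",
    "toj_twi",
    "exclude_nonperformers",
    "group_psychometric",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Location, shape and asymmetric lapse rates of the lapse-logistic."""

    mu: float
    sigma: float
    lambda_a: float
    lambda_v: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0 (got {self.sigma})")
        if not (0 <= self.lambda_a < 1 and 0 <= self.lambda_v < 1):
            raise ValueError("lapse rates must lie in [0, 1)")
        if not self.lambda_a + self.lambda_v < 1:
            raise ValueError("lambda_a + lambda_v must be < 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.lambda_a, self.lambda_v])


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (defaults are the analysis standards).

    Lapse rates: Beta(alpha=2, beta=20) each (mode 1/20 = 0.05).
    Location mu: Normal(mean 0, sd 200) ms.
    Shape sigma: Gamma(shape kappa=1.05, scale theta=1000) ms — near-flat,
    mode (kappa-1)*theta = 50 ms.
    """

    lapse_alpha: float = 2.0
    lapse_beta: float = 20.0
    mu_mean: float = 0.0
    mu_sd: float = 200.0
    sigma_shape: float = 1.05
    sigma_scale: float = 1000.0

    def modes(self) -> PsychometricParams:
        """Prior modes, used as sampler initial values."""
        lapse_mode = (self.lapse_alpha - 1) / (self.lapse_alpha + self.lapse_beta - 2)
        sigma_mode = max((self.sigma_shape - 1) * self.sigma_scale, 1.0)
        return PsychometricParams(self.mu_mean, sigma_mode, lapse_mode, lapse_mode)

    def sds(self) -> np.ndarray:
        """Prior standard deviations per coordinate (slice widths)."""
        a, b = self.lapse_alpha, self.lapse_beta
        lapse_sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        sigma_sd = math.sqrt(self.sigma_shape) * self.sigma_scale
        return np.array([self.mu_sd, sigma_sd, lapse_sd, lapse_sd])


def psi(x, params: PsychometricParams):
    """Lapse-contaminated logistic probability of a "visual first" report."""
    f = expit((np.asarray(x, dtype=float) - params.mu) / params.sigma)
    out = params.lambda_a + (1 - params.lambda_a - params.lambda_v) * f
    return out if out.ndim else float(out)


def _log_prior(theta: np.ndarray, priors: PriorSpec) -> float:
    mu, sigma, la, lv = theta
    if sigma <= 0 or la <= 0 or lv <= 0 or la >= 1 or lv >= 1 or la + lv >= 1:
        return -np.inf
    a, b = priors.lapse_alpha, priors.lapse_beta
    lp = -0.5 * ((mu - priors.mu_mean) / priors.mu_sd) ** 2 - math.log(
        priors.mu_sd * math.sqrt(2 * math.pi)
    )
    lp += (
        (priors.sigma_shape - 1) * math.log(sigma)
        - sigma / priors.sigma_scale
        - priors.sigma_shape * math.log(priors.sigma_scale)
        - gammaln(priors.sigma_shape)
    )
    for lam in (la, lv):
        lp += (a - 1) * math.log(lam) + (b - 1) * math.log1p(-lam) - betaln(a, b)
    return float(lp)


def log_posterior_unnorm(
    params: PsychometricParams | np.ndarray,
    toj: TOJTable,
    priors: PriorSpec = PriorSpec(),
    include_binomial_coefficients: bool = True,
) -> float:
    """Unnormalised log posterior; -inf outside the parameter domain.

    Zero-trial rows contribute nothing (a binomial with n = 0 has a single
    outcome of probability one).
    """
    theta = params.as_array() if isinstance(params, PsychometricParams) else np.asarray(params, float)
    lp = _log_prior(theta, priors)
    if not np.isfinite(lp):
        return -np.inf
    mu, sigma, la, lv = theta
    x = toj.soas.astype(float)
    c = toj.counts.astype(float)
    n = toj.totals.astype(float)
    f = expit((x - mu) / sigma)
    p = la + (1 - la - lv) * f
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(n > 0, c * np.log(p) + (n - c) * np.log1p(-p), 0.0)
    if np.any(np.isnan(ll)):
        return -np.inf
    total = lp + float(np.sum(ll))
    if include_binomial_coefficients:
        total += float(np.sum(gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)))
    return total


# ---------------------------------------------------------------------------
# Compiled slice-sampler core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_log_post(theta, x, c, n, pr):
    """Log posterior up to the data-dependent constant (numba kernel).

    ``pr`` packs (lapse_alpha, lapse_beta, mu_mean, mu_sd, sigma_shape,
    sigma_scale).  Binomial coefficients are omitted (constant in theta).
    """
    mu, sigma, la, lv = theta[0], theta[1], theta[2], theta[3]
    if sigma <= 0.0 or la <= 0.0 or lv <= 0.0 or la >= 1.0 or lv >= 1.0 or la + lv >= 1.0:
        return -np.inf
    a, b = pr[0], pr[1]
    lp = -0.5 * ((mu - pr[2]) / pr[3]) ** 2
    lp += (pr[4] - 1.0) * math.log(sigma) - sigma / pr[5]
    lp += (a - 1.0) * math.log(la) + (b - 1.0) * math.log1p(-la)
    lp += (a - 1.0) * math.log(lv) + (b - 1.0) * math.log1p(-lv)
    scale = 1.0 - la - lv
    for i in range(x.size):
        if n[i] <= 0.0:
            continue
        z = (x[i] - mu) / sigma
        if z >= 0.0:
            f = 1.0 / (1.0 + math.exp(-z))
        else:
            e = math.exp(z)
            f = e / (1.0 + e)
        p = la + scale * f
        if p <= 0.0 or p >= 1.0:
            return -np.inf
        lp += c[i] * math.log(p) + (n[i] - c[i]) * math.log1p(-p)
    return lp


@njit(cache=True)
def _nb_slice_sample(x, c, n, pr, theta0, widths, n_keep, burn_in, thin, seed):
    """Coordinate-wise univariate slice sampling with doubling expansion.

    Per coordinate: place an interval of the prior-SD width at random
    around the current point, expand each end with doubling step sizes
    until it leaves the slice, then sample by shrinkage.
    """
    np.random.seed(seed)
    theta = theta0.copy()
    out = np.empty((n_keep, 4))
    f_cur = _nb_log_post(theta, x, c, n, pr)
    kept = 0
    total = burn_in + thin * n_keep
    for it in range(total):
        for j in range(4):
            logy = f_cur + math.log(np.random.random())
            w = widths[j]
            u = np.random.random()
            left = theta[j] - w * u
            right = left + w
            old = theta[j]
            # expand with doubling step sizes, capped expansions
            step = w
            for _ in range(32):
                theta[j] = left
                if _nb_log_post(theta, x, c, n, pr) <= logy:
                    break
                left -= step
                step *= 2.0
            step = w
            for _ in range(32):
                theta[j] = right
                if _nb_log_post(theta, x, c, n, pr) <= logy:
                    break
                right += step
                step *= 2.0
            # shrinkage
            while True:
                cand = left + np.random.random() * (right - left)
                theta[j] = cand
                f_new = _nb_log_post(theta, x, c, n, pr)
                if f_new > logy:
                    f_cur = f_new
                    break
                if cand < old:
                    left = cand
                else:
                    right = cand
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            out[kept, 0] = theta[0]
            out[kept, 1] = theta[1]
            out[kept, 2] = theta[2]
            out[kept, 3] = theta[3]
            kept += 1
    return out


@dataclass
class PosteriorSamples:
    """Retained posterior draws plus sampler diagnostics."""

    draws: np.ndarray  # (n_samples, 4): mu, sigma, lambda_a, lambda_v
    burn_in: int
    thin: int
    seed: int
    lag1_autocorr: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.lag1_autocorr is None:
            d = self.draws
            ac = np.empty(d.shape[1])
            for j in range(d.shape[1]):
                v = d[:, j] - d[:, j].mean()
                denom = float(v @ v)
                ac[j] = float(v[:-1] @ v[1:]) / denom if denom > 0 else 0.0
            self.lag1_autocorr = ac

    @property
    def n_samples(self) -> int:
        return self.draws.shape[0]

    def medians(self) -> PsychometricParams:
        m = np.median(self.draws, axis=0)
        return PsychometricParams(*m)

    def param_draws(self):
        for row in self.draws:
            yield PsychometricParams(*row)


def slice_sample_posterior(
    toj: TOJTable,
    priors: PriorSpec = PriorSpec(),
    n_samples: int = 2000,
    burn_in: int = 100,
    thin: int = 10,
    rng: np.random.Generator | int | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of the psychometric parameters.

    Runs ``burn_in + thin * n_samples`` raw iterations, keeping every
    ``thin``-th draw after burn-in.  Deterministic given the seed.
    """
    if int(np.count_nonzero(toj.totals > 0)) < 2:
        raise ValueError("need at least 2 SOAs with trials to fit the curve")
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    elif rng is None:
        seed = int(np.random.default_rng().integers(0, 2**31 - 1))
    else:
        seed = int(rng)
    pr = np.array(
        [
            priors.lapse_alpha,
            priors.lapse_beta,
            priors.mu_mean,
            priors.mu_sd,
            priors.sigma_shape,
            priors.sigma_scale,
        ]
    )
    theta0 = priors.modes().as_array()
    x = toj.soas.astype(np.float64)
    c = toj.counts.astype(np.float64)
    n = toj.totals.astype(np.float64)
    if not np.isfinite(_nb_log_post(theta0, x, c, n, pr)):
        raise ValueError(
            "posterior is non-finite at the initial values; "
            "try different starting parameters"
        )
    draws = _nb_slice_sample(
        x, c, n, pr, theta0, priors.sds(), int(n_samples), int(burn_in), int(thin), seed
    )
    return PosteriorSamples(draws, burn_in, thin, seed)


# ---------------------------------------------------------------------------
# Thresholds and the TOJ-defined temporal window
# ---------------------------------------------------------------------------

def thresholds(params: PsychometricParams) -> tuple[float, float]:
    """Auditory-first and visual-first above-chance thresholds (ms).

    Solve Psi(thr_A) = (lambda_A + 0.5)/2 and
    Psi(thr_V) = (0.5 + 1 - lambda_V)/2 via the logistic inverse
    x = mu + sigma * ln(q / (1 - q)) with
    q = (target - lambda_A) / (1 - lambda_A - lambda_V).
    """
    la, lv = params.lambda_a, params.lambda_v
    out = []
    for target in ((la + 0.5) / 2.0, (0.5 + 1.0 - lv) / 2.0):
        q = (target - la) / (1.0 - la - lv)
        out.append(params.mu + params.sigma * math.log(q / (1.0 - q)))
    return out[0], out[1]


@dataclass(frozen=True)
class TojTWI:
    """TOJ-defined temporal window [threshold_A, threshold_V] in ms."""

    threshold_a: float
    threshold_v: float

    @property
    def width(self) -> float:
        return self.threshold_v - self.threshold_a

    def contains(self, soa: float) -> bool:
        return self.threshold_a <= soa <= self.threshold_v


def threshold_draws(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw thresholds, vectorised over the posterior sample."""
    mu = samples.draws[:, 0]
    sigma = samples.draws[:, 1]
    la = samples.draws[:, 2]
    lv = samples.draws[:, 3]
    denom = 1.0 - la - lv
    q_a = ((la + 0.5) / 2.0 - la) / denom
    q_v = ((1.5 - lv) / 2.0 - la) / denom
    thr_a = mu + sigma * np.log(q_a / (1.0 - q_a))
    thr_v = mu + sigma * np.log(q_v / (1.0 - q_v))
    return thr_a, thr_v


def toj_twi(samples: PosteriorSamples) -> TojTWI:
    """Widest-plausible window: 5th pct of thr_A draws, 95th pct of thr_V.

    Percentiles use linearly interpolated order statistics.
    """
    thr_a, thr_v = threshold_draws(samples)
    return TojTWI(
        float(np.percentile(thr_a, 5.0)), float(np.percentile(thr_v, 95.0))
    )


def exclude_nonperformers(
    twi: TojTWI, soa_range: tuple[float, float] = (-400.0, 400.0)
) -> tuple[bool, str | None]:
    """Keep/exclude a participant whose thresholds escape the tested range.

    Returns ``(keep, reason)``; the reason names the failing side.
    """
    reasons = []
    if twi.threshold_a < soa_range[0]:
        reasons.append("auditory-first side")
    if twi.threshold_v > soa_range[1]:
        reasons.append("visual-first side")
    if reasons:
        return False, " and ".join(reasons)
    return True, None


def group_psychometric(per_participant) -> tuple[PsychometricParams, tuple[float, float]]:
    """Group curve: average the per-participant posterior medians.

    Per-parameter posterior medians are averaged arithmetically across
    participants; the group thresholds come from the averaged parameters.
    """
    per_participant = list(per_participant)
    if not per_participant:
        raise ValueError("no participants retained for the group curve")
    med = np.array([s.medians().as_array() for s in per_participant])
    mean = med.mean(axis=0)
    params = PsychometricParams(*mean)
    return params, thresholds(params)
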