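"""Race-model-inequality testing of redundant-signals reaction times.

The race model bounds the speed-up a bisensory stimulus can produce by
probability summation of the unisensory channels:

    P_AV(t) <= P_A(t - dA) + P_V(t - dV)

where dA/dV shift each unisensory CDF to the modality's physical onset
(reaction times are clocked from the first stimulus; with a signed SOA
``s`` where negative = auditory leading, dA = max(s, 0), dV = max(-s, 0)).

Empirical CDFs use the plotting-position convention in which the i-th of n
order statistics (n counts infinite entries) sits at probability
(i - 0.5)/n, with linear interpolation between order statistics.  The test
statistic collapses the bisensory-vs-bound quantile differences at
percentiles 10, 15, 20 and 25:

    D = sum_p [ Q_AV(p) - Q_bound(p) ]        (D < 0: violation)

Significance per SOA comes from a resampling null in which the bisensory
sample is replaced by antithetically paired unisensory draws (quantile u in
one modality with quantile 1-u in the other, keeping the faster), the most
negatively dependent race — a deliberately conservative null.  A group-level
sign-permutation test sums D across participants under all 2^n sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ConditionRTs, ParticipantData, SOA_GRID
from .preprocess import KillTwinMode, kill_the_twin

__all__ = [
    "QuantileFunction",
    "RaceTestResult",
    "RtTWI",
    "DEFAULT_PERCENTILES",
    "empirical_quantile_function",
    "race_bound_quantiles",
    "d_statistic",
    "simulate_null_av",
    "race_test",
    "rt_twi",
    "group_sign_permutation",
]

#: Percentiles collapsed into the D statistic.
DEFAULT_PERCENTILES: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)


class QuantileError(ValueError):
    """A requested percentile lies beyond the finite support of a sample."""


@dataclass(frozen=True)
class QuantileFunction:
    """Empirical CDF / quantile function of one RT sample.

    ``sorted_finite`` holds the finite order statistics; ``n_total`` counts
    every trial including infinite entries, which contribute upper-tail
    mass only.  Plotting positions are (i - 0.5) / n_total.
    """

    sorted_finite: np.ndarray
    n_total: int

    @property
    def positions(self) -> np.ndarray:
        return (np.arange(1, self.sorted_finite.size + 1) - 0.5) / self.n_total

    @property
    def max_percentile(self) -> float:
        """Largest percentile attainable from finite latencies."""
        return (self.sorted_finite.size - 0.5) / self.n_total

    def quantile(self, p: float) -> float:
        """Latency at which the empirical CDF reaches ``p``.

        Linear interpolation between adjacent plotting positions; ``p``
        below the first position clamps to the minimum latency; ``p``
        beyond the last finite position raises :class:`QuantileError`.
        """
        if not 0.0 < p <= 1.0:
            raise QuantileError(f"percentile {p} outside (0, 1]")
        if p > self.max_percentile:
            raise QuantileError(
                f"percentile {p:.4g} beyond finite support "
                f"(max attainable {self.max_percentile:.4g})"
            )
        pos = self.positions
        return float(np.interp(p, pos, self.sorted_finite))

    def quantiles(self, ps) -> np.ndarray:
        return np.array([self.quantile(p) for p in np.atleast_1d(ps)], dtype=float)

    def cdf(self, t) -> np.ndarray:
        """Empirical CDF at times ``t`` (0 below the minimum latency)."""
        t = np.asarray(t, dtype=float)
        if self.sorted_finite.size == 0:
            return np.zeros_like(t)
        pos = self.positions
        out = np.interp(t, self.sorted_finite, pos, left=0.0, right=pos[-1])
        return np.where(t < self.sorted_finite[0], 0.0, out)


def empirical_quantile_function(rts: ConditionRTs) -> QuantileFunction:
    """Build the plotting-position quantile function of an RT sample."""
    finite = np.sort(rts.finite)
    if finite.size == 0:
        raise ValueError(
            f"{rts.condition_label}: no finite latencies; quantiles undefined"
        )
    return QuantileFunction(finite, rts.n_total)


def onset_delays(soa: float) -> tuple[float, float]:
    """Per-modality onset delays (dA, dV) from first-stimulus onset."""
    return max(float(soa), 0.0), max(-float(soa), 0.0)


def _cdf_sorted(fin: np.ndarray, n_total: int, t: np.ndarray) -> np.ndarray:
    """Plotting-position CDF of a sorted finite sample at times ``t``."""
    pos = (np.arange(1, fin.size + 1) - 0.5) / n_total
    out = np.interp(t, fin, pos, left=0.0, right=pos[-1])
    return np.where(t < fin[0], 0.0, out)


def _bound_times(
    a_fin: np.ndarray,
    na_tot: int,
    v_fin: np.ndarray,
    nv_tot: int,
    d_a: float,
    d_v: float,
    ps: np.ndarray,
) -> np.ndarray:
    """Invert B(t) = P_A(t - dA) + P_V(t - dV) at each percentile in ps.

    B is piecewise linear between the merged, onset-shifted sample
    latencies, so inversion interpolates exactly on that grid.
    """
    grid = np.unique(np.concatenate([a_fin + d_a, v_fin + d_v]))
    s = _cdf_sorted(a_fin, na_tot, grid - d_a) + _cdf_sorted(v_fin, nv_tot, grid - d_v)
    out = np.empty(ps.size)
    for i, p in enumerate(ps):
        if p > s[-1]:
            raise QuantileError(
                f"race bound never reaches percentile {p:.4g} "
                f"(max attainable {s[-1]:.4g})"
            )
        j = int(np.searchsorted(s, p))
        if j == 0 or s[j] == p:
            t = grid[j] if s[j] >= p else grid[0]
        else:
            t = grid[j - 1] + (p - s[j - 1]) / (s[j] - s[j - 1]) * (grid[j] - grid[j - 1])
        out[i] = t
    return out


def race_bound_quantiles(
    aud: QuantileFunction,
    vis: QuantileFunction,
    soa: float,
    percentiles=DEFAULT_PERCENTILES,
):
    """Times at which the race bound first reaches each percentile.

    The bound CDF is B(t) = min(1, P_A(t - dA) + P_V(t - dV)); the cap at 1
    never matters when inverting at percentiles <= 1.
    """
    ps = np.atleast_1d(np.asarray(percentiles, dtype=float))
    if np.any((ps <= 0) | (ps > 1)):
        raise QuantileError("race-bound percentiles must lie in (0, 1]")
    d_a, d_v = onset_delays(soa)
    times = _bound_times(
        aud.sorted_finite, aud.n_total, vis.sorted_finite, vis.n_total, d_a, d_v, ps
    )
    return {float(p): float(t) for p, t in zip(ps, times)}


def d_statistic(
    av: QuantileFunction, bound, percentiles=DEFAULT_PERCENTILES
) -> float:
    """Collapsed bisensory-minus-bound quantile difference (ms); < 0 violates."""
    return float(
        sum(av.quantile(p) - bound[float(p)] for p in percentiles)
    )


# ---------------------------------------------------------------------------
# Resampling null
# ---------------------------------------------------------------------------

def _antithetic_minima(
    aud_sorted: np.ndarray,
    vis_sorted: np.ndarray,
    soa: float,
    shape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minima of antithetically paired, onset-shifted unisensory resamples.

    Reaction times (infinite ones included, sorted last) are resampled
    with replacement: the draw at quantile u of one modality is paired
    with the draw at quantile 1 - u of the other (rank ceil(u * n), the
    step-function inverse CDF), and the faster onset-shifted response is
    kept.  Discrete resampling of observed latencies, not interpolation,
    so the null replicates the published bootstrap exactly.
    """
    d_a, d_v = onset_delays(soa)
    na, nv = aud_sorted.size, vis_sorted.size
    u = rng.random(shape)
    ra = np.maximum(np.ceil(u * na), 1.0).astype(np.intp) - 1
    rv = np.maximum(np.ceil((1.0 - u) * nv), 1.0).astype(np.intp) - 1
    return np.minimum(aud_sorted[ra] + d_a, vis_sorted[rv] + d_v)


def simulate_null_av(
    aud: ConditionRTs,
    vis: ConditionRTs,
    soa: float,
    n_out: int,
    catch: ConditionRTs,
    rng: np.random.Generator,
) -> ConditionRTs:
    """One simulated bisensory sample under the race-model null.

    Each draw pairs the auditory quantile at u with the visual quantile at
    1 - u (maximal negative dependence) and keeps the faster onset-shifted
    response; the sample then undergoes kill-the-twin in PROGRESSIVE mode
    with the participant's catch responses.
    """
    if int(soa) not in SOA_GRID:
        raise ValueError(f"SOA {soa} not on the tested grid")
    if aud.finite.size == 0 or vis.finite.size == 0:
        raise ValueError("both unisensory samples need finite latencies")
    m = _antithetic_minima(
        np.sort(aud.latencies), np.sort(vis.latencies), soa, n_out, rng
    )
    cond = ConditionRTs("av", int(soa), m)
    return kill_the_twin(cond, catch, KillTwinMode.PROGRESSIVE)


def _row_quantiles_sorted(m: np.ndarray, n_total: int, ps) -> np.ndarray:
    """Plotting-position quantiles per row of a row-sorted matrix.

    Rows share the same positions because every row has ``n_total`` entries
    (infinite ones included).  Rows whose finite support does not reach a
    percentile yield ``inf`` there.
    """
    pos = (np.arange(1, n_total + 1) - 0.5) / n_total
    out = np.empty((m.shape[0], len(ps)), dtype=float)
    for j, p in enumerate(ps):
        k = int(np.searchsorted(pos, p))
        if k == 0:
            out[:, j] = m[:, 0]
        elif k >= n_total:
            out[:, j] = np.inf
        else:
            frac = (p - pos[k - 1]) / (pos[k] - pos[k - 1])
            lo, hi = m[:, k - 1], m[:, k]
            with np.errstate(invalid="ignore"):
                q = lo + frac * (hi - lo)
            out[:, j] = np.where(np.isinf(hi), np.inf, q)
    return out


def _kill_twins_rows(m: np.ndarray, guesses: np.ndarray) -> np.ndarray:
    """Progressive kill-the-twin applied to every row of a sorted matrix."""
    for g in np.sort(guesses):
        with np.errstate(invalid="ignore"):
            d = np.abs(m - g)
        idx = np.argmin(d, axis=1)  # ties -> first (lower) entry
        rows = np.nonzero(np.isfinite(d[np.arange(m.shape[0]), idx]))[0]
        m[rows, idx[rows]] = np.inf
    return m


@dataclass(frozen=True)
class RaceTestResult:
    """Per-SOA outcome of the resampling race-model test."""

    soa: int
    d: float
    p: float
    significant: bool
    n_iter: int
    alpha: float
    untestable: bool = False
    null_draws: np.ndarray | None = field(default=None, repr=False, compare=False)


def race_test(
    participant: ParticipantData,
    soa: int,
    n_iter: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    percentiles=DEFAULT_PERCENTILES,
    regenerate_bound: bool = True,
    keep_null_draws: bool = False,
) -> RaceTestResult:
    """Resampling test of the race inequality at one SOA.

    The observed D is compared with ``n_iter`` null statistics D* obtained
    by substituting antithetic unisensory resamples (size-matched to the
    observed bisensory sample, progressive kill-the-twin applied) for the
    observed bisensory distribution; p = (#{D* <= D} + 1) / (n_iter + 1),
    one-sided.  By default each iteration also rebuilds the bound from
    bootstrap resamples of the unisensory samples so D* and D carry the
    same two sources of estimation noise (``regenerate_bound=False`` reuses
    the observed bound).  SOAs whose bisensory sample cannot reach
    percentile 25 with finite latencies are flagged untestable and treated
    as non-significant.
    """
    if rng is None:
        rng = np.random.default_rng()
    av = participant.av(soa)
    aud = participant.auditory
    vis = participant.visual
    catch = participant.catch
    ps = tuple(float(p) for p in percentiles)

    try:
        q_av = empirical_quantile_function(av)
        q_a = empirical_quantile_function(aud)
        q_v = empirical_quantile_function(vis)
        bound = race_bound_quantiles(q_a, q_v, soa, ps)
        if q_av.max_percentile < max(ps):
            raise QuantileError("bisensory sample too sparse")
        d_obs = d_statistic(q_av, bound, ps)
    except (QuantileError, ValueError):
        return RaceTestResult(int(soa), np.nan, 1.0, False, n_iter, alpha, untestable=True)

    n_out = av.n_total
    m = _antithetic_minima(
        np.sort(aud.latencies), np.sort(vis.latencies), soa, (n_iter, n_out), rng
    )
    m.sort(axis=1)
    guesses = catch.finite
    if guesses.size:
        m = _kill_twins_rows(m, guesses)
        m.sort(axis=1)
    q_null = _row_quantiles_sorted(m, n_out, ps)
    if regenerate_bound:
        # Rebuild the bound each iteration from bootstrap resamples of the
        # unisensory samples, so D* carries the bound's sampling variance
        # just as the observed D does.  Without this the null distribution
        # is underdispersed and the test anticonservative.
        d_a, d_v = onset_delays(soa)
        ps_arr = np.asarray(ps, dtype=float)
        a_lat = aud.latencies
        v_lat = vis.latencies
        a_idx = rng.integers(0, a_lat.size, size=(n_iter, a_lat.size))
        v_idx = rng.integers(0, v_lat.size, size=(n_iter, v_lat.size))
        d_null = np.empty(n_iter)
        for i in range(n_iter):
            a_bs = a_lat[a_idx[i]]
            v_bs = v_lat[v_idx[i]]
            a_fin = np.sort(a_bs[np.isfinite(a_bs)])
            v_fin = np.sort(v_bs[np.isfinite(v_bs)])
            if a_fin.size == 0 or v_fin.size == 0:
                d_null[i] = np.inf
                continue
            try:
                b_i = _bound_times(
                    a_fin, a_lat.size, v_fin, v_lat.size, d_a, d_v, ps_arr
                )
                d_null[i] = np.sum(q_null[i] - b_i)
            except QuantileError:
                d_null[i] = np.inf
    else:
        d_null = np.sum(q_null - np.array([bound[p] for p in ps]), axis=1)
    p_val = (np.count_nonzero(d_null <= d_obs) + 1) / (n_iter + 1)
    return RaceTestResult(
        int(soa),
        d_obs,
        float(p_val),
        bool(p_val < alpha),
        n_iter,
        alpha,
        null_draws=d_null if keep_null_draws else None,
    )


# ---------------------------------------------------------------------------
# Temporal window from the RT task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RtTWI:
    """Contiguous run of significantly race-violating SOAs (ms)."""

    lower: int
    upper: int
    members: tuple[int, ...]

    @property
    def width(self) -> int:
        return self.upper - self.lower


def rt_twi(results) -> RtTWI | None:
    """Contiguity rule: the significant run containing 0, else nearest to 0.

    Among maximal contiguous runs of significant SOAs on the tested grid,
    return the run containing physical simultaneity; otherwise the run whose
    nearest endpoint is closest to 0 (tie broken toward the positive,
    visual-leading side).  ``None`` when no SOA is significant.
    """
    by_soa = {r.soa: r for r in results}
    grid = sorted(by_soa)
    runs: list[list[int]] = []
    current: list[int] = []
    for s in grid:
        if by_soa[s].significant and not by_soa[s].untestable:
            current.append(s)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if not runs:
        return None

    def distance(run: list[int]) -> float:
        if run[0] <= 0 <= run[-1]:
            return 0.0
        return min(abs(run[0]), abs(run[-1]))

    best = min(runs, key=lambda r: (distance(r), -(r[0] > 0)))
    return RtTWI(best[0], best[-1], tuple(best))


def group_sign_permutation(d_values) -> float:
    """Exact one-sided sign-permutation p for per-participant D at one SOA.

    All 2^n reassignments of each participant's D to +/- are enumerated;
    p = fraction of permutation sums <= the observed sum (observed
    assignment included).
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ValueError("no D values supplied")
    if not np.all(np.isfinite(d)):
        raise ValueError("sign-permutation test requires finite D values")
    n = d.size
    if n > 20:
        raise ValueError(f"exhaustive enumeration limited to n <= 20 (got {n})")
    obs = float(d.sum())
    codes = np.arange(2 ** n, dtype=np.int64)
    signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)
    sums = signs @ d
    # tolerance so the observed assignment counts itself regardless of
    # floating-point summation order
    tol = 1e-9 * max(1.0, float(np.abs(d).sum()))
    return float(np.count_nonzero(sums <= obs + tol) / sums.size)
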