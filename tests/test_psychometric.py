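"""Lapse-logistic model, priors, posterior, slice sampler and thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from twindow.datasets import SOA_GRID, TOJTable
from twindow.psychometric import (
    PosteriorSamples,
    PriorSpec,
    PsychometricParams,
    exclude_nonperformers,
    group_psychometric,
    log_posterior_unnorm,
    psi,
    slice_sample_posterior,
    thresholds,
    toj_twi,
)
from twindow.psychometric import _nb_log_post


def table(counts, totals=None, soas=None):
    soas = np.array(SOA_GRID if soas is None else soas)
    counts = np.asarray(counts)
    totals = np.full(soas.size, 60) if totals is None else np.asarray(totals)
    return TOJTable(soas, counts, totals)


valid_params = st.builds(
    PsychometricParams,
    mu=st.floats(-150, 150),
    sigma=st.floats(5, 400),
    lambda_a=st.floats(0.001, 0.3),
    lambda_v=st.floats(0.001, 0.3),
)


class TestPsi:
    def test_midpoint_and_asymptotes(self):
        p = PsychometricParams(10.0, 50.0, 0.0, 0.0)
        assert psi(10.0, p) == pytest.approx(0.5)
        p2 = PsychometricParams(0.0, 50.0, 0.06, 0.09)
        assert psi(-1e9, p2) == pytest.approx(0.06)
        assert psi(1e9, p2) == pytest.approx(1 - 0.09)

    def test_threequarters_at_mu_plus_sigma_ln3(self):
        p = PsychometricParams(0.0, 40.0, 0.0, 0.0)
        assert psi(40.0 * math.log(3.0), p) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=60)
    @given(params=valid_params, x=st.floats(-500, 500), dx=st.floats(0.1, 100))
    def test_monotone_and_bounded(self, params, x, dx):
        # monotone non-decreasing (strictness is lost to rounding only when
        # the logistic saturates in double precision)
        lo, hi = psi(x, params), psi(x + dx, params)
        assert lo <= hi
        assert params.lambda_a <= lo <= 1 - params.lambda_v
        if abs((x - params.mu) / params.sigma) < 30:
            assert lo < hi

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PsychometricParams(0.0, -1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            PsychometricParams(0.0, 50.0, 0.6, 0.5)


class TestLogPosterior:
    def test_single_row_matches_hand_computation(self):
        params = PsychometricParams(0.0, 50.0, 0.05, 0.05)
        t = table([5], totals=[10], soas=[0])
        got = log_posterior_unnorm(params, t)
        p0 = psi(0.0, params)
        expected = (
            math.lgamma(11) - 2 * math.lgamma(6)  # log C(10, 5)
            + 5 * math.log(p0) + 5 * math.log(1 - p0)
            + stats.norm.logpdf(0.0, 0.0, 200.0)
            + stats.gamma.logpdf(50.0, a=1.05, scale=1000.0)
            + 2 * stats.beta.logpdf(0.05, 2.0, 20.0)
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_trial_rows_contribute_nothing(self):
        params = PsychometricParams(5.0, 60.0, 0.04, 0.04)
        t1 = table([5, 9], totals=[10, 10], soas=[-40, 40])
        t2 = table([5, 0, 9], totals=[10, 0, 10], soas=[-40, 0, 40])
        assert log_posterior_unnorm(params, t1) == pytest.approx(
            log_posterior_unnorm(params, t2)
        )

    def test_out_of_domain_is_minus_inf(self):
        t = table([5], totals=[10], soas=[0])
        assert log_posterior_unnorm(np.array([0.0, -1.0, 0.05, 0.05]), t) == -np.inf
        assert log_posterior_unnorm(np.array([0.0, 50.0, 0.6, 0.6]), t) == -np.inf

    def test_compiled_kernel_agrees_up_to_constant(self, rng):
        """The numba kernel omits binomial coefficients only; it must equal
        the reference log posterior up to that data constant."""
        t = table(rng.integers(0, 61, 23))
        pr = np.array([2.0, 20.0, 0.0, 200.0, 1.05, 1000.0])
        const = None
        for _ in range(20):
            theta = np.array(
                [rng.uniform(-80, 80), rng.uniform(10, 200),
                 rng.uniform(0.01, 0.3), rng.uniform(0.01, 0.3)]
            )
            ref = log_posterior_unnorm(theta, t, include_binomial_coefficients=False)
            # reference includes normalising constants of the priors
            norm_const = (
                -math.log(200.0 * math.sqrt(2 * math.pi))
                - 1.05 * math.log(1000.0) - math.lgamma(1.05)
                + 2 * (math.lgamma(22.0) - math.lgamma(2.0) - math.lgamma(20.0))
            )
            got = _nb_log_post(theta, t.soas.astype(float), t.counts.astype(float),
                               t.totals.astype(float), pr)
            assert got + norm_const == pytest.approx(ref, abs=1e-8)

    def test_priors_are_proper(self):
        """Each prior factor integrates to one."""
        spec = PriorSpec()
        one, _ = integrate.quad(lambda m: stats.norm.pdf(m, spec.mu_mean, spec.mu_sd), -4000, 4000)
        assert one == pytest.approx(1.0, abs=1e-6)
        one, _ = integrate.quad(
            lambda s: stats.gamma.pdf(s, a=spec.sigma_shape, scale=spec.sigma_scale),
            0, 50000, limit=200,
        )
        assert one == pytest.approx(1.0, abs=1e-4)
        one, _ = integrate.quad(
            lambda l: stats.beta.pdf(l, spec.lapse_alpha, spec.lapse_beta), 0, 1
        )
        assert one == pytest.approx(1.0, abs=1e-9)


class TestSliceSampler:
    def test_same_seed_identical_draws(self):
        t = table(np.clip((np.array(SOA_GRID) > 0) * 55 + 3, 0, 60))
        a = slice_sample_posterior(t, n_samples=50, burn_in=20, thin=2, rng=99)
        b = slice_sample_posterior(t, n_samples=50, burn_in=20, thin=2, rng=99)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.n_samples == 50

    def test_draws_satisfy_domain_invariants(self):
        t = table(np.clip((np.array(SOA_GRID) > 0) * 55 + 3, 0, 60))
        s = slice_sample_posterior(t, n_samples=200, burn_in=50, thin=2, rng=5)
        d = s.draws
        assert np.all(d[:, 1] > 0)
        assert np.all((d[:, 2] > 0) & (d[:, 2] < 1))
        assert np.all(d[:, 2] + d[:, 3] < 1)

    def test_zero_trial_table_rejected(self):
        t = table(np.zeros(23, dtype=int), totals=np.zeros(23, dtype=int))
        with pytest.raises(ValueError, match="at least 2"):
            slice_sample_posterior(t, n_samples=10, rng=0)

    def test_sharp_data_recovers_truth(self):
        """n = 10^4 trials per SOA pins the posterior onto the truth."""
        truth = PsychometricParams(15.0, 70.0, 0.05, 0.08)
        rng = np.random.default_rng(31)
        soas = np.array(SOA_GRID)
        n = 10_000
        counts = rng.binomial(n, psi(soas.astype(float), truth))
        t = TOJTable(soas, counts, np.full(23, n))
        s = slice_sample_posterior(t, n_samples=500, burn_in=100, thin=5, rng=17)
        med = s.medians()
        assert med.mu == pytest.approx(truth.mu, abs=2.0)
        assert med.sigma == pytest.approx(truth.sigma, rel=0.05)
        assert med.lambda_a == pytest.approx(truth.lambda_a, abs=0.01)
        assert med.lambda_v == pytest.approx(truth.lambda_v, abs=0.01)


class TestThresholds:
    def test_closed_form_no_lapse(self):
        thr_a, thr_v = thresholds(PsychometricParams(0.0, 50.0, 0.0, 0.0))
        assert thr_a == pytest.approx(-50 * math.log(3))
        assert thr_v == pytest.approx(50 * math.log(3))
        # 75% correct on each side when there are no lapses
        p = PsychometricParams(0.0, 50.0, 0.0, 0.0)
        assert psi(thr_a, p) == pytest.approx(0.25)
        assert psi(thr_v, p) == pytest.approx(0.75)

    def test_location_equivariance(self):
        p0 = PsychometricParams(0.0, 40.0, 0.05, 0.1)
        p1 = PsychometricParams(20.0, 40.0, 0.05, 0.1)
        a0, v0 = thresholds(p0)
        a1, v1 = thresholds(p1)
        assert a1 - a0 == pytest.approx(20.0)
        assert v1 - v0 == pytest.approx(20.0)

    @settings(deadline=None, max_examples=50)
    @given(params=valid_params)
    def test_agrees_with_numeric_root_finding(self, params):
        thr_a, thr_v = thresholds(params)
        target_a = (params.lambda_a + 0.5) / 2
        target_v = (1.5 - params.lambda_v) / 2
        lo, hi = params.mu - 60 * params.sigma, params.mu + 60 * params.sigma
        root_a = optimize.brentq(lambda x: psi(x, params) - target_a, lo, hi, xtol=1e-12)
        root_v = optimize.brentq(lambda x: psi(x, params) - target_v, lo, hi, xtol=1e-12)
        assert abs(thr_a - root_a) < 1e-9
        assert abs(thr_v - root_v) < 1e-9


class TestTojTwi:
    def _samples(self, draws):
        return PosteriorSamples(np.asarray(draws, dtype=float), 100, 10, 0)

    def test_degenerate_posterior_equals_point_thresholds(self):
        p = PsychometricParams(5.0, 60.0, 0.02, 0.03)
        s = self._samples([p.as_array()] * 2000)
        w = toj_twi(s)
        thr_a, thr_v = thresholds(p)
        assert w.threshold_a == pytest.approx(thr_a)
        assert w.threshold_v == pytest.approx(thr_v)

    def test_spread_never_narrows_the_window(self):
        base = PsychometricParams(0.0, 50.0, 0.02, 0.02).as_array()
        tight = np.tile(base, (2000, 1))
        spread = tight.copy()
        spread[::2, 0] += 15.0  # mean-preserving spread of the location
        spread[1::2, 0] -= 15.0
        w_tight = toj_twi(self._samples(tight))
        w_spread = toj_twi(self._samples(spread))
        assert w_spread.threshold_a <= w_tight.threshold_a
        assert w_spread.threshold_v >= w_tight.threshold_v

    def test_nonperformer_exclusion_rules(self):
        from twindow.psychometric import TojTWI

        keep, reason = exclude_nonperformers(TojTWI(-100.0, 500.0))
        assert not keep and reason == "visual-first side"
        keep, reason = exclude_nonperformers(TojTWI(-450.0, 60.0))
        assert not keep and reason == "auditory-first side"
        keep, reason = exclude_nonperformers(TojTWI(-100.0, 60.0))
        assert keep and reason is None


class TestGroupCurve:
    def _samples_for(self, params, jitter=0.0):
        draws = np.tile(params.as_array(), (100, 1))
        return PosteriorSamples(draws, 100, 10, 0)

    def test_single_participant_identity(self):
        p = PsychometricParams(12.0, 45.0, 0.03, 0.06)
        group, (thr_a, thr_v) = group_psychometric([self._samples_for(p)])
        assert group.mu == pytest.approx(p.mu)
        assert group.sigma == pytest.approx(p.sigma)
        ta, tv = thresholds(p)
        assert (thr_a, thr_v) == pytest.approx((ta, tv))

    def test_symmetric_locations_average_to_zero(self):
        a = PsychometricParams(20.0, 50.0, 0.0001, 0.0001)
        b = PsychometricParams(-20.0, 50.0, 0.0001, 0.0001)
        group, _ = group_psychometric([self._samples_for(a), self._samples_for(b)])
        assert group.mu == pytest.approx(0.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            group_psychometric([])
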