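"""Quantile machinery, the race bound, D, the resampling test, contiguity,
and the group sign-permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twindow.datasets import ConditionRTs
from twindow.race import (
    QuantileFunction,
    RaceTestResult,
    d_statistic,
    empirical_quantile_function,
    group_sign_permutation,
    race_bound_quantiles,
    race_test,
    rt_twi,
    simulate_null_av,
)
from twindow.race import QuantileError, _antithetic_minima, _row_quantiles_sorted

from conftest import make_participant


def qf(values, n_total=None):
    values = np.asarray(values, dtype=float)
    c = ConditionRTs("auditory_only", None, values)
    return empirical_quantile_function(c)


class TestQuantileFunction:
    def test_hand_interpolation_example(self):
        q = qf([200.0, 250.0, 300.0, 350.0])
        # positions 0.125, 0.375, ...; interpolate between 200 and 250
        assert q.quantile(0.25) == pytest.approx(225.0)

    def test_degenerate_distribution(self):
        q = qf([300.0] * 5)
        for p in (0.05, 0.25, 0.5, 0.9):
            assert q.quantile(p) == 300.0

    def test_clamps_below_first_position(self):
        q = qf([200.0, 300.0])
        assert q.quantile(0.01) == 200.0

    def test_infinite_mass_accounting(self):
        lat = [250.0 + i for i in range(30)] + [np.inf] * 30
        q = qf(lat)
        q.quantile(0.25)  # attainable: (30 - 0.5)/60 ~ 0.49
        with pytest.raises(QuantileError, match="0.6"):
            q.quantile(0.60)

    def test_all_infinite_is_an_error(self):
        with pytest.raises(ValueError):
            qf([np.inf, np.inf])

    @settings(deadline=None, max_examples=80)
    @given(
        sample=st.lists(st.floats(1, 1000), min_size=1, max_size=30),
        p=st.floats(0.01, 0.99),
    )
    def test_matches_hazen_convention_on_finite_samples(self, sample, p):
        """With no infinite entries the convention is the Hazen plotting
        position, implemented independently in numpy."""
        q = qf(sample)
        p = min(p, q.max_percentile)
        expected = np.quantile(np.asarray(sample), p, method="hazen")
        assert q.quantile(p) == pytest.approx(float(expected), abs=1e-9)

    def test_row_quantiles_agree_with_scalar_path(self, rng):
        m = rng.uniform(100, 500, size=(50, 12))
        m[rng.random((50, 12)) < 0.1] = np.inf
        m.sort(axis=1)
        ps = (0.10, 0.15, 0.20, 0.25)
        rows = _row_quantiles_sorted(m.copy(), 12, ps)
        for i in range(m.shape[0]):
            q = QuantileFunction(m[i][np.isfinite(m[i])], 12)
            for j, p in enumerate(ps):
                if p <= q.max_percentile:
                    assert rows[i, j] == pytest.approx(q.quantile(p))
                else:
                    assert np.isinf(rows[i, j])


class TestRaceBound:
    def test_identical_point_masses(self):
        a = qf([300.0])
        b = race_bound_quantiles(a, a, soa=0, percentiles=(0.25, 0.9, 1.0))
        assert all(v == 300.0 for v in b.values())

    def test_large_positive_soa_is_visual_dominated(self, rng):
        """With the auditory channel delayed beyond every visual latency the
        bound at low percentiles is the visual quantile function, so SOAs
        +300 and +400 coincide."""
        aud = qf(rng.uniform(200, 290, 40))
        vis = qf(rng.uniform(180, 295, 40))
        ps = (0.10, 0.15, 0.20, 0.25)
        b300 = race_bound_quantiles(aud, vis, soa=300, percentiles=ps)
        b400 = race_bound_quantiles(aud, vis, soa=400, percentiles=ps)
        for p in ps:
            assert b300[p] == pytest.approx(b400[p])
            assert b300[p] == pytest.approx(vis.quantile(p))

    def test_direct_evaluation_oracle(self, rng):
        """Bound inversion equals a brute-force scan of B on a fine grid."""
        aud = qf(rng.uniform(200, 400, 15))
        vis = qf(rng.uniform(220, 450, 15))
        soa = -60
        ps = (0.10, 0.25)
        b = race_bound_quantiles(aud, vis, soa, percentiles=ps)
        t_grid = np.linspace(100, 600, 200001)
        s = aud.cdf(t_grid - max(soa, 0)) + vis.cdf(t_grid - max(-soa, 0))
        for p in ps:
            t_first = t_grid[np.argmax(s >= p)]
            assert b[p] == pytest.approx(t_first, abs=0.01)

    def test_unreachable_percentile_errors(self):
        # one finite of two trials per modality: bound tops out at 0.5
        a = QuantileFunction(np.array([300.0]), 2)
        with pytest.raises(QuantileError, match="never reaches"):
            race_bound_quantiles(a, a, soa=0, percentiles=(0.9,))


class TestDStatistic:
    def test_identity_and_linearity(self):
        av = qf([200.0, 250.0, 300.0, 350.0])
        ps = (0.10, 0.15, 0.20, 0.25)
        bound = {p: av.quantile(p) for p in ps}
        assert d_statistic(av, bound, ps) == pytest.approx(0.0)
        shifted = {p: av.quantile(p) + 10.0 for p in ps}
        assert d_statistic(av, shifted, ps) == pytest.approx(-40.0)

    def test_matches_bruteforce_sum(self, rng):
        av = qf(rng.uniform(150, 500, 25))
        ps = (0.10, 0.15, 0.20, 0.25)
        bound = {p: float(rng.uniform(150, 400)) for p in ps}
        expected = 0.0
        for p in ps:
            expected += av.quantile(p) - bound[p]
        assert d_statistic(av, bound, ps) == pytest.approx(expected)

    def test_translation_equivariance(self, rng):
        lat = rng.uniform(200, 400, 30)
        ps = (0.10, 0.15, 0.20, 0.25)
        bound = {p: 250.0 for p in ps}
        d0 = d_statistic(qf(lat), bound, ps)
        d1 = d_statistic(qf(lat + 17.0), bound, ps)
        assert d1 - d0 == pytest.approx(4 * 17.0)


class TestNullSimulation:
    def test_point_masses_reproduce_point(self, rng):
        aud = ConditionRTs("auditory_only", None, [300.0] * 10)
        vis = ConditionRTs("visual_only", None, [300.0] * 10)
        catch = ConditionRTs("catch", None, [])
        sim = simulate_null_av(aud, vis, 0, 10, catch, rng)
        np.testing.assert_allclose(sim.latencies, 300.0)

    def test_one_catch_response_one_infinite(self, rng):
        aud = ConditionRTs("auditory_only", None, list(np.linspace(200, 400, 20)))
        vis = ConditionRTs("visual_only", None, list(np.linspace(250, 450, 20)))
        catch = ConditionRTs("catch", None, [260.0])
        sim = simulate_null_av(aud, vis, 0, 20, catch, rng)
        assert sim.n_infinite == 1 and sim.n_total == 20

    def test_antithetic_pairing_is_fastest_race(self, rng):
        """Antithetic (u, 1-u) rank pairing yields minima stochastically
        faster than independent resampling of the same marginals."""
        aud = np.sort(rng.uniform(200, 400, 40))
        vis = np.sort(rng.uniform(220, 460, 40))
        n = 40000
        anti = _antithetic_minima(aud, vis, 0, n, rng)
        a_idx = rng.integers(0, 40, n)
        v_idx = rng.integers(0, 40, n)
        indep = np.minimum(aud[a_idx], vis[v_idx])
        assert np.mean(anti) < np.mean(indep)


class TestRaceTest:
    def test_slow_bisensory_sample_is_not_significant(self, rng):
        aud = list(np.linspace(200, 350, 30))
        vis = list(np.linspace(220, 380, 30))
        p = make_participant(aud=aud, vis=vis, av={0: np.array(aud) + 200.0})
        res = race_test(p, 0, n_iter=400, rng=rng)
        assert not res.significant and res.p > 0.5

    def test_sparse_bisensory_sample_flagged_untestable(self, rng):
        av = np.concatenate([np.linspace(250, 300, 10), np.full(50, np.inf)])
        p = make_participant(av={0: av})
        res = race_test(p, 0, n_iter=100, rng=rng)
        assert res.untestable and not res.significant and res.p == 1.0

    def test_deterministic_given_rng_seed(self, participant):
        r1 = race_test(participant, 40, n_iter=200, rng=np.random.default_rng(7))
        r2 = race_test(participant, 40, n_iter=200, rng=np.random.default_rng(7))
        assert r1.d == r2.d and r1.p == r2.p

    def test_p_value_uses_add_one_convention(self, participant):
        res = race_test(participant, 0, n_iter=50, rng=np.random.default_rng(3))
        assert 1 / 51 <= res.p <= 1.0


class TestRtTwi:
    def _results(self, significant):
        from twindow.datasets import SOA_GRID

        return [
            RaceTestResult(s, -1.0, 0.01 if s in significant else 0.5, s in significant, 100, 0.05)
            for s in SOA_GRID
        ]

    def test_discontinuous_pattern_keeps_central_run(self):
        sig = {-40, -20, 0, 20, 40, 60, 80, 120}
        w = rt_twi(self._results(sig))
        assert (w.lower, w.upper) == (-40, 80)
        assert 120 not in w.members

    def test_no_significant_soa_gives_none(self):
        assert rt_twi(self._results(set())) is None

    def test_closest_run_to_zero_selected(self):
        w = rt_twi(self._results({100, 120}))
        assert (w.lower, w.upper) == (100, 120)

    def test_tie_breaks_to_positive_side(self):
        w = rt_twi(self._results({-120, -100, 100, 120}))
        assert (w.lower, w.upper) == (100, 120)


class TestGroupSignPermutation:
    def test_all_negative_eleven_participants(self):
        p = group_sign_permutation([-5.0] * 11)
        assert p == pytest.approx(1 / 2048)

    def test_single_participant(self):
        assert group_sign_permutation([-3.0]) == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration(self, rng):
        d = rng.normal(0, 10, 8)
        obs = d.sum() + 1e-9 * np.abs(d).sum()
        count = 0
        for signs in itertools.product((-1, 1), repeat=8):
            if float(np.dot(signs, d)) <= obs:
                count += 1
        assert group_sign_permutation(d) == pytest.approx(count / 2**8)

    def test_invariant_to_participant_order(self, rng):
        d = rng.normal(-2, 5, 9)
        assert group_sign_permutation(d) == group_sign_permutation(d[::-1])

    def test_nonfinite_d_is_an_error(self):
        with pytest.raises(ValueError):
            group_sign_permutation([1.0, np.inf])
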