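"""Kinetic-model unit tests: closed forms, master equation, stochastic oracle."""

import numpy as np
import pytest

from rhoterm import (
    ChainSpec,
    InvalidParameterError,
    NoCatchupError,
    RateParameters,
    TimeCourse,
    commitment_cdf,
    mean_commitment_time,
    mean_release_time,
    predict_termination_zone,
    sample_commitment_times,
    simulate_atp_trace,
    simulate_release_analytic,
    simulate_release_gillespie,
)


def params(**kw) -> RateParameters:
    base = dict(k_on=1.0, k_off=1.0, k_iso=1.0, k_step=1.0, k_dislodge=1.0)
    base.update(kw)
    return RateParameters(**base)


class TestMeanCommitmentTime:
    @pytest.mark.parametrize("kw, nusg, expected", [
        (dict(k_off=0.0), False, 2.0),           # two sequential unit-rate steps
        (dict(), False, 3.0),                     # reversible binding adds one cycle
        (dict(k_iso=5.0), False, 1.4),
    ])
    def test_closed_form(self, kw, nusg, expected):
        assert mean_commitment_time(params(**kw), nusg) == pytest.approx(expected)

    def test_nusg_multiplier_equals_direct_rate(self):
        # k_iso=0.05 with a 100x NusG boost is exactly the k_iso=5 chain
        boosted = params(k_iso=0.05, nusg_factor=100.0)
        direct = params(k_iso=5.0)
        assert mean_commitment_time(boosted, nusg=True) == \
            mean_commitment_time(direct, nusg=False)
        assert mean_commitment_time(boosted, nusg=True) == pytest.approx(1.4)

    def test_matches_stochastic_mean(self):
        p = params(k_on=0.7, k_off=2.0, k_iso=0.3)
        sample = sample_commitment_times(p, 100_000, seed=10)
        assert np.mean(sample) == pytest.approx(mean_commitment_time(p), rel=0.02)

    def test_multistage_mean_matches_sampler(self):
        p = params()
        for n in (2, 5):
            sample = sample_commitment_times(p, 100_000, seed=11, n_iso_stages=n)
            assert np.mean(sample) == pytest.approx(
                mean_commitment_time(p, n_iso_stages=n), rel=0.02)

    def test_monotone_in_k_iso_and_nusg(self):
        times = [mean_commitment_time(params(k_iso=k)) for k in (0.05, 0.5, 5.0)]
        assert times == sorted(times, reverse=True)
        factors = [mean_commitment_time(params(nusg_factor=f), nusg=True)
                   for f in (1.0, 10.0, 100.0)]
        assert factors == sorted(factors, reverse=True)

    @pytest.mark.parametrize("bad", [dict(k_on=0.0), dict(k_iso=-1.0),
                                     dict(k_off=-0.1), dict(nusg_factor=0.0)])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            params(**bad)


class TestReleaseAnalytic:
    def test_basic_shape(self):
        tc = simulate_release_analytic(params(), ChainSpec(3),
                                       np.linspace(0.0, 80.0, 200))
        assert tc.values[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(tc.values) >= -1e-9)
        assert tc.values[-1] > 0.999

    def test_hypoexponential_mean(self):
        # k_off=0, all rates 1, n_steps=3: stages 1+1+3+1 -> mean 6 s
        p = params(k_off=0.0)
        chain = ChainSpec(3)
        assert mean_release_time(p, chain) == pytest.approx(6.0)
        t = np.linspace(0.0, 80.0, 800)
        tc = simulate_release_analytic(p, chain, t)
        mean_from_curve = np.trapezoid(1.0 - tc.values, t)
        assert mean_from_curve == pytest.approx(6.0, rel=1e-3)
        _, sample = simulate_release_gillespie(p, chain, 10_000, seed=1)
        assert np.mean(sample) == pytest.approx(6.0, rel=0.05)

    def test_fast_isomerization_collapses_to_two_stage_chain(self):
        # k_iso >= 1e3 makes the iso stage invisible: binding + dislodge only
        p = params(k_off=0.0, k_iso=1e4)
        t = np.linspace(0.0, 30.0, 300)
        tc = simulate_release_analytic(p, ChainSpec(0), t)
        erlang2 = 1.0 - np.exp(-t) * (1.0 + t)  # two unit-rate stages
        assert np.max(np.abs(tc.values - erlang2)) < 1e-3

    def test_slow_isomerization_lag(self):
        p = params(k_iso=0.05)
        tc = simulate_release_analytic(p, ChainSpec(50), [5.0, 200.0])
        assert tc.values[0] < 0.05
        assert tc.values[1] > 0.9

    def test_invalid_chain(self):
        with pytest.raises(InvalidParameterError):
            ChainSpec(-1)
        with pytest.raises(InvalidParameterError):
            ChainSpec(0, n_iso_stages=0)


class TestGillespie:
    def test_seeded_determinism(self):
        p, chain = params(), ChainSpec(4)
        _, s1 = simulate_release_gillespie(p, chain, 500, seed=42)
        _, s2 = simulate_release_gillespie(p, chain, 500, seed=42)
        assert np.array_equal(s1, s2)

    def test_single_trajectory_is_step_function(self):
        tc, sample = simulate_release_gillespie(params(), ChainSpec(0), 1, seed=7)
        assert sample.shape == (1,)
        assert set(np.unique(tc.values)) <= {0.0, 1.0}

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_master_equation(self, seed):
        rng = np.random.default_rng(1000 + seed)
        p = RateParameters(k_on=rng.uniform(0.2, 2), k_off=rng.uniform(0, 2),
                           k_iso=rng.uniform(0.1, 2), k_step=rng.uniform(0.5, 3),
                           k_dislodge=rng.uniform(0.2, 2))
        chain = ChainSpec(int(rng.integers(0, 8)), int(rng.integers(1, 4)))
        horizon = 4.0 * mean_release_time(p, chain)
        t = np.linspace(horizon / 100, horizon, 100)
        analytic = simulate_release_analytic(p, chain, t)
        ecdf, _ = simulate_release_gillespie(p, chain, 10_000, seed=seed, times=t)
        assert np.max(np.abs(analytic.values - ecdf.values)) < 0.02

    def test_release_time_variance_is_hypoexponential(self):
        # k_off=0: variance = sum of 1/rate^2 over all stages
        p = params(k_off=0.0, k_step=2.0)
        chain = ChainSpec(3)
        expected = 1.0 + 1.0 + 3 * 0.25 + 1.0
        _, sample = simulate_release_gillespie(p, chain, 100_000, seed=5)
        assert np.var(sample) == pytest.approx(expected, rel=0.05)


class TestAtpTrace:
    def test_instant_commitment_linear_limit(self):
        # commitment immediate -> f(t) = min(1, 0.01 t); f(50) = 0.5
        p = params(k_on=1e5, k_iso=1e5, k_cat=0.01)
        tc = simulate_atp_trace(p, ChainSpec(0), np.linspace(0.5, 50.0, 100))
        assert tc.values[-1] == pytest.approx(0.5, rel=0.01)
        assert np.max(np.abs(tc.values - np.minimum(1.0, 0.01 * tc.times))) < 0.005

    def test_monotone_capped_and_zero_at_origin(self):
        tc = simulate_atp_trace(params(k_cat=0.5), ChainSpec(0),
                                np.linspace(0.0, 400.0, 100))
        assert tc.values[0] == 0.0
        assert np.all(np.diff(tc.values) >= -1e-12)
        assert np.all(tc.values <= 1.0)

    def test_lag_increases_as_isomerization_slows(self):
        # the linear asymptote of f extrapolates back to the mean commitment
        # time, so its x-intercept orders the lags
        t = np.linspace(0.0, 600.0, 300)

        def intercept(p):
            tc = simulate_atp_trace(p, ChainSpec(0), t)
            tail = tc.times > 300
            slope, icept = np.polyfit(tc.times[tail], tc.values[tail], 1)
            return -icept / slope

        slow = intercept(params(k_iso=0.05, k_cat=1e-3))
        fast = intercept(params(k_iso=5.0, k_cat=1e-3))
        assert slow > fast
        assert slow == pytest.approx(mean_commitment_time(params(k_iso=0.05)),
                                     rel=0.05)

    def test_nusg_equivalence(self):
        t = np.linspace(0.0, 100.0, 50)
        boosted = simulate_atp_trace(params(k_iso=0.05, nusg_factor=100.0),
                                     ChainSpec(0), t, nusg=True)
        direct = simulate_atp_trace(params(k_iso=5.0), ChainSpec(0), t)
        assert np.max(np.abs(boosted.values - direct.values)) < 1e-6


class TestTerminationZone:
    def test_mean_distance_closed_form(self):
        # E[T]=10 s, RNAP 20 nt/s, Rho 60 nt/s, instant dislodge -> 300 nt
        p = params(k_on=0.2, k_off=0.0, k_iso=0.2, k_dislodge=1e9)
        assert mean_commitment_time(p) == pytest.approx(10.0)
        pred = predict_termination_zone(p, 20.0, 60.0, n_traj=10_000, seed=3)
        assert pred.mean_analytic == pytest.approx(300.0, rel=1e-6)
        assert pred.mean_mc == pytest.approx(300.0, rel=0.05)
        assert np.all(pred.distances > 0)

    def test_no_catchup_error(self):
        with pytest.raises(NoCatchupError):
            predict_termination_zone(params(), 60.0, 60.0, seed=0)

    def test_slow_vs_fast_isomerization_distance_contrast(self):
        slow = predict_termination_zone(params(k_iso=0.05), 20.0, 60.0,
                                        n_traj=100, seed=0)
        fast = predict_termination_zone(params(k_iso=5.0), 20.0, 60.0,
                                        n_traj=100, seed=0)
        assert slow.mean_analytic / fast.mean_analytic > 3.0

    def test_mean_distance_monotone_in_k_iso_and_nusg(self):
        means = [predict_termination_zone(params(k_iso=k), 20.0, 60.0,
                                          n_traj=10, seed=0).mean_analytic
                 for k in np.geomspace(0.02, 20.0, 8)]
        assert np.all(np.diff(means) < 0)
        means_f = [predict_termination_zone(params(k_iso=0.05, nusg_factor=f),
                                            20.0, 60.0, n_traj=10, seed=0,
                                            nusg=True).mean_analytic
                   for f in (1.0, 10.0, 100.0)]
        assert np.all(np.diff(means_f) < 0)


class TestCommitmentCdf:
    def test_cdf_matches_sampler(self):
        p = params(k_iso=0.3)
        t = np.linspace(0.5, 30.0, 60)
        cdf = commitment_cdf(p, t, n_iso_stages=3)
        sample = sample_commitment_times(p, 50_000, seed=9, n_iso_stages=3)
        ecdf = np.searchsorted(np.sort(sample), t, side="right") / sample.size
        assert np.max(np.abs(cdf.values - ecdf)) < 0.01


class TestTimeCourse:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            TimeCourse(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            simulate_release_analytic(params(), ChainSpec(0), [])
        with pytest.raises(ValueError):
            simulate_release_analytic(params(), ChainSpec(0), [-1.0, 2.0])
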