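"""Simulator mechanics: signals, event scheduling, conservation, closed loop."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from hsckinetics.abm import (
    HYP1,
    HYP2_1,
    HYP2_2,
    PROG,
    ABMParams,
    SimState,
    SubtypeCycling,
    demand_signal,
    perturb,
    recovery_time,
    run_replicates,
    run_simulation,
    step,
)
from hsckinetics.synthetic import LT, ST


def _micro_params(**kwargs):
    """One LT agent, deterministic durations, no exit flux or noise."""
    defaults = dict(
        hypothesis=HYP2_2,
        target_pools={LT: 1, ST: 1, PROG: 10},
        cycling={
            LT: SubtypeCycling(14.2, 0.0, 30.0, 0.0),
            ST: SubtypeCycling(14.2, 0.0, 26.8, 0.0),
        },
        hsc_pool_exit_rate=0.0,
        noise=0.0,
        activation_rate=1e6,  # certain activation while the signal is on
        horizon_days=10.0,
    )
    defaults.update(kwargs)
    return ABMParams(**defaults)


class TestDemandSignal:
    def test_zero_at_target(self):
        params = ABMParams()
        state = SimState(params)
        sig = demand_signal(state, params, np.random.default_rng(0))
        assert sig[LT] == 0.0 and sig[ST] == 0.0

    def test_full_progenitor_deficit_saturates(self):
        params = ABMParams(noise=0.0)
        state = SimState(params)
        state.n_prog = 0
        sig = demand_signal(state, params, np.random.default_rng(0))
        assert sig[ST] == 1.0  # full downstream deficit, clamped at 1 before noise

    def test_noise_bound(self):
        """With 5% noise the signal stays within +-5% of its noiseless value."""
        params = ABMParams(noise=0.05)
        state = SimState(params)
        state.n_prog = 9000  # 10% progenitor deficit
        rng = np.random.default_rng(1)
        noiseless = 0.1
        draws = np.array([demand_signal(state, params, rng)[ST] for _ in range(10_000)])
        assert np.all(draws >= noiseless * 0.95 - 1e-12)
        assert np.all(draws <= noiseless * 1.05 + 1e-12)
        assert draws.min() < noiseless * 0.96 and draws.max() > noiseless * 1.04


class TestStepMechanics:
    def test_no_signal_no_divisions(self):
        params = _micro_params()
        state = SimState(params)
        rng = np.random.default_rng(0)
        for _ in range(480):
            step(state, params, rng, signals={LT: 0.0, ST: 0.0})
        assert state.cum_divisions[LT] == 0 and state.cum_divisions[ST] == 0

    def test_single_agent_deterministic_first_division(self):
        """HYP2.2, zero SDs, permanent signal: division at exit+delay+transit."""
        params = _micro_params()
        state = SimState(params)
        rng = np.random.default_rng(0)
        t_div = None
        for _ in range(200):
            step(state, params, rng, signals={LT: 1.0, ST: 0.0})
            if state.cum_divisions[LT] == 1:
                t_div = state.time
                break
        expected = 14.2 + 5.8 + 30.0
        assert t_div is not None
        assert abs(t_div - expected) <= params.dt + 1e-9
        assert state.pool(LT) == 2  # two quiescent daughters

    def test_event_list_matches_hand_computation(self):
        """Small-instance oracle: activation, commitment and division steps."""
        params = _micro_params(
            cycling={
                LT: SubtypeCycling(4.0, 0.0, 6.0, 0.0),
                ST: SubtypeCycling(4.0, 0.0, 6.0, 0.0),
            },
            lt_g0_exit_delay=0.0,
        )
        state = SimState(params)
        rng = np.random.default_rng(0)
        log = []
        for i in range(1, 25):
            step(state, params, rng, signals={LT: 1.0, ST: 0.0})
            log.append(
                (i, len(state.exiting[LT]), len(state.cycling_pipe[LT]),
                 state.cum_divisions[LT])
            )
        by_step = {i: rest for i, *rest in log}
        assert by_step[1] == [1, 0, 0]  # activated into the exit phase at t=0.5
        assert by_step[7] == [1, 0, 0]
        assert by_step[8] == [0, 1, 0]  # committed at t=4.0
        assert by_step[18] == [0, 1, 0]
        assert by_step[19] == [0, 0, 1]  # divided at t=9.5

    def test_abort_on_signal_withdrawal(self):
        """An exiting cell returns to quiescence when the signal drops to zero."""
        params = _micro_params()
        state = SimState(params)
        rng = np.random.default_rng(0)
        for _ in range(10):  # 5 hr of signal, shorter than the 20 hr exit
            step(state, params, rng, signals={LT: 1.0, ST: 0.0})
        assert len(state.exiting[LT]) == 1
        for _ in range(400):
            step(state, params, rng, signals={LT: 0.0, ST: 0.0})
        assert len(state.exiting[LT]) == 0
        assert state.n_q[LT] == 1
        assert state.cum_divisions[LT] == 0

    def test_hyp1_commits_where_hyp2_aborts(self):
        """A transient signal shorter than the exit phase divides under HYP1 only."""
        divisions = {}
        for hyp in (HYP1, HYP2_1):
            params = _micro_params(hypothesis=hyp)
            state = SimState(params)
            rng = np.random.default_rng(0)
            for i in range(300):
                sig = 1.0 if i < 10 else 0.0  # 5 hr window < 14.2 hr exit
                step(state, params, rng, signals={LT: sig, ST: 0.0})
            divisions[hyp] = state.cum_divisions[LT]
        assert divisions[HYP1] >= divisions[HYP2_1]
        assert divisions[HYP1] == 1 and divisions[HYP2_1] == 0


class TestRunSimulation:
    def test_zero_horizon(self):
        result = run_simulation(ABMParams(horizon_days=0.0), seed=0)
        assert len(result.times) == 1 and result.times[0] == 0.0

    def test_seed_determinism(self):
        p = ABMParams(horizon_days=30.0)
        a = run_simulation(p, seed=7)
        b = run_simulation(p, seed=7)
        assert np.array_equal(a.pools[LT], b.pools[LT])
        assert np.array_equal(a.cum_divisions[ST], b.cum_divisions[ST])
        c = run_simulation(p, seed=8)
        assert not np.array_equal(a.pools[LT], c.pools[LT])

    def test_conservation(self):
        """Cells appear only through division and leave only through the
        downstream demand or injury."""
        params = ABMParams(horizon_days=30.0, perturb_day=10.0)
        rng = np.random.default_rng(11)
        state = SimState(params)
        initial = state.total_cells()
        for i in range(int(30 * 48)):
            if i == 10 * 48:
                perturb(state, params.perturb_fraction, rng)
            step(state, params, rng)
        expected = (
            initial
            + state.cum_divisions[LT]
            + state.cum_divisions[ST]
            - state.cum_consumed
            - state.cum_perturbed
        )
        assert state.total_cells() == expected

    def test_pool_homeostasis_within_10pct(self):
        result = run_simulation(ABMParams(), seed=3)
        for comp, target in ((LT, 3360), (ST, 3360), (PROG, 10000)):
            assert abs(result.mean_pool(comp) - target) / target < 0.10

    def test_coarse_dt_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            ABMParams(dt=5.0).validate()


class TestReplicatesAndPerturbation:
    def test_replicates_validate_and_vary(self):
        with pytest.raises(ValueError):
            run_replicates(ABMParams(n_runs=1))
        summary = run_replicates(ABMParams(n_runs=4, horizon_days=60.0, seed=2))
        assert summary.n_runs == 4
        assert summary.divisions_per_year[LT].std(ddof=1) > 0.0
        assert np.all(summary.pool_sd[PROG] >= 0.0)

    def test_sampling_consistency(self):
        """Few-run and many-run means agree within 3 combined SEs."""
        p = ABMParams(horizon_days=120.0, seed=4)
        small = run_replicates(replace(p, n_runs=8)).divisions_per_year[LT]
        large = run_replicates(replace(p, n_runs=24)).divisions_per_year[LT]
        se = np.hypot(small.sem(), large.sem())
        assert abs(small.mean() - large.mean()) < 3 * se

    def test_perturb_arithmetic(self):
        params = ABMParams()
        state = SimState(params)
        rng = np.random.default_rng(0)
        assert perturb(state, 0.01, rng) == 100
        assert state.n_prog == 9900
        perturb(state, 1.0, rng)
        assert state.n_prog == 0
        assert perturb(state, 0.5, rng) == 0  # empty compartment: no-op
        with pytest.raises(ValueError):
            perturb(state, 0.0, rng)

    def test_closed_loop_returns_toward_target(self):
        """After eliminating 1% of progenitors the deficit shrinks again."""
        for hyp in (HYP1, HYP2_1, HYP2_2):
            p = ABMParams(
                hypothesis=hyp, perturb_day=10.0, horizon_days=120.0, seed=6
            )
            r = run_simulation(p, seed=13)
            prog = r.pools[PROG]
            t = r.times / 24.0
            dip = 10000 - prog[(t > 10) & (t < 12)].min()
            final_deficit = 10000 - np.mean(prog[t > 100])
            assert dip >= 80  # the injury is visible
            assert final_deficit < dip / 2  # and mostly healed by day 100

    def test_recovery_time_edge_cases(self):
        r = run_simulation(ABMParams(horizon_days=30.0), seed=1)
        assert recovery_time(r, PROG, 0.01)["recovery_hours"] == 0.0  # no injury
        rp = run_simulation(
            ABMParams(horizon_days=30.0, perturb_day=10.0), seed=1
        )
        out = recovery_time(rp, PROG, 1.0, target=10000)
        assert out["recovery_hours"] == 0.0  # an all-permissive band


class TestHypothesisDegeneracies:
    def test_zero_delay_reproduces_hyp21(self):
        """HYP2.2 with no delay is statistically identical to HYP2.1."""
        p = ABMParams(horizon_days=120.0, n_runs=24, seed=8)
        a = run_replicates(replace(p, hypothesis=HYP2_2, lt_g0_exit_delay=0.0))
        b = run_replicates(replace(p, hypothesis=HYP2_1, seed=9))
        res = stats.mannwhitneyu(
            a.divisions_per_year[LT], b.divisions_per_year[LT],
            alternative="two-sided",
        )
        assert res.pvalue > 0.01

    @pytest.mark.filterwarnings("ignore:dt=0.5 hr is coarse")
    def test_hyp1_matches_hyp21_with_vanishing_exit(self):
        """With a negligible exit phase the commitment point is immaterial."""
        cycling = {
            LT: SubtypeCycling(0.1, 0.0, 44.2, 6.0),
            ST: SubtypeCycling(0.1, 0.0, 40.9, 6.0),
        }
        p = ABMParams(
            cycling=cycling, lt_g0_exit_delay=0.0, horizon_days=120.0,
            n_runs=16, seed=10,
        )
        a = run_replicates(replace(p, hypothesis=HYP1))
        b = run_replicates(replace(p, hypothesis=HYP2_1, seed=11))
        res = stats.mannwhitneyu(
            a.divisions_per_year[LT], b.divisions_per_year[LT],
            alternative="two-sided",
        )
        assert res.pvalue > 0.01
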