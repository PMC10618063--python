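"""Exactness, determinism and classification of the stochastic simulator."""

import numpy as np
import pytest
from _oracles import truncated_me_distribution

from conftest import static_env
from coopamr.environment import EnvParams
from coopamr.model import Absorption, ModelParams
from coopamr.ssa import (
    Outcome,
    TruncatedSimulationError,
    classify_outcome,
    coexistence_equilibrium_init,
    default_horizon,
    run_ensemble,
    simulate,
)


@pytest.fixture(scope="module")
def small_params():
    return ModelParams(s=0.1, a=0.25, nth=10)


class TestSingleTrajectories:
    def test_already_absorbed_at_start(self, small_params):
        env = static_env(50)
        _, oc = simulate(small_params, env, (0, 50, 1), seed=0, horizon=10.0)
        assert oc.label is Absorption.S_FIXED
        assert oc.absorption_time == 0.0

    def test_same_seed_bitwise_identical(self, small_params):
        env = EnvParams(Kplus=200, Kminus=40, nu=0.5, delta=0.2)
        t1, o1 = simulate(small_params, env, (10, 30, 1), seed=123, horizon=50.0)
        t2, o2 = simulate(small_params, env, (10, 30, 1), seed=123, horizon=50.0)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.NR, t2.NR)
        assert np.array_equal(t1.xi, t2.xi)
        assert o1 == o2

    def test_event_log_invariants(self, small_params):
        """Strictly increasing times; successive records differ by exactly
        one event (one abundance +-1, or an environment flip)."""
        env = EnvParams(Kplus=200, Kminus=40, nu=0.5, delta=0.0)
        traj, _ = simulate(small_params, env, (10, 30, 1), seed=5, horizon=40.0)
        assert np.all(np.diff(traj.times) > 0)
        dnr = np.diff(traj.NR)
        dns = np.diff(traj.NS)
        dxi = np.diff(traj.xi)
        changed = (np.abs(dnr) + np.abs(dns) + (dxi != 0)).astype(int)
        assert np.all(changed == 1)
        assert traj.NR.min() >= 0 and traj.NS.min() >= 0

    def test_thinned_recording_keeps_switches(self, small_params):
        env = EnvParams(Kplus=200, Kminus=40, nu=1.0, delta=0.0)
        full, _ = simulate(small_params, env, (10, 30, 1), seed=9, horizon=30.0)
        thin, _ = simulate(
            small_params, env, (10, 30, 1), seed=9, horizon=30.0, record_interval=1.0
        )
        assert thin.times.size < full.times.size
        n_switches_full = np.sum(np.diff(full.xi) != 0)
        n_switches_thin = np.sum(np.diff(thin.xi) != 0)
        assert n_switches_thin == n_switches_full

    def test_event_guard_raises(self, small_params):
        env = static_env(100)
        with pytest.raises(TruncatedSimulationError):
            simulate(small_params, env, (10, 90, 1), seed=1, horizon=1e6, max_events=100)

    def test_population_tracks_capacity_after_fixation(self, small_params):
        """Composition absorbs but size keeps fluctuating with K(t)."""
        env = EnvParams(Kplus=200, Kminus=40, nu=0.2, delta=0.0)
        traj, oc = simulate(
            small_params,
            env,
            (3, 200, 1),
            seed=21,
            horizon=400.0,
            stop_at_absorption=False,
            record_interval=0.5,
        )
        assert oc.label in (Absorption.S_FIXED, Absorption.R_FIXED)
        post = traj.times > (oc.absorption_time + 20.0)
        assert post.sum() > 50
        mean_n = traj.N[post].mean()
        assert env.Kminus <= mean_n <= env.Kplus


class TestClassification:
    def test_reclassify_at_shorter_horizon(self, small_params):
        env = static_env(60)
        traj, oc = simulate(small_params, env, (2, 58, 1), seed=3, horizon=500.0)
        assert oc.absorption_time is not None
        early = classify_outcome(traj, horizon=oc.absorption_time / 2)
        assert early.label == Outcome.COEXISTENCE
        late = classify_outcome(traj, horizon=oc.absorption_time + 1)
        assert late.label == oc.label

    def test_extinction_is_its_own_label(self, small_params):
        env = static_env(2.0)
        # tiny capacity: total extinction is reachable and must not be
        # reported as fixation of the survivor
        labels = set()
        for seed in range(40):
            _, oc = simulate(
                small_params, env, (1, 1, 1), seed=seed, horizon=200.0,
                stop_at_absorption=False,
            )
            labels.add(oc.label)
        assert Absorption.EXTINCT in labels


class TestEnsembles:
    def test_single_rep_already_fixed(self, small_params):
        env = static_env(50)
        summ = run_ensemble(small_params, env, 1, seed_base=0, init=(50, 0, 1))
        assert summ.phi_R == 1.0

    def test_fractions_partition_unity(self, small_params):
        env = EnvParams(Kplus=100, Kminus=30, nu=0.1, delta=0.0)
        summ = run_ensemble(small_params, env, 100, seed_base=4)
        assert summ.phi_R + summ.phi_S + summ.p_coex + summ.p_extinct == pytest.approx(1.0)
        assert sum(summ.counts.values()) == 100

    def test_near_neutral_fixation_matches_n0_over_K0(self):
        """With vanishing selection the fixation probability reduces to the
        classical neutral n0/K0."""
        p = ModelParams(s=1e-7, a=2e-7, nth=5)
        env = static_env(30)
        n0, n_reps = 10, 800
        summ = run_ensemble(p, env, n_reps, seed_base=8, horizon=1e6, init=(n0, 20, 1))
        expected = n0 / 30
        se = np.sqrt(expected * (1 - expected) / n_reps)
        assert abs(summ.phi_R - expected) < 3 * se

    def test_default_init_rule(self, small_params):
        env = EnvParams(Kplus=200, Kminus=40, nu=0.5, delta=0.0)
        rng = np.random.Generator(np.random.MT19937(0))
        nr0, ns0, xi0 = coexistence_equilibrium_init(small_params, env, rng)
        assert nr0 == small_params.nth
        assert nr0 + ns0 == int(round(env.capacity(xi0)))
        assert default_horizon(env) == pytest.approx(2 * env.mean_K)


class TestMasterEquationExactness:
    def test_state_distribution_matches_truncated_me(self):
        """The empirical (NR, NS) law at an early time matches direct
        integration of the truncated master equation (total variation)."""
        p = ModelParams(s=0.2, a=0.5, nth=4)
        K0 = 8.0
        env = static_env(K0)
        t_snap, n_cap, n_reps = 1.5, 28, 20000
        me = truncated_me_distribution(p, K0, (3, 3), t_snap, n_cap)
        summ = run_ensemble(
            p, env, n_reps, seed_base=17, horizon=t_snap,
            init=(3, 3, 1), stop_at_absorption=False,
        )
        emp: dict[tuple[int, int], float] = {}
        for nr, ns in zip(summ.final_NR, summ.final_NS):
            emp[(nr, ns)] = emp.get((nr, ns), 0.0) + 1.0 / n_reps
        keys = set(me) | set(emp)
        tv = 0.5 * sum(abs(me.get(k, 0.0) - emp.get(k, 0.0)) for k in keys)
        assert tv < 0.05
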