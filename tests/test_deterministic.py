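"""Mean-field/PDMP integration and transient-dip analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopamr.deterministic import (
    InvalidRegimeError,
    dip_minimum,
    dip_time,
    integrate_mean_field,
    integrate_pdmp,
    large_population_criterion,
    optimal_eradication_region,
)
from coopamr.environment import EnvParams, EnvPath, effective_carrying_capacities
from coopamr.model import ModelParams


@pytest.fixture(scope="module")
def params():
    return ModelParams(s=0.1, a=0.25, nth=80)


@pytest.fixture(scope="module")
def env(params):
    return EnvParams(Kplus=1000, Kminus=120, nu=0.1, delta=0.0)


class TestMeanField:
    def test_capacity_is_fixed_point(self, params):
        path = integrate_mean_field(params, 500.0, (500.0, 0.05), 20.0)
        assert np.allclose(path.N, 500.0, rtol=1e-6)

    def test_logistic_closed_form(self, params):
        K0, N0 = 500.0, 50.0
        path = integrate_mean_field(params, K0, (N0, 0.05), 10.0)
        closed = K0 * N0 * np.exp(path.t) / (K0 + N0 * (np.exp(path.t) - 1))
        assert np.max(np.abs(path.N - closed) / closed) < 1e-6

    def test_composition_moves_towards_threshold(self, params):
        """x rises while NR < Nth and falls while NR > Nth."""
        up = integrate_mean_field(params, 1000.0, (1000.0, 0.02), 5.0)  # NR0=20
        assert up.x[-1] > up.x[0]
        down = integrate_mean_field(params, 1000.0, (1000.0, 0.5), 5.0)  # NR0=500
        assert down.x[-1] < down.x[0]

    def test_converges_to_coexistence_equilibrium(self, params):
        path = integrate_mean_field(params, 400.0, (400.0, 0.05), 200.0)
        assert path.NR[-1] == pytest.approx(params.nth, rel=1e-6)
        assert path.x[-1] == pytest.approx(params.nth / 400.0, rel=1e-6)

    def test_timescale_separation(self):
        """N relaxes on a ~1 time scale, x on the much slower ~1/s scale."""
        p = ModelParams(s=0.05, a=0.12, nth=100)
        path = integrate_mean_field(p, 1000.0, (100.0, 0.02), 8.0)
        at6 = np.searchsorted(path.t, 6.0)
        assert abs(path.N[at6] - 1000.0) / 1000.0 < 0.05
        x_eq = p.nth / 1000.0
        assert abs(path.x[at6] - x_eq) / x_eq > 0.5

    def test_invalid_initial_conditions(self, params):
        with pytest.raises(ValueError):
            integrate_mean_field(params, 100.0, (0.0, 0.5), 1.0)
        with pytest.raises(ValueError):
            integrate_mean_field(params, 100.0, (50.0, 1.5), 1.0)


class TestPdmp:
    def test_no_switches_reduces_to_mean_field(self, params, env):
        path_env = EnvPath(xi0=1, switch_times=np.array([]), t_end=30.0)
        pdmp = integrate_pdmp(params, env, (500.0, 0.1, 1), 30.0, env_path=path_env)
        mf = integrate_mean_field(params, env.Kplus, (500.0, 0.1), 30.0)
        # compare on common interpolation grid
        grid = np.linspace(0.5, 29.5, 50)
        n_p = np.interp(grid, pdmp.t, pdmp.N)
        n_m = np.interp(grid, mf.t, mf.N)
        assert np.allclose(n_p, n_m, rtol=1e-6)

    def test_tracks_switching_capacity(self, params, env):
        """N relaxes to K(t) after each switch; x heads towards Nth/N."""
        path_env = EnvPath(xi0=1, switch_times=np.array([20.0, 45.0]), t_end=70.0)
        pdmp = integrate_pdmp(params, env, (1000.0, 0.08, 1), 70.0, env_path=path_env)
        at = lambda t: np.searchsorted(pdmp.t, t)
        assert pdmp.N[at(19.9)] == pytest.approx(env.Kplus, rel=1e-3)
        assert pdmp.N[at(44.0)] == pytest.approx(env.Kminus, rel=1e-2)
        assert pdmp.N[at(69.9)] == pytest.approx(env.Kplus, rel=1e-2)
        assert pdmp.xi[at(30.0)] == -1

    def test_fast_switching_effective_capacity(self, params, env):
        """Mean-field surrogate at Kbar: stationary N equals the harmonic
        effective capacity of the fast-switching limit."""
        kbar, _ = effective_carrying_capacities(env)
        mf = integrate_mean_field(params, kbar, (kbar / 2, 0.3), 50.0)
        assert mf.N[-1] == pytest.approx(kbar, rel=1e-6)


class TestDipAnalytics:
    def test_dip_time_hand_value(self, params, env):
        assert dip_time(params, env) == pytest.approx(math.log(5.28), rel=1e-12)

    def test_dip_time_deep_bottleneck_limit(self, params):
        env_deep = EnvParams(Kplus=1e9, Kminus=1.0, nu=0.1)
        expected = math.log((1 - params.s) / (params.a - params.s))
        assert dip_time(params, env_deep) == pytest.approx(expected, rel=1e-6)

    def test_invalid_regimes(self, params):
        with pytest.raises(InvalidRegimeError):
            dip_time(params, EnvParams(Kplus=100, Kminus=100, nu=0.1))
        # shallow bottleneck: ln argument <= 1, no dip
        shallow = ModelParams(s=0.1, a=0.95, nth=10)
        with pytest.raises(InvalidRegimeError):
            dip_time(shallow, EnvParams(Kplus=100, Kminus=99, nu=0.1))

    def test_dip_minimum_hand_values(self, params, env):
        dip = dip_minimum(params, env)
        assert dip.NR_dip == pytest.approx(16.49, abs=0.01)
        assert dip.lower_bound == pytest.approx(9.6)
        assert dip.N_at_dip == pytest.approx(144.0)
        assert not dip.eradication_feasible  # 16.5 > 10
        assert dip_minimum(params, env, o1_threshold=20).eradication_feasible

    @settings(max_examples=100, derandomize=True)
    @given(
        s=st.floats(0.02, 0.3),
        gap=st.floats(0.05, 0.4),
        nth=st.integers(5, 200),
        ratio=st.floats(2.0, 100.0),
    )
    def test_dip_bounded_below(self, s, gap, nth, ratio):
        a = min(s + gap, 0.9)
        p = ModelParams(s=s, a=a, nth=nth)
        env = EnvParams(Kplus=100.0 * ratio, Kminus=100.0, nu=0.1)
        try:
            dip = dip_minimum(p, env)
        except InvalidRegimeError:
            return
        assert dip.NR_dip >= dip.lower_bound - 1e-9
        if ratio >= 8.0:
            # the closed form only describes a genuine dip for deep bottlenecks
            assert dip.NR_dip < p.nth

    def test_dip_deepens_with_capacity_contrast(self, params):
        dips = [
            dip_minimum(params, EnvParams(Kplus=kp, Kminus=120.0, nu=0.1)).NR_dip
            for kp in (600.0, 1000.0, 3000.0, 10000.0)
        ]
        assert np.all(np.diff(dips) < 0)

    def test_numeric_dip_matches_formulas(self, params, env):
        """Relax on the mild capacity, bottleneck to the harsh one, and
        compare the numeric PDMP dip with the closed forms."""
        t_sw = 40.0
        path_env = EnvPath(xi0=1, switch_times=np.array([t_sw]), t_end=t_sw + 15.0)
        pdmp = integrate_pdmp(
            params, env, (env.Kplus, params.nth / env.Kplus, 1),
            t_sw + 15.0, env_path=path_env, dt=0.005,
        )
        after = pdmp.t >= t_sw
        i = int(np.argmin(pdmp.NR[after]))
        t_num = pdmp.t[after][i] - t_sw
        nr_num = pdmp.NR[after][i]
        n_num = pdmp.N[after][i]
        dip = dip_minimum(params, env)
        assert t_num == pytest.approx(dip.t_dip, rel=0.10)
        assert nr_num == pytest.approx(dip.NR_dip, rel=0.15)
        assert n_num == pytest.approx(dip.N_at_dip, rel=0.10)


class TestEradicationRegion:
    def test_hand_worked_bounds(self, params, env):
        region = optimal_eradication_region(params, env)
        L = math.log(env.Kplus / env.Kminus)
        assert region.mild_bounds[0] == pytest.approx(0.1 / (2 * L), rel=1e-12)
        assert region.mild_bounds == (pytest.approx(0.02358, abs=2e-5), pytest.approx(0.1))
        assert region.harsh_bounds[0] == pytest.approx(0.03537, abs=2e-5)
        assert region.harsh_bounds[1] == pytest.approx(1 / dip_time(params, env))
        assert region.nonempty

    def test_membership(self, params, env):
        region = optimal_eradication_region(params, env)
        assert region.membership(0.05, 0.0)
        assert not region.membership(0.05, 0.999)  # nu(1-delta) below lower bound
        assert not region.membership(1e-4, 0.0)
        assert not region.membership(100.0, 0.0)
        grid = region.membership(np.array([1e-4, 0.05, 100.0]), np.array([0.0, 0.0, 0.0]))
        assert list(grid) == [False, True, False]

    def test_large_population_criterion(self, env):
        value, ok = large_population_criterion(ModelParams(s=0.1, a=0.25, nth=80), env)
        assert value == pytest.approx(9.6) and ok
        value2, ok2 = large_population_criterion(ModelParams(s=0.1, a=0.25, nth=100), env)
        assert value2 == pytest.approx(12.0) and not ok2
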