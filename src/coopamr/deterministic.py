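"""Mean-field and piecewise-deterministic (PDMP) dynamics, dip analytics.

In the infinite-population limit the model reduces to

    dN/dt  = N (1 - N/K(t))
    dNR/dt = NR ((1-s)/fbar - N/K(t)),   fbar = ((1-s) NR + f_S (N-NR)) / N

with ``f_S`` jumping at the cooperation threshold ``NR = Nth`` (below: 1-a,
at/above: 1).  The right-hand side is discontinuous there and, near the
carrying capacity, both branches point *towards* the threshold: the
composition sits on a sliding equilibrium ``NR = Nth`` (x = Nth/N).  The
integrator therefore alternates between free flow in either branch and an
explicit sliding mode (NR pinned at Nth, N logistic), entering and leaving
the surface through event detection.  Between environmental switches the
flow is deterministic, so a PDMP trajectory is a concatenation of such
segments with K jumping at switch times.

After a bottleneck (K+ -> K-), sliding cannot be maintained — the surface
collapses faster than selection can track it — and NR undergoes a transient
dip whose depth and timing admit closed forms:

    t_dip  ~= ln[ (1-s)/(a-s) * (1 - K-/K+) ]
    NR_dip ~= Nth (K-/K+) ((1-s)/(1-a)) ((1-s)/(a-s))^((a-s)/(1-a))

Dips reaching NR_dip = O(1)-O(10) expose resistance to demographic
extinction; the optimal-eradication-region criterion bounds the switching
statistics (nu, delta) for which such dips recur without starving the
sensitive strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .environment import EnvParams, EnvPath, sample_dmn_path
from .model import ModelParams

__all__ = [
    "DeterministicPath",
    "DipCharacteristics",
    "EradicationRegion",
    "InvalidRegimeError",
    "integrate_mean_field",
    "integrate_pdmp",
    "dip_time",
    "dip_minimum",
    "alpha_R",
    "optimal_eradication_region",
    "large_population_criterion",
]


class InvalidRegimeError(ValueError):
    """Parameters outside the regime where the requested quantity exists."""


@dataclass(frozen=True)
class DeterministicPath:
    """Continuous path of (N, x) (plus xi for PDMP runs)."""

    t: np.ndarray = field(repr=False)
    N: np.ndarray = field(repr=False)
    NR: np.ndarray = field(repr=False)
    xi: np.ndarray | None = field(default=None, repr=False)

    @property
    def x(self) -> np.ndarray:
        return self.NR / self.N

    def to_records(self) -> np.ndarray:
        cols = [self.t, self.N, self.x, self.NR]
        if self.xi is not None:
            cols.append(self.xi)
        return np.column_stack(cols)


def _dnr(N: float, NR: float, s: float, a: float, K: float, fs: float) -> float:
    fbar = ((1.0 - s) * NR + fs * (N - NR)) / N
    return NR * ((1.0 - s) / fbar - N / K)


def _integrate_const_K(
    params: ModelParams,
    K: float,
    N0: float,
    NR0: float,
    t0: float,
    t1: float,
    rtol: float,
    dt: float,
):
    """Hybrid (free/sliding) integration at fixed K on [t0, t1].

    Returns (ts, Ns, NRs, N_end, NR_end); samples lie on a uniform grid of
    step dt plus segment endpoints.
    """
    s, a, nth = params.s, params.a, float(params.nth)
    eps = 1e-9 * max(1.0, nth)
    atol = rtol * max(1.0, K) * 1e-2

    ts_out: list[np.ndarray] = []
    ns_out: list[np.ndarray] = []
    nrs_out: list[np.ndarray] = []

    def fs_of(below: bool) -> float:
        return 1.0 - a if below else 1.0

    t, N, NR = t0, N0, NR0
    for _ in range(10000):
        if t >= t1 - 1e-12:
            break
        on_surface = abs(NR - nth) <= eps and NR > 0
        if on_surface:
            db = _dnr(N, nth, s, a, K, 1.0 - a)
            da = _dnr(N, nth, s, a, K, 1.0)
            sliding = db >= 0.0 >= da
        else:
            sliding = False

        if sliding:
            # NR pinned at Nth; leave when either one-sided field stops
            # pointing at the surface.
            def ev_below(tt, y):
                return _dnr(y[0], nth, s, a, K, 1.0 - a)

            def ev_above(tt, y):
                return _dnr(y[0], nth, s, a, K, 1.0)

            ev_below.terminal = True
            ev_below.direction = -1.0
            ev_above.terminal = True
            ev_above.direction = 1.0
            grid = np.arange(t, t1, dt)
            sol = solve_ivp(
                lambda tt, y: [y[0] * (1.0 - y[0] / K)],
                (t, t1),
                [N],
                events=(ev_below, ev_above),
                t_eval=grid[grid > t],
                rtol=rtol,
                atol=atol,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(f"slide integration failed at t={t}: {sol.message}")
            ts_out.append(sol.t)
            ns_out.append(sol.y[0])
            nrs_out.append(np.full(sol.t.size, nth))
            if sol.status == 1:  # event: leave the surface
                te = sol.t_events[0][0] if sol.t_events[0].size else sol.t_events[1][0]
                Ne = sol.y_events[0][0][0] if sol.t_events[0].size else sol.y_events[1][0][0]
                left_down = sol.t_events[0].size > 0
                t, N = float(te), float(Ne)
                NR = nth - eps if left_down else nth + eps
            else:
                t = t1
                N = float(sol.y[0][-1]) if sol.t.size else N
                NR = nth
                # endpoint value regardless of grid coverage
                end = solve_ivp(
                    lambda tt, y: [y[0] * (1.0 - y[0] / K)],
                    (sol.t[-1] if sol.t.size else t0, t1),
                    [N],
                    rtol=rtol,
                    atol=atol,
                )
                N = float(end.y[0][-1])
        else:
            below = NR < nth or (abs(NR - nth) <= eps and _dnr(N, nth, s, a, K, 1.0 - a) < 0)
            fs = fs_of(below)

            def rhs(tt, y):
                NN, NNR = y
                fbar = ((1.0 - s) * NNR + fs * (NN - NNR)) / NN
                return [NN * (1.0 - NN / K), NNR * ((1.0 - s) / fbar - NN / K)]

            def cross(tt, y):
                return y[1] - nth

            cross.terminal = True
            cross.direction = 1.0 if below else -1.0
            grid = np.arange(t, t1, dt)
            sol = solve_ivp(
                rhs,
                (t, t1),
                [N, NR],
                events=(cross,),
                t_eval=grid[grid > t],
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(f"free integration failed at t={t}: {sol.message}")
            ts_out.append(sol.t)
            ns_out.append(sol.y[0])
            nrs_out.append(sol.y[1])
            if sol.status == 1:
                t = float(sol.t_events[0][0])
                N = float(sol.y_events[0][0][0])
                NR = nth  # on the surface; next pass decides slide or crossing
            else:
                end = solve_ivp(rhs, (t, t1), [N, NR], rtol=rtol, atol=atol)
                t = t1
                N = float(end.y[0][-1])
                NR = float(end.y[1][-1])
    else:
        raise RuntimeError("threshold chattering: segment limit exceeded")

    if ts_out:
        ts = np.concatenate(ts_out)
        Ns = np.concatenate(ns_out)
        NRs = np.concatenate(nrs_out)
    else:
        ts = np.empty(0)
        Ns = np.empty(0)
        NRs = np.empty(0)
    return ts, Ns, NRs, N, NR


def integrate_mean_field(
    params: ModelParams,
    K0: float,
    init: tuple[float, float],
    t_end: float,
    *,
    rtol: float = 1e-8,
    dt: float = 0.01,
) -> DeterministicPath:
    """Deterministic dynamics at constant carrying capacity K0.

    ``init = (N0, x0)`` with N0 > 0 and x0 in [0, 1].  N follows the closed
    logistic form towards K0; x converges to the coexistence equilibrium
    x_th = Nth/N (pinned by the sliding mode once reached).
    """
    N0, x0 = init
    if N0 <= 0:
        raise ValueError(f"N0 must be positive, got {N0}")
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0 must lie in [0, 1], got {x0}")
    ts, Ns, NRs, N_end, NR_end = _integrate_const_K(
        params, float(K0), N0, x0 * N0, 0.0, float(t_end), rtol, dt
    )
    ts = np.concatenate([[0.0], ts, [t_end]])
    Ns = np.concatenate([[N0], Ns, [N_end]])
    NRs = np.concatenate([[x0 * N0], NRs, [NR_end]])
    return DeterministicPath(t=ts, N=Ns, NR=NRs)


def integrate_pdmp(
    params: ModelParams,
    env: EnvParams,
    init: tuple[float, float, int],
    t_end: float,
    *,
    env_path: EnvPath | None = None,
    seed: int | None = None,
    rtol: float = 1e-8,
    dt: float = 0.01,
) -> DeterministicPath:
    """Piecewise-deterministic dynamics under a switching carrying capacity.

    ``init = (N0, x0, xi0)``.  Provide either an explicit ``env_path``
    (fully deterministic output) or a ``seed`` to draw one; with no
    switches in the path the result coincides with ``integrate_mean_field``
    at K(xi0).
    """
    N0, x0, xi0 = init
    if env_path is None:
        if seed is None:
            raise ValueError("provide either env_path or seed")
        rng = np.random.Generator(np.random.MT19937(seed))
        env_path = sample_dmn_path(env, t_end, rng, xi0=xi0)
    if env_path.xi0 != xi0:
        raise ValueError("env_path.xi0 disagrees with init")

    switches = env_path.switch_times[env_path.switch_times < t_end]
    bounds = np.concatenate([[0.0], switches, [t_end]])
    ts_all = [np.array([0.0])]
    ns_all = [np.array([N0])]
    nrs_all = [np.array([x0 * N0])]
    xi_all = [np.array([xi0])]

    N, NR, xi = float(N0), float(x0) * float(N0), int(xi0)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        K = env.capacity(xi)
        ts, Ns, NRs, N, NR = _integrate_const_K(params, K, N, NR, float(t0), float(t1), rtol, dt)
        ts = np.concatenate([ts, [t1]])
        Ns = np.concatenate([Ns, [N]])
        NRs = np.concatenate([NRs, [NR]])
        ts_all.append(ts)
        ns_all.append(Ns)
        nrs_all.append(NRs)
        xi_all.append(np.full(ts.size, xi))
        xi = -xi

    return DeterministicPath(
        t=np.concatenate(ts_all),
        N=np.concatenate(ns_all),
        NR=np.concatenate(nrs_all),
        xi=np.concatenate(xi_all),
    )


def alpha_R(N: float, K: float, params: ModelParams) -> float:
    """Instantaneous growth factor of the below-threshold R dynamics,
    ``alpha_R = ((1-s)K - (1-a)N) / ((a-s)K)``; the dip bottom sits where
    alpha_R ~ NR/K ~ 0."""
    return ((1.0 - params.s) * K - (1.0 - params.a) * N) / ((params.a - params.s) * K)


def _check_dip_regime(params: ModelParams, env: EnvParams) -> float:
    if env.Kminus >= env.Kplus:
        raise InvalidRegimeError("a transient dip requires K- < K+")
    arg = (1.0 - params.s) / (params.a - params.s) * (1.0 - env.Kminus / env.Kplus)
    if arg <= 1.0:
        raise InvalidRegimeError(
            f"no dip in this regime: ln argument {arg:.4g} <= 1"
        )
    return arg


def dip_time(params: ModelParams, env: EnvParams) -> float:
    """Time from a K+ -> K- switch to the bottom of the resistant dip,
    ``t_dip = ln[(1-s)/(a-s) (1 - K-/K+)]``, starting from N ~ K+."""
    return math.log(_check_dip_regime(params, env))


@dataclass(frozen=True)
class DipCharacteristics:
    """Closed-form transient-dip summary (continuum, NR(0) = Nth)."""

    t_dip: float
    NR_dip: float
    lower_bound: float
    alpha_R_at_dip: float
    N_at_dip: float
    eradication_feasible: bool


def dip_minimum(
    params: ModelParams, env: EnvParams, *, o1_threshold: float = 10.0
) -> DipCharacteristics:
    """Resistant abundance at the bottom of the dip after a bottleneck.

    ``NR_dip = Nth (K-/K+) ((1-s)/(1-a)) ((1-s)/(a-s))^((a-s)/(1-a))``,
    bounded below by ``Nth K-/K+``.  Fluctuation-driven eradication is
    flagged feasible when NR_dip falls at or below ``o1_threshold``
    (demographic noise of order sqrt(NR_dip) can then reach zero).
    """
    tdip = dip_time(params, env)
    s, a = params.s, params.a
    ratio = env.Kminus / env.Kplus
    nr_dip = (
        params.nth
        * ratio
        * ((1.0 - s) / (1.0 - a))
        * ((1.0 - s) / (a - s)) ** ((a - s) / (1.0 - a))
    )
    n_at_dip = env.Kminus * (1.0 - s) / (1.0 - a)
    return DipCharacteristics(
        t_dip=tdip,
        NR_dip=nr_dip,
        lower_bound=params.nth * ratio,
        alpha_R_at_dip=alpha_R(n_at_dip, env.Kminus, params),
        N_at_dip=n_at_dip,
        eradication_feasible=nr_dip <= o1_threshold,
    )


@dataclass(frozen=True)
class EradicationRegion:
    """Bounds on nu(1-delta) and nu(1+delta) for optimal R eradication.

    The four conditions: the mild phase must last long enough for R to
    regrow to Nth (nu(1-delta) <= s) but cycle fast (>= s/(2 ln(K+/K-)));
    the harsh phase must outlast the dip (nu(1+delta) <= 1/t_dip) yet stay
    short enough to spare S (>= (a-s)/(2 ln(K+/K-))).
    """

    mild_bounds: tuple[float, float]  # on nu*(1-delta)
    harsh_bounds: tuple[float, float]  # on nu*(1+delta)
    nonempty: bool

    def membership(self, nu, delta):
        """Vectorised predicate: is (nu, delta) inside the region?"""
        nu = np.asarray(nu, dtype=float)
        delta = np.asarray(delta, dtype=float)
        p_mild = nu * (1.0 - delta)
        p_harsh = nu * (1.0 + delta)
        inside = (
            (self.mild_bounds[0] <= p_mild)
            & (p_mild <= self.mild_bounds[1])
            & (self.harsh_bounds[0] <= p_harsh)
            & (p_harsh <= self.harsh_bounds[1])
        )
        return inside if inside.ndim else bool(inside)


def optimal_eradication_region(params: ModelParams, env: EnvParams) -> EradicationRegion:
    """Interval constraints on the switching statistics for fast eradication."""
    tdip = dip_time(params, env)
    L = math.log(env.Kplus / env.Kminus)
    mild = (params.s / (2.0 * L), params.s)
    harsh = ((params.a - params.s) / (2.0 * L), 1.0 / tdip)
    return EradicationRegion(
        mild_bounds=mild,
        harsh_bounds=harsh,
        nonempty=(mild[0] < mild[1]) and (harsh[0] < harsh[1]),
    )


def large_population_criterion(
    params: ModelParams, env: EnvParams, *, threshold: float = 10.0
) -> tuple[float, bool]:
    """Transferability to large populations: ``Nth K-/K+`` and whether it is
    at or below ``threshold`` (dips then still graze O(1) abundances
    regardless of overall scale)."""
    value = params.nth * env.Kminus / env.Kplus
    return value, value <= threshold
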