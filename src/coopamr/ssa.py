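"""Exact stochastic simulation of the coupled demographic/environmental model.

`simulate` draws one statistically exact sample path of the master equation
(four birth/death channels plus environmental switching), `classify_outcome`
applies the fixation/coexistence/extinction rule at a finite horizon, and
`run_ensemble` estimates fixation and coexistence probabilities over
replicates with binomial confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import _kernel
from .environment import EnvParams, draw_stationary_xi
from .model import Absorption, ModelParams

__all__ = [
    "Trajectory",
    "Outcome",
    "EnsembleSummary",
    "TruncatedSimulationError",
    "simulate",
    "classify_outcome",
    "run_ensemble",
    "coexistence_equilibrium_init",
    "default_horizon",
]


class TruncatedSimulationError(RuntimeError):
    """The event-count guard was exceeded before absorption or horizon."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped sample path of (NR, NS, xi) with run metadata."""

    times: np.ndarray = field(repr=False)
    NR: np.ndarray = field(repr=False)
    NS: np.ndarray = field(repr=False)
    xi: np.ndarray = field(repr=False)
    params: ModelParams
    env: EnvParams
    seed: int
    horizon: float
    n_events: int
    truncated: bool

    @property
    def N(self) -> np.ndarray:
        return self.NR + self.NS

    @property
    def K(self) -> np.ndarray:
        return np.where(self.xi == 1, self.env.Kplus, self.env.Kminus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "NR": self.NR, "NS": self.NS, "xi": self.xi, "K": self.K}
        )

    def write(self, path: str) -> None:
        """Write the path as TSV with a JSON metadata sidecar."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "model": {"s": self.params.s, "a": self.params.a, "nth": self.params.nth},
            "env": {
                "Kplus": self.env.Kplus,
                "Kminus": self.env.Kminus,
                "nu": self.env.nu,
                "delta": self.env.delta,
            },
            "seed": int(self.seed),
            "horizon": self.horizon,
            "n_events": self.n_events,
            "truncated": self.truncated,
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass(frozen=True)
class Outcome:
    """Terminal classification of a replicate."""

    label: Absorption | str
    absorption_time: float | None
    final_NR: int
    final_NS: int
    final_xi: int
    horizon: float

    COEXISTENCE = "coexistence"


def default_horizon(env: EnvParams) -> float:
    """Default coexistence horizon 2<K> (twice the stationary mean capacity)."""
    return 2.0 * env.mean_K


def coexistence_equilibrium_init(
    params: ModelParams, env: EnvParams, rng: np.random.Generator, xi0: int | None = None
) -> tuple[int, int, int]:
    """Default ensemble start: stationary environment, N0 = K(xi0), and the
    composition at the coexistence equilibrium (NR0 = Nth, capped at N0-1 so
    both strains are present)."""
    if xi0 is None:
        xi0 = draw_stationary_xi(env, rng)
    n0 = int(round(env.capacity(xi0)))
    nr0 = min(params.nth, n0 - 1)
    return nr0, n0 - nr0, xi0


def _resolve_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


def simulate(
    params: ModelParams,
    env: EnvParams,
    init: tuple[int, int, int],
    seed: int,
    horizon: float,
    *,
    stop_at_absorption: bool = True,
    max_events: int = 200_000_000,
    record: bool = True,
    record_interval: float = 0.0,
    record_cap: int = 2_000_000,
) -> tuple[Trajectory, Outcome]:
    """Simulate one replicate from ``init = (NR0, NS0, xi0)``.

    The same seed and inputs reproduce the trajectory bit for bit.  With
    ``record_interval > 0`` the stored path is thinned to switching events
    plus a uniform time grid; 0 stores every event (subject to
    ``record_cap``).  Exceeding ``max_events`` raises
    :class:`TruncatedSimulationError` — never a silent truncation.
    """
    nr0, ns0, xi0 = init
    if nr0 < 0 or ns0 < 0 or xi0 not in (-1, 1):
        raise ValueError(f"invalid initial condition {init}")
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    cap = record_cap if record else 0
    rec_t = np.empty(cap, dtype=np.float64)
    rec_nr = np.empty(cap, dtype=np.int64)
    rec_ns = np.empty(cap, dtype=np.int64)
    rec_xi = np.empty(cap, dtype=np.int64)
    out = _kernel.gillespie_core(
        nr0,
        ns0,
        xi0,
        params.s,
        params.a,
        params.nth,
        float(env.Kplus),
        float(env.Kminus),
        env.nu_plus,
        env.nu_minus,
        float(horizon),
        _resolve_seed(seed),
        stop_at_absorption,
        max_events,
        float(record_interval),
        rec_t,
        rec_nr,
        rec_ns,
        rec_xi,
    )
    t, nr, ns, xi, ab_t, ab_nr, ab_ns, n_events, truncated, n_rec = out
    if truncated:
        raise TruncatedSimulationError(
            f"event-count guard ({max_events}) exceeded at t={t:.3g}"
        )
    traj = Trajectory(
        times=rec_t[:n_rec].copy(),
        NR=rec_nr[:n_rec].copy(),
        NS=rec_ns[:n_rec].copy(),
        xi=rec_xi[:n_rec].copy(),
        params=params,
        env=env,
        seed=seed,
        horizon=horizon,
        n_events=int(n_events),
        truncated=bool(truncated),
    )
    outcome = _classify(ab_t, ab_nr, ab_ns, int(nr), int(ns), int(xi), horizon)
    return traj, outcome


def _classify(
    ab_t: float, ab_nr: int, ab_ns: int, nr: int, ns: int, xi: int, horizon: float
) -> Outcome:
    if ab_t >= 0.0:
        if ab_nr + ab_ns == 0 or nr + ns == 0:
            label: Absorption | str = Absorption.EXTINCT
        elif ab_ns == 0:
            label = Absorption.R_FIXED
        else:
            label = Absorption.S_FIXED
        return Outcome(label, float(ab_t), nr, ns, xi, horizon)
    return Outcome(Outcome.COEXISTENCE, None, nr, ns, xi, horizon)


def classify_outcome(traj: Trajectory, horizon: float) -> Outcome:
    """Re-classify a recorded trajectory at a (possibly shorter) horizon.

    Coexistence means both strains are still present at the horizon; total
    extinction is reported as its own label, never folded into fixation.
    """
    keep = traj.times <= horizon
    if not keep.any():
        raise ValueError("trajectory does not cover the requested horizon")
    nrs, nss, xis, ts = traj.NR[keep], traj.NS[keep], traj.xi[keep], traj.times[keep]
    absorbed = (nrs == 0) | (nss == 0)
    if absorbed.any():
        i = int(np.argmax(absorbed))
        ab_nr, ab_ns = int(nrs[i]), int(nss[i])
        j = -1
        return _classify(
            float(ts[i]), ab_nr, ab_ns, int(nrs[j]), int(nss[j]), int(xis[j]), horizon
        )
    return Outcome(Outcome.COEXISTENCE, None, int(nrs[-1]), int(nss[-1]), int(xis[-1]), horizon)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-parameter-point fixation/coexistence estimates over replicates."""

    n_reps: int
    counts: dict
    phi_R: float
    phi_S: float
    p_coex: float
    p_extinct: float
    ci_phi_R: tuple[float, float]
    ci_phi_S: tuple[float, float]
    ci_p_coex: tuple[float, float]
    horizon: float
    seed_base: int
    labels: np.ndarray = field(repr=False)
    final_NR: np.ndarray = field(repr=False)
    final_NS: np.ndarray = field(repr=False)
    final_xi: np.ndarray = field(repr=False)
    absorption_times: np.ndarray = field(repr=False)

    @property
    def final_N(self) -> np.ndarray:
        return self.final_NR + self.final_NS

    def to_row(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "phi_R": self.phi_R,
            "phi_S": self.phi_S,
            "p_coex": self.p_coex,
            "p_extinct": self.p_extinct,
            "phi_R_lo": self.ci_phi_R[0],
            "phi_R_hi": self.ci_phi_R[1],
            "phi_S_lo": self.ci_phi_S[0],
            "phi_S_hi": self.ci_phi_S[1],
            "p_coex_lo": self.ci_p_coex[0],
            "p_coex_hi": self.ci_p_coex[1],
            "mean_N": float(self.final_N.mean()),
            "mean_NR": float(self.final_NR.mean()),
            "mean_NS": float(self.final_NS.mean()),
            "horizon": self.horizon,
            "seed_base": self.seed_base,
        }


def _wilson(k: int, n: int) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return float(ci.low), float(ci.high)


def run_ensemble(
    params: ModelParams,
    env: EnvParams,
    n_reps: int,
    seed_base: int,
    *,
    horizon: float | None = None,
    init: tuple[int, int, int] | Callable | None = None,
    stop_at_absorption: bool = True,
    max_events: int = 200_000_000,
) -> EnsembleSummary:
    """Estimate fixation/coexistence probabilities from ``n_reps`` replicates.

    Per-replicate seeds are derived reproducibly from ``seed_base``;
    ``init`` may be a fixed ``(NR0, NS0, xi0)`` tuple, a callable
    ``init(rng) -> (NR0, NS0, xi0)``, or None for the coexistence-equilibrium
    default with a stationary starting environment.  With
    ``stop_at_absorption=False`` replicates run to the horizon so that final
    states sample the (quasi-)stationary population statistics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if horizon is None:
        horizon = default_horizon(env)
    root = np.random.SeedSequence(seed_base)
    init_rng = np.random.Generator(np.random.MT19937(root.generate_state(1)[0]))
    rep_seeds = np.random.SeedSequence((seed_base, 1)).generate_state(n_reps)

    labels = np.empty(n_reps, dtype=object)
    fnr = np.empty(n_reps, dtype=np.int64)
    fns = np.empty(n_reps, dtype=np.int64)
    fxi = np.empty(n_reps, dtype=np.int64)
    ab_times = np.full(n_reps, np.nan)
    empty = np.empty(0)
    empty_i = np.empty(0, dtype=np.int64)

    for i in range(n_reps):
        if init is None:
            start = coexistence_equilibrium_init(params, env, init_rng)
        elif callable(init):
            start = init(init_rng)
        else:
            start = init
        nr0, ns0, xi0 = start
        out = _kernel.gillespie_core(
            int(nr0),
            int(ns0),
            int(xi0),
            params.s,
            params.a,
            params.nth,
            float(env.Kplus),
            float(env.Kminus),
            env.nu_plus,
            env.nu_minus,
            float(horizon),
            int(rep_seeds[i]),
            stop_at_absorption,
            max_events,
            0.0,
            empty,
            empty_i,
            empty_i,
            empty_i,
        )
        _, nr, ns, xi, ab_t, ab_nr, ab_ns, _, truncated, _ = out
        if truncated:
            raise TruncatedSimulationError(f"replicate {i} exceeded {max_events} events")
        oc = _classify(ab_t, ab_nr, ab_ns, int(nr), int(ns), int(xi), horizon)
        labels[i] = oc.label
        fnr[i], fns[i], fxi[i] = oc.final_NR, oc.final_NS, oc.final_xi
        if oc.absorption_time is not None:
            ab_times[i] = oc.absorption_time

    # note: numpy elementwise == misbehaves for str-subclass enums; count in Python
    counts = {
        key: sum(1 for lab in labels if lab == key)
        for key in (Absorption.R_FIXED, Absorption.S_FIXED, Outcome.COEXISTENCE, Absorption.EXTINCT)
    }
    n = n_reps
    return EnsembleSummary(
        n_reps=n,
        counts={str(k.value if isinstance(k, Absorption) else k): v for k, v in counts.items()},
        phi_R=counts[Absorption.R_FIXED] / n,
        phi_S=counts[Absorption.S_FIXED] / n,
        p_coex=counts[Outcome.COEXISTENCE] / n,
        p_extinct=counts[Absorption.EXTINCT] / n,
        ci_phi_R=_wilson(counts[Absorption.R_FIXED], n),
        ci_phi_S=_wilson(counts[Absorption.S_FIXED], n),
        ci_p_coex=_wilson(counts[Outcome.COEXISTENCE], n),
        horizon=float(horizon),
        seed_base=seed_base,
        labels=labels,
        final_NR=fnr,
        final_NS=fns,
        final_xi=fxi,
        absorption_times=ab_times,
    )
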