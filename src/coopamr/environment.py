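"""Randomly switching environment: dichotomous Markov noise (DMN).

The carrying capacity is a binary random telegraph signal

    K(t) = (K+ + K- + xi(t) (K+ - K-)) / 2,   xi(t) in {-1, +1},

where xi flips at rate ``(1 - delta*xi) * nu``.  ``nu`` is the mean
switching rate (half the inverse correlation time) and ``delta`` the
switching bias: the stationary law is ``P(xi = +/-1) = (1 +/- delta)/2``,
the stationary mean of xi is ``delta`` and the autocovariance decays as
``(1 - delta^2) exp(-2 nu |t - t'|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class EnvParams:
    """Environment constants.

    Parameters
    ----------
    Kplus, Kminus : float
        Carrying capacities of the mild (abundant) and harsh (scarce)
        states, in cells, with ``Kplus >= Kminus >= 1``.  Equality gives a
        static environment (useful for constant-capacity runs).
    nu : float
        Mean switching rate, per unit time (> 0).
    delta : float
        Switching bias in (-1, 1); delta > 0 favours the mild state.
    """

    Kplus: float
    Kminus: float
    nu: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.Kminus >= 1:
            raise ValueError(f"env.Kminus: must be >= 1, got {self.Kminus}")
        if not self.Kplus >= self.Kminus:
            raise ValueError(
                f"env.Kplus: must be >= Kminus (got K+={self.Kplus}, K-={self.Kminus})"
            )
        if not self.nu > 0:
            raise ValueError(f"env.nu: must be > 0, got {self.nu}")
        if not (-1.0 < self.delta < 1.0):
            raise ValueError(f"env.delta: must lie in (-1, 1), got {self.delta}")

    @property
    def nu_plus(self) -> float:
        """Rate of leaving the mild state (K+ -> K-)."""
        return self.nu * (1.0 - self.delta)

    @property
    def nu_minus(self) -> float:
        """Rate of leaving the harsh state (K- -> K+)."""
        return self.nu * (1.0 + self.delta)

    def capacity(self, xi: int) -> float:
        """Carrying capacity K(xi) of environmental state xi = +/-1."""
        if xi not in (-1, 1):
            raise ValueError(f"xi must be -1 or +1, got {xi}")
        return 0.5 * (self.Kplus + self.Kminus + xi * (self.Kplus - self.Kminus))

    @property
    def mean_K(self) -> float:
        """Arithmetic stationary mean <K> = ((1+d)K+ + (1-d)K-)/2."""
        return 0.5 * ((1.0 + self.delta) * self.Kplus + (1.0 - self.delta) * self.Kminus)


@dataclass(frozen=True)
class EnvState:
    """Binary environmental state with its carrying capacity."""

    xi: int

    def __post_init__(self) -> None:
        if self.xi not in (-1, 1):
            raise ValueError(f"xi must be -1 or +1, got {self.xi}")

    def K(self, env: EnvParams) -> float:
        return env.capacity(self.xi)


def switching_rate(xi: int, env: EnvParams) -> float:
    """Rate ``(1 - delta*xi) nu`` at which state xi flips."""
    if xi == 1:
        return env.nu_plus
    if xi == -1:
        return env.nu_minus
    raise ValueError(f"xi must be -1 or +1, got {xi}")


def stationary_env_probability(delta: float) -> tuple[float, float]:
    """Stationary probabilities ``(P(xi=+1), P(xi=-1)) = ((1+d)/2, (1-d)/2)``."""
    if not (-1.0 < delta < 1.0):
        raise ValueError(f"delta must lie in (-1, 1), got {delta}")
    return (1.0 + delta) / 2.0, (1.0 - delta) / 2.0


def effective_carrying_capacities(env: EnvParams) -> tuple[float, float]:
    """Return ``(Kbar, <K>)``.

    ``Kbar = 1/<1/K> = 2 K+ K- / ((1-d) K+ + (1+d) K-)`` is the harmonic
    self-averaged capacity felt under very fast switching; ``<K>`` is the
    arithmetic stationary mean.  ``K- <= Kbar <= <K> <= K+``.
    """
    d = env.delta
    kbar = 2.0 * env.Kplus * env.Kminus / (
        (1.0 - d) * env.Kplus + (1.0 + d) * env.Kminus
    )
    return kbar, env.mean_K


def draw_stationary_xi(env: EnvParams, rng: np.random.Generator) -> int:
    """Sample xi from the stationary law (1 +/- delta)/2."""
    p_plus, _ = stationary_env_probability(env.delta)
    return 1 if rng.random() < p_plus else -1


@dataclass(frozen=True)
class EnvPath:
    """A realisation of the DMN on [0, t_end].

    ``switch_times`` are the strictly increasing flip times; the state is
    ``xi0`` on [0, switch_times[0]) and flips sign at each entry.
    """

    xi0: int
    switch_times: np.ndarray = field(repr=False)
    t_end: float

    def xi_at(self, t: np.ndarray | float) -> np.ndarray:
        """Piecewise-constant state at times t (vectorised)."""
        t = np.asarray(t, dtype=float)
        flips = np.searchsorted(self.switch_times, t, side="right")
        return self.xi0 * np.where(flips % 2 == 0, 1, -1)

    def resample(self, dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        """Evenly resampled (times, xi) on a grid of step dt (avoids
        event-time bias in statistics)."""
        ts = np.arange(0.0, self.t_end, dt)
        return ts, self.xi_at(ts)

    def to_records(self) -> np.ndarray:
        """(time, xi) records at t=0 and every switch, for TSV export."""
        ts = np.concatenate([[0.0], self.switch_times])
        signs = self.xi0 * (-1) ** np.arange(ts.size)
        return np.column_stack([ts, signs])


def sample_dmn_path(
    env: EnvParams,
    t_end: float,
    rng: np.random.Generator,
    xi0: int | None = None,
) -> EnvPath:
    """Simulate the telegraph process exactly on [0, t_end].

    The initial state is drawn from the stationary law unless ``xi0`` is
    given.  Waiting times in state xi are exponential with rate
    ``(1 - delta*xi) nu``.
    """
    if xi0 is None:
        xi0 = draw_stationary_xi(env, rng)
    elif xi0 not in (-1, 1):
        raise ValueError(f"xi0 must be -1 or +1, got {xi0}")
    times = []
    t, xi = 0.0, xi0
    while True:
        t += rng.exponential(1.0 / switching_rate(xi, env))
        if t >= t_end:
            break
        times.append(t)
        xi = -xi
    return EnvPath(xi0=xi0, switch_times=np.asarray(times), t_end=t_end)


@dataclass(frozen=True)
class DmnStatistics:
    mean: float
    lags: np.ndarray
    autocovariance: np.ndarray
    n_switches: int
    low_confidence: bool


def dmn_statistics(
    path: EnvPath,
    lags: Sequence[float] = (0.0, 1.0, 2.0, 5.0, 10.0),
    dt: float = 0.1,
) -> DmnStatistics:
    """Empirical mean and autocovariance of a DMN realisation.

    The path is resampled on an even grid of step ``dt``.  For a long path
    the mean converges to ``delta`` and the autocovariance at lag ``u`` to
    ``(1 - delta^2) exp(-2 nu u)``.  A path with fewer than one switch is
    flagged low-confidence.
    """
    _, xs = path.resample(dt)
    xs = xs.astype(float)
    mean = float(xs.mean())
    centred = xs - mean
    lags = np.asarray(lags, dtype=float)
    acov = np.empty(lags.size)
    for i, lag in enumerate(lags):
        k = int(round(lag / dt))
        if k >= xs.size:
            acov[i] = np.nan
        elif k == 0:
            acov[i] = float(np.mean(centred * centred))
        else:
            acov[i] = float(np.mean(centred[:-k] * centred[k:]))
    return DmnStatistics(
        mean=mean,
        lags=lags,
        autocovariance=acov,
        n_switches=int(path.switch_times.size),
        low_confidence=path.switch_times.size < 1,
    )
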