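"""Two-strain birth-death model of cooperative antimicrobial resistance.

A well-mixed population holds ``NR`` resistant (R) and ``NS`` sensitive (S)
microbes under a constant biostatic drug.  R cells pay a metabolic cost
``s`` for producing a drug-inactivating enzyme; when their abundance reaches
the cooperation threshold ``Nth`` the enzyme becomes a public good and the
drug no longer reduces S growth.  Below threshold, S growth is reduced by a
factor ``1 - a``.

Per-capita birth rates are fitnesses normalised by the population mean
fitness, and deaths are logistic with rate ``N/K`` for carrying capacity
``K``:

    T+_alpha = (f_alpha / fbar) * N_alpha,   T-_alpha = (N / K) * N_alpha

so the total birth rate is exactly ``N`` and the total death rate exactly
``N^2/K``.  Time is measured in units of the baseline division time
(fitness 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class EmptyPopulationError(ValueError):
    """Raised when an operation requires a non-empty population."""


@dataclass(frozen=True)
class ModelParams:
    """Strain-level constants.

    Parameters
    ----------
    s : float
        Extra metabolic cost of resistance (dimensionless, 0 < s < 1);
        resistant fitness is ``f_R = 1 - s``.
    a : float
        Growth-rate reduction of the sensitive strain by the drug above the
        minimum inhibitory concentration (dimensionless, s < a < 1).
    nth : int
        Cooperation threshold: resistant abundance at and above which drug
        inactivation protects the whole community (cells, >= 1).
    """

    s: float
    a: float
    nth: int

    def __post_init__(self) -> None:
        if not (0.0 < self.s < 1.0):
            raise ValueError(f"model.s: must satisfy 0 < s < 1, got {self.s}")
        if not (self.s < self.a < 1.0):
            raise ValueError(
                f"model.a: must satisfy s < a < 1 (got s={self.s}, a={self.a})"
            )
        if not (isinstance(self.nth, (int,)) and self.nth >= 1):
            raise ValueError(f"model.nth: must be a positive integer, got {self.nth}")

    @property
    def f_R(self) -> float:
        return 1.0 - self.s


@dataclass(frozen=True)
class PopulationState:
    """Integer strain abundances (NR resistant, NS sensitive)."""

    NR: int
    NS: int

    def __post_init__(self) -> None:
        if self.NR < 0 or self.NS < 0:
            raise ValueError(f"abundances must be non-negative, got ({self.NR}, {self.NS})")

    @property
    def N(self) -> int:
        return self.NR + self.NS

    @property
    def x(self) -> float:
        """Resistant fraction NR/N; undefined for an empty population."""
        if self.N == 0:
            raise EmptyPopulationError("x = NR/N is undefined when N = 0")
        return self.NR / self.N


@dataclass(frozen=True)
class RateSet:
    """Propensities of the four demographic reactions (events per unit time)."""

    TR_plus: float
    TR_minus: float
    TS_plus: float
    TS_minus: float

    @property
    def total(self) -> float:
        return self.TR_plus + self.TR_minus + self.TS_plus + self.TS_minus


class Absorption(str, Enum):
    """Compositional absorption label of a population state."""

    NONE = "none"
    R_FIXED = "R_fixed"
    S_FIXED = "S_fixed"
    EXTINCT = "extinct"


def fitness_S(NR: int, params: ModelParams) -> float:
    """Sensitive-strain fitness ``f_S = 1 - a * theta[Nth - NR]``.

    The step function uses the convention ``theta[0] = 0``: cooperation is
    already active at ``NR = Nth`` exactly.
    """
    if NR < 0:
        raise ValueError("NR must be non-negative")
    return 1.0 if NR >= params.nth else 1.0 - params.a


def mean_fitness(state: PopulationState, params: ModelParams) -> float:
    """Abundance-weighted mean fitness ``fbar = f_R NR/N + f_S NS/N``."""
    n = state.N
    if n == 0:
        raise EmptyPopulationError("mean fitness is undefined for an empty population")
    fs = fitness_S(state.NR, params)
    return (params.f_R * state.NR + fs * state.NS) / n


def transition_rates(state: PopulationState, K: float, params: ModelParams) -> RateSet:
    """Birth/death propensities of both strains at carrying capacity ``K``.

    Births are fitness-weighted with mean-fitness normalisation, deaths are
    logistic; the empty population returns an all-zero rate set.
    """
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"carrying capacity must be finite and positive, got {K}")
    n = state.N
    if n == 0:
        return RateSet(0.0, 0.0, 0.0, 0.0)
    fbar = mean_fitness(state, params)
    fs = fitness_S(state.NR, params)
    death_percap = n / K
    return RateSet(
        TR_plus=params.f_R / fbar * state.NR,
        TR_minus=death_percap * state.NR,
        TS_plus=fs / fbar * state.NS,
        TS_minus=death_percap * state.NS,
    )


def is_absorbing(state: PopulationState) -> Absorption:
    """Classify compositional absorption.

    Only the composition is absorbed: after fixation the population size
    keeps fluctuating with the carrying capacity.
    """
    if state.N == 0:
        return Absorption.EXTINCT
    if state.NS == 0:
        return Absorption.R_FIXED
    if state.NR == 0:
        return Absorption.S_FIXED
    return Absorption.NONE
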