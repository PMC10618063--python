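"""Static-environment fixation theory via an effective Moran process.

At constant carrying capacity ``K0`` the population size relaxes to ``K0``
much faster than its composition evolves, so the resistant count ``n``
performs a one-dimensional birth-death chain on {0, ..., K0} with effective
rates ``T~R+-(n) = TR+- TS-+ / N`` (a birth of one strain paired with a
death of the other).  The hop ratio

    gamma(n) = T~R-(n) / T~R+(n) = f_S(n) / f_R

is piecewise constant: ``(1-a)/(1-s) < 1`` below the cooperation threshold
(selection favours R) and ``1/(1-s) > 1`` at and above it (favours S).
Fixation probabilities and the mean coexistence time (MCT, the
unconditional mean absorption time) follow from the standard absorption
formulas of such a chain; products of gamma are handled in log space.

A closed-form approximation for the fixation probability of R started at
the coexistence equilibrium ``n0 = Nth`` is

    phi ~= 1 / (1 + (1-s)^-(K0 - K0*)),
    K0* = Nth ln(1-a)/ln(1-s) - ln(s(1-a)/(a-s))/ln(1-s),

where ``K0*`` is the population size at which R and S fixate with equal
probability 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import ModelParams

__all__ = [
    "MoranChain",
    "effective_moran_rates",
    "hop_ratio",
    "fixation_probability_exact",
    "fixation_probability_approx",
    "k0_star",
    "k0_star_leading_ratio",
    "mean_coexistence_time",
]

# float64 overflow guard for linear-domain MCT sums
_MAX_LOG = 650.0


def effective_moran_rates(n: int, K0: int, params: ModelParams) -> tuple[float, float]:
    """Effective hop rates ``(T~R+, T~R-)`` of the R count at fixed N = K0."""
    if not 0 <= n <= K0:
        raise ValueError(f"n must lie in [0, {K0}], got {n}")
    if n == 0 or n == K0:
        return 0.0, 0.0
    fr = params.f_R
    fs = 1.0 if n >= params.nth else 1.0 - params.a
    fbar = (fr * n + fs * (K0 - n)) / K0
    common = n * (K0 - n) / K0
    return fr / fbar * common, fs / fbar * common


def hop_ratio(n: int, params: ModelParams) -> float:
    """gamma(n) = T~R-(n)/T~R+(n) = f_S(n)/f_R, piecewise constant in n."""
    fs = 1.0 if n >= params.nth else 1.0 - params.a
    return fs / params.f_R


@dataclass(frozen=True)
class MoranChain:
    """Effective birth-death chain of the R count at fixed total size K0."""

    K0: int
    params: ModelParams

    def __post_init__(self) -> None:
        if self.K0 < 2:
            raise ValueError(f"K0 must be >= 2, got {self.K0}")

    def rates(self, n: int) -> tuple[float, float]:
        return effective_moran_rates(n, self.K0, self.params)

    def log_gammas(self) -> np.ndarray:
        """log gamma(n) for interior states n = 1..K0-1."""
        ns = np.arange(1, self.K0)
        below = ns < self.params.nth
        lg_lo = math.log1p(-self.params.a) - math.log1p(-self.params.s)
        lg_hi = -math.log1p(-self.params.s)
        return np.where(below, lg_lo, lg_hi)


def fixation_probability_exact(n0: int, K0: int, params: ModelParams) -> float:
    """Exact fixation probability of R from n0 copies in a population of K0.

    Standard absorption formula of the birth-death chain,
    ``phi(n0) = sum_{k<n0} prod_{j<=k} gamma(j) / sum_{k<K0} prod_{j<=k} gamma(j)``,
    evaluated in log space.  Neutral parameters give ``phi = n0/K0``.
    """
    if not 0 <= n0 <= K0:
        raise ValueError(f"n0 must lie in [0, {K0}], got {n0}")
    if n0 == 0:
        return 0.0
    if n0 == K0:
        return 1.0
    chain = MoranChain(K0, params)
    # log of cumulative products rho_k = prod_{j=1..k} gamma(j), k = 0..K0-1
    log_rho = np.concatenate([[0.0], np.cumsum(chain.log_gammas())])
    return float(np.exp(logsumexp(log_rho[:n0]) - logsumexp(log_rho)))


def k0_star(params: ModelParams) -> float:
    """Population size K0* at which R and S fixation are equiprobable."""
    s, a, nth = params.s, params.a, params.nth
    log1ms = math.log1p(-s)
    return nth * math.log1p(-a) / log1ms - math.log(s * (1.0 - a) / (a - s)) / log1ms


def k0_star_leading_ratio(params: ModelParams) -> float:
    """Leading-order ratio K0*/Nth = ln(1-a)/ln(1-s) for large thresholds."""
    return math.log1p(-params.a) / math.log1p(-params.s)


def fixation_probability_approx(K0: float, params: ModelParams) -> tuple[float, float]:
    """Closed-form (phi, K0*) for a start at the coexistence equilibrium.

    Valid for ``Nth < K0`` and ``0 < s < a < 1``; ``phi(K0*) = 1/2``
    exactly.
    """
    if params.a <= params.s:
        raise ValueError("requires a > s")
    if K0 <= params.nth:
        raise ValueError(f"requires K0 > Nth, got K0={K0}, Nth={params.nth}")
    ks = k0_star(params)
    phi = 1.0 / (1.0 + (1.0 - params.s) ** (-(K0 - ks)))
    return phi, ks


def mean_coexistence_time(n0: int, K0: int, params: ModelParams) -> float:
    """Unconditional mean time to absorption (either strain fixing) from n0.

    Solves the first-step equations by exact forward telescoping in O(K0):
    with ``d(n) = tau(n+1) - tau(n)``,

        d(n) = rho_n (d(0) - w_n),  w_n = sum_{k<=n} 1/(rho_k T~R+(k)),

    and ``d(0)`` fixed by ``tau(K0) = 0``.  Raises for population sizes
    where the cumulative products overflow double precision (K0 beyond a
    few thousand for the default parameters).
    """
    if not 0 < n0 < K0:
        raise ValueError(f"n0 must lie strictly inside (0, {K0}), got {n0}")
    chain = MoranChain(K0, params)
    log_rho = np.concatenate([[0.0], np.cumsum(chain.log_gammas())])  # k = 0..K0-1
    if np.max(np.abs(log_rho)) > _MAX_LOG:
        raise OverflowError(
            f"MCT sums overflow double precision for K0={K0} with these parameters"
        )
    rho = np.exp(log_rho)
    tplus = np.array([effective_moran_rates(n, K0, params)[0] for n in range(1, K0)])
    # w_n for n = 0..K0-1 (w_0 = 0)
    w = np.concatenate([[0.0], np.cumsum(1.0 / (rho[1:] * tplus))])
    d0 = float(np.sum(rho * w) / np.sum(rho))
    tau = float(np.sum(rho[:n0] * (d0 - w[:n0])))
    return tau
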