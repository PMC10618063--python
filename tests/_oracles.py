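"""Independent oracles used only by the tests.

Kept deliberately separate from the library code paths they validate:
first-step-analysis linear solves for the effective Moran chain, and direct
numerical integration of the truncated master equation for tiny systems.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import expm_multiply

from coopamr.model import ModelParams


def _rational_rates(n: int, K0: int, s: Fraction, a: Fraction, nth: int):
    fr = 1 - s
    fs = Fraction(1) if n >= nth else 1 - a
    fbar = (fr * n + fs * (K0 - n)) / K0
    common = Fraction(n * (K0 - n), K0)
    return fr / fbar * common, fs / fbar * common


def moran_first_step_solve(K0: int, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Fixation probability and unconditional mean absorption time for every
    start n0 = 0..K0, solving the tridiagonal first-step equations by the
    Thomas algorithm in exact rational arithmetic (the chain is too
    ill-conditioned for a float64 solve at strong selection)."""
    s, a, nth = Fraction(params.s), Fraction(params.a), params.nth

    def solve(rhs_val: Fraction, boundary_K: Fraction) -> np.ndarray:
        c = [Fraction(0)] * K0
        d = [Fraction(0)] * K0
        for n in range(1, K0):
            tp, tm = _rational_rates(n, K0, s, a, nth)
            diag = -(tp + tm)
            rhs = rhs_val
            upper = tp
            if n == K0 - 1:
                rhs -= tp * boundary_K
                upper = Fraction(0)
            denom = diag - tm * c[n - 1]
            c[n] = upper / denom
            d[n] = (rhs - tm * d[n - 1]) / denom
        x = [Fraction(0)] * (K0 + 1)
        x[K0] = boundary_K
        for n in range(K0 - 1, 0, -1):
            x[n] = d[n] - c[n] * x[n + 1]
        return np.array([float(v) for v in x])

    phi = solve(Fraction(0), Fraction(1))
    tau = solve(Fraction(-1), Fraction(0))
    return phi, tau


def truncated_me_distribution(
    params: ModelParams,
    K0: float,
    init: tuple[int, int],
    t: float,
    n_cap: int,
) -> dict[tuple[int, int], float]:
    """Probability over (NR, NS) at time t for a static environment,
    integrating the truncated master equation with a matrix exponential.

    States with NR + NS > n_cap are dropped; choose n_cap large enough that
    the lost mass is negligible for the test at hand.
    """
    states = [
        (nr, ns) for nr in range(n_cap + 1) for ns in range(n_cap + 1 - nr)
    ]
    index = {st: i for i, st in enumerate(states)}
    Q = lil_matrix((len(states), len(states)))
    fr = 1.0 - params.s
    for (nr, ns), i in index.items():
        n = nr + ns
        if n == 0:
            continue
        fs = 1.0 if nr >= params.nth else 1.0 - params.a
        fbar = (fr * nr + fs * ns) / n
        flows = []
        if nr + ns + 1 <= n_cap:
            flows.append(((nr + 1, ns), fr / fbar * nr))
            flows.append(((nr, ns + 1), fs / fbar * ns))
        if nr > 0:
            flows.append(((nr - 1, ns), n / K0 * nr))
        if ns > 0:
            flows.append(((nr, ns - 1), n / K0 * ns))
        for dest, rate in flows:
            if rate > 0:
                Q[index[dest], i] += rate
                Q[i, i] -= rate
    p0 = np.zeros(len(states))
    p0[index[init]] = 1.0
    pt = expm_multiply(Q.tocsr() * t, p0)
    return {st: float(pt[i]) for st, i in index.items()}
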