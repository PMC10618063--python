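"""Ensemble experiments over the environmental statistics (nu, delta).

Phase diagrams of fixation/coexistence probability, quasi-stationary
abundance distributions, mean abundances and coexistence composition.  All
estimates come from independent SSA replicates; per-point seeds are derived
reproducibly from a base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .deterministic import InvalidRegimeError, optimal_eradication_region
from .environment import EnvParams, effective_carrying_capacities
from .model import ModelParams
from .ssa import EnsembleSummary, default_horizon, run_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseDiagram",
    "AbundanceDistribution",
    "scan_phase_diagram",
    "abundance_distributions",
    "mean_abundances_vs_environment",
    "coexistence_composition",
    "default_nu_grid",
    "default_delta_grid",
]


def default_nu_grid(n: int = 13) -> np.ndarray:
    """Log-spaced switching rates covering 1e-4 .. 1e2."""
    return np.logspace(-4, 2, n)


def default_delta_grid(n: int = 7) -> np.ndarray:
    """Linear switching biases covering -0.9 .. 0.9."""
    return np.linspace(-0.9, 0.9, n)


@dataclass(frozen=True)
class PhaseDiagram:
    """Gridded ensemble estimates over (nu, delta)."""

    table: pd.DataFrame = field(repr=False)
    params: ModelParams
    n_reps: int
    seed_base: int

    def point(self, nu: float, delta: float) -> pd.Series:
        t = self.table
        i = ((t["nu"] - nu).abs() + (t["delta"] - delta).abs()).idxmin()
        return t.loc[i]


def _point_seeds(seed_base: int, n_points: int) -> np.ndarray:
    return np.random.SeedSequence((seed_base, 77)).generate_state(n_points)


def scan_phase_diagram(
    params: ModelParams,
    env_template: EnvParams,
    nus: Sequence[float],
    deltas: Sequence[float],
    n_reps: int = 500,
    seed_base: int = 0,
    *,
    horizon: float | None = None,
    overlay_eradication_region: bool = True,
    **ensemble_kwargs,
) -> PhaseDiagram:
    """Run an ensemble at every (nu, delta) grid point.

    The horizon defaults to 2<K> per point.  Per-point failures are logged
    and flagged (``failed`` column); the scan continues.  When requested,
    the analytic eradication-region membership is overlaid per point.
    """
    nus = np.sort(np.asarray(nus, dtype=float))
    deltas = np.sort(np.asarray(deltas, dtype=float))
    points = [(nu, d) for nu in nus for d in deltas]
    seeds = _point_seeds(seed_base, len(points))
    try:
        region = optimal_eradication_region(params, env_template)
    except InvalidRegimeError:
        region = None

    rows = []
    for (nu, d), sd in zip(points, seeds):
        env = EnvParams(env_template.Kplus, env_template.Kminus, nu, d)
        row: dict = {"nu": nu, "delta": d, "seed": int(sd), "failed": False}
        try:
            summ = run_ensemble(
                params,
                env,
                n_reps,
                int(sd),
                horizon=horizon if horizon is not None else default_horizon(env),
                **ensemble_kwargs,
            )
            row.update(summ.to_row())
        except Exception:  # noqa: BLE001 - scan must survive point failures
            logger.exception("phase point (nu=%g, delta=%g) failed", nu, d)
            row["failed"] = True
        if overlay_eradication_region and region is not None:
            row["in_eradication_region"] = bool(region.membership(nu, d))
        rows.append(row)
    return PhaseDiagram(
        table=pd.DataFrame(rows), params=params, n_reps=n_reps, seed_base=seed_base
    )


@dataclass(frozen=True)
class AbundanceDistribution:
    """Histogram over cell counts, optionally Gaussian-smoothed."""

    counts: np.ndarray = field(repr=False)  # bin index = cell count
    mass: np.ndarray = field(repr=False)  # smoothed, sums to 1
    sigma: float
    n_modes: int
    peak_locations: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": np.arange(self.mass.size), "mass": self.mass, "raw": self.counts}
        )


def _smooth_and_peaks(
    values: np.ndarray, sigma: float, prominence_frac: float
) -> AbundanceDistribution:
    hist = np.bincount(values.astype(np.int64))
    mass = hist / hist.sum()
    if sigma > 0:
        # truncated at 4 sigma; edge-renormalised so total mass is preserved
        smooth = gaussian_filter1d(mass, sigma, truncate=4.0, mode="constant")
        norm = gaussian_filter1d(np.ones_like(mass), sigma, truncate=4.0, mode="constant")
        smooth = smooth / norm
        smooth = smooth / smooth.sum()
    else:
        smooth = mass
    peaks, _ = find_peaks(smooth, prominence=prominence_frac * smooth.max())
    # an edge maximum at 0 (absorbed strain) counts as a mode
    if smooth.size > 1 and smooth[0] > smooth[1] and smooth[0] >= prominence_frac * smooth.max():
        peaks = np.concatenate([[0], peaks])
    return AbundanceDistribution(
        counts=hist, mass=smooth, sigma=sigma, n_modes=int(peaks.size), peak_locations=peaks
    )


def abundance_distributions(
    params: ModelParams,
    env: EnvParams,
    n_reps: int = 500,
    seed_base: int = 0,
    *,
    sampling_time: float | None = None,
    sigma: float = 10.0,
    prominence_frac: float = 0.1,
    **ensemble_kwargs,
) -> dict[str, AbundanceDistribution]:
    """Quasi-stationary distributions of N, NR and NS.

    Each replicate runs (through any compositional fixation) to the
    sampling time, default 2<K>; the state there is one draw from the
    quasi-stationary law.  Histograms are smoothed by a Gaussian of width
    ``sigma`` cells truncated at 4 sigma and edge-renormalised; modality is
    the count of maxima with prominence above ``prominence_frac`` of the
    highest peak.
    """
    if sampling_time is None:
        sampling_time = default_horizon(env)
    summ = run_ensemble(
        params,
        env,
        n_reps,
        seed_base,
        horizon=sampling_time,
        stop_at_absorption=False,
        **ensemble_kwargs,
    )
    return {
        "N": _smooth_and_peaks(summ.final_N, sigma, prominence_frac),
        "NR": _smooth_and_peaks(summ.final_NR, sigma, prominence_frac),
        "NS": _smooth_and_peaks(summ.final_NS, sigma, prominence_frac),
    }


def mean_abundances_vs_environment(
    params: ModelParams,
    env_template: EnvParams,
    nus: Sequence[float],
    deltas: Sequence[float],
    n_reps: int = 300,
    seed_base: int = 0,
    **ensemble_kwargs,
) -> pd.DataFrame:
    """Stationary mean <N>, <NR>, <NS> on a (nu, delta) grid.

    Averages include replicates past compositional fixation (the surviving
    strain's abundance keeps tracking K).  <N> decreases with nu at fixed
    delta and tends to K+- as delta -> +-1.
    """
    nus = np.asarray(nus, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    points = [(nu, d) for nu in nus for d in deltas]
    seeds = _point_seeds(seed_base, len(points))
    rows = []
    for (nu, d), sd in zip(points, seeds):
        env = EnvParams(env_template.Kplus, env_template.Kminus, nu, d)
        summ = run_ensemble(
            params,
            env,
            n_reps,
            int(sd),
            horizon=default_horizon(env),
            stop_at_absorption=False,
            **ensemble_kwargs,
        )
        kbar, kmean = effective_carrying_capacities(env)
        rows.append(
            {
                "nu": nu,
                "delta": d,
                "mean_N": float(summ.final_N.mean()),
                "mean_NR": float(summ.final_NR.mean()),
                "mean_NS": float(summ.final_NS.mean()),
                "Kbar": kbar,
                "mean_K": kmean,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def coexistence_composition(
    params: ModelParams,
    env_template: EnvParams,
    nus: Sequence[float],
    deltas: Sequence[float],
    n_reps: int = 500,
    seed_base: int = 0,
    **ensemble_kwargs,
) -> pd.DataFrame:
    """Mean resistant fraction among replicates still coexisting at the
    horizon, with the coexistence probability per grid point.

    Points where no replicate coexists are flagged (``no_coexisting``) with
    NaN composition, never interpolated.
    """
    nus = np.asarray(nus, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    points = [(nu, d) for nu in nus for d in deltas]
    seeds = _point_seeds(seed_base, len(points))
    rows = []
    for (nu, d), sd in zip(points, seeds):
        env = EnvParams(env_template.Kplus, env_template.Kminus, nu, d)
        summ: EnsembleSummary = run_ensemble(
            params,
            env,
            n_reps,
            int(sd),
            horizon=default_horizon(env),
            stop_at_absorption=False,
            **ensemble_kwargs,
        )
        coex = (summ.final_NR > 0) & (summ.final_NS > 0)
        n_coex = int(coex.sum())
        if n_coex:
            x = summ.final_NR[coex] / (summ.final_NR[coex] + summ.final_NS[coex])
            mean_x = float(x.mean())
            mean_nr = float(summ.final_NR[coex].mean())
            mean_ns = float(summ.final_NS[coex].mean())
        else:
            mean_x = mean_nr = mean_ns = float("nan")
        rows.append(
            {
                "nu": nu,
                "delta": d,
                "p_coex": n_coex / n_reps,
                "mean_x_coex": mean_x,
                "mean_NR_coex": mean_nr,
                "mean_NS_coex": mean_ns,
                "n_coexisting": n_coex,
                "no_coexisting": n_coex == 0,
            }
        )
    return pd.DataFrame(rows)
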