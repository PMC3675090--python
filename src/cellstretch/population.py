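"""Whole-population reorientation Monte Carlo.

Cells that cannot maintain focal adhesions and stress fibers at their
current orientation detach, diffuse rotationally, and try again: the loop
of orientation search, focal-complex nucleation and adhesion/fiber
development repeats until an orientation with long-term stability is
found.  The ensemble is tracked by the nematic order parameter

    S = <cos 2 theta> ,

+1 for parallel, -1 for perpendicular alignment and 0 for a random
population, and its relaxation is summarized by a fitted exponential
decay time.

Because the attached-phase dynamics at a given orientation are
deterministic (each trial starts from the same nascent state with an
unloaded filament), trial outcomes are precomputed once on a fine angle
grid (an :class:`~cellstretch.cell.AngleSweepResult`) and the Monte Carlo
loop reduces to table lookups; this is exact up to the grid resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cell import AngleSweepResult, angle_sweep
from .params import ModelParams, ReorientationPolicy, StretchProtocol

__all__ = [
    "wrap_angle",
    "rotate_hop",
    "order_parameter",
    "build_orientation_table",
    "PopulationTrace",
    "simulate_population",
    "DecayFit",
    "fit_characteristic_time",
    "EnsembleResult",
    "run_ensemble",
]


def wrap_angle(theta: float) -> float:
    """Fold an orientation to the half-circle (-pi/2, pi/2] (period pi)."""
    folded = math.remainder(theta, math.pi)
    if folded <= -math.pi / 2.0:
        folded += math.pi
    return folded


def rotate_hop(theta: float, policy: ReorientationPolicy, rng: np.random.Generator) -> float:
    """One rotational-diffusion hop between detachment and re-attachment.

    ``theta' = theta + sqrt(2*Dr*t0)*N`` with standard-normal ``N``: the
    mean-square angular deviation accumulated over the nucleation interval
    ``t0`` is ``2*Dr*t0``, as for one-dimensional Brownian motion.
    """
    step = math.sqrt(2.0 * policy.dr * policy.t0) * rng.standard_normal()
    return wrap_angle(theta + step)


def order_parameter(thetas) -> float:
    """Nematic order parameter S = mean of cos(2*theta)."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("order_parameter requires at least one orientation")
    return float(np.mean(np.cos(2.0 * thetas)))


def build_orientation_table(
    protocol: StretchProtocol,
    params: ModelParams,
    policy: ReorientationPolicy,
) -> AngleSweepResult:
    """Per-orientation trial outcomes on the policy's angle grid.

    Each grid angle is assessed exactly as a cell trial would be: attach
    with the policy's nascent densities and integrate for ``trial_time``.
    """
    thetas = np.deg2rad(
        np.arange(0.0, 90.0 + 0.5 * policy.table_step_deg, policy.table_step_deg)
    )
    return angle_sweep(
        protocol,
        params,
        thetas,
        xi0=policy.xi0,
        zeta0=policy.zeta0,
        tau_end=policy.trial_time,
        collapse_threshold=policy.collapse_threshold,
        grace_time=policy.grace_time,
    )


@dataclass
class PopulationTrace:
    """Orientation histories and order parameter of a cell population."""

    tau: np.ndarray
    theta_matrix: np.ndarray  # (n_cells, n_grid), zero-order hold
    s_series: np.ndarray
    settled: np.ndarray  # bool per cell
    settle_time: np.ndarray  # attachment time of the settling trial (nan if not)
    seed: Optional[int] = None

    @property
    def n_cells(self) -> int:
        return self.theta_matrix.shape[0]

    @property
    def settled_fraction(self) -> float:
        return float(np.mean(self.settled))

    def s_tail_mean(self, fraction: float = 0.25) -> float:
        """Mean order parameter over the final ``fraction`` of the horizon."""
        n = max(1, int(round(fraction * self.tau.size)))
        return float(np.mean(self.s_series[-n:]))

    def to_dataframe(self):
        import pandas as pd

        st = self.settle_time[self.settled]
        n_settled = (st[:, None] <= self.tau[None, :]).sum(axis=0)
        return pd.DataFrame({"tau": self.tau, "S": self.s_series, "n_settled": n_settled})


def simulate_population(
    n_cells: int,
    protocol: StretchProtocol,
    params: ModelParams,
    policy: ReorientationPolicy,
    tau_end: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    table: Optional[AngleSweepResult] = None,
) -> PopulationTrace:
    """Monte Carlo of ``n_cells`` independent cells searching orientations.

    Each cell starts at an independent uniform random orientation and runs
    the attach/assess/detach/hop loop: an attached trial either survives
    ``policy.trial_time`` (the cell settles; stable attached dynamics
    cannot destabilize spontaneously, so its orientation is frozen) or
    collapses at the tabulated collapse time, after which the cell hops by
    rotational diffusion and its clock advances by the nucleation interval
    ``t0``.  The order parameter is sampled on a uniform grid of
    ``policy.n_grid`` points by zero-order hold of each cell's orientation.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if tau_end < policy.trial_time:
        raise ValueError(
            f"tau_end={tau_end:g} is shorter than one trial window "
            f"({policy.trial_time:g}); no cell could settle"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if table is None:
        table = build_orientation_table(protocol, params, policy)

    grid = np.linspace(0.0, tau_end, policy.n_grid)
    theta_matrix = np.empty((n_cells, policy.n_grid))
    settled = np.zeros(n_cells, dtype=bool)
    settle_time = np.full(n_cells, np.nan)

    for i in range(n_cells):
        theta = wrap_angle(rng.uniform(-math.pi / 2.0, math.pi / 2.0))
        t = 0.0
        times = [0.0]
        angles = [theta]
        while t < tau_end:
            stable, collapse_time = table.lookup(theta)
            if stable:
                settled[i] = True
                settle_time[i] = t
                break
            t += collapse_time + policy.t0
            theta = rotate_hop(theta, policy, rng)
            times.append(t)
            angles.append(theta)
        idx = np.searchsorted(np.asarray(times), grid, side="right") - 1
        theta_matrix[i] = np.asarray(angles)[idx]

    if not settled.any():
        warnings.warn(
            "no cell settled within the horizon; the trace is a pure search "
            "transient — extend tau_end",
            RuntimeWarning,
            stacklevel=2,
        )
    s_series = np.cos(2.0 * theta_matrix).mean(axis=0)
    return PopulationTrace(grid, theta_matrix, s_series, settled, settle_time, seed)


@dataclass(frozen=True)
class DecayFit:
    """Three-parameter exponential fit S(tau) = S_inf + (S_0-S_inf) e^{-tau/tau_c}."""

    tau_c: float
    s0: float
    s_inf: float
    rms_residual: float


def fit_characteristic_time(
    tau,
    s=None,
) -> DecayFit:
    """Fit the order-parameter relaxation by a single exponential.

    Accepts a :class:`PopulationTrace` or a pair of arrays.  The fit is
    refused (``ValueError``) when the trace shows no net decay
    (|S_end - S_start| <= 0.1): the decay time is then unidentifiable.
    """
    if isinstance(tau, PopulationTrace):
        trace = tau
        tau, s = trace.tau, trace.s_series
    tau = np.asarray(tau, dtype=float)
    s = np.asarray(s, dtype=float)
    if abs(s[-1] - s[0]) <= 0.1:
        raise ValueError(
            f"no net decay to fit: S changes by {abs(s[-1] - s[0]):.3f} <= 0.1"
        )

    def model(t, s0, s_inf, tau_c):
        return s_inf + (s0 - s_inf) * np.exp(-t / tau_c)

    p0 = (s[0], s[-1], max(tau[-1] / 5.0, tau[1]))
    try:
        popt, _ = curve_fit(
            model,
            tau,
            s,
            p0=p0,
            bounds=([-1.5, -1.5, 0.0], [1.5, 1.5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    resid = s - model(tau, *popt)
    return DecayFit(
        tau_c=float(popt[2]),
        s0=float(popt[0]),
        s_inf=float(popt[1]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class EnsembleResult:
    """Replicate population runs under one protocol."""

    traces: list
    s_mean: np.ndarray
    tau: np.ndarray
    s_inf_mean: float
    s_inf_sd: float
    seeds: tuple

    def fit(self) -> DecayFit:
        """Exponential fit of the ensemble-mean order parameter."""
        return fit_characteristic_time(self.tau, self.s_mean)


def run_ensemble(
    n_cells: int,
    protocol: StretchProtocol,
    params: ModelParams,
    policy: ReorientationPolicy,
    tau_end: float,
    seeds: Sequence[int],
    table: Optional[AngleSweepResult] = None,
    tail_fraction: float = 0.25,
) -> EnsembleResult:
    """Run one population per seed and aggregate the order parameter.

    The per-seed steady-state order parameter is the tail mean of each
    trace; the spread over seeds (standard deviation) quantifies the
    finite-population noise.
    """
    if table is None:
        table = build_orientation_table(protocol, params, policy)
    traces = [
        simulate_population(
            n_cells, protocol, params, policy, tau_end, seed=int(s), table=table
        )
        for s in seeds
    ]
    s_mean = np.mean([t.s_series for t in traces], axis=0)
    tails = np.array([t.s_tail_mean(tail_fraction) for t in traces])
    return EnsembleResult(
        traces=traces,
        s_mean=s_mean,
        tau=traces[0].tau,
        s_inf_mean=float(tails.mean()),
        s_inf_sd=float(tails.std(ddof=1)) if len(traces) > 1 else 0.0,
        seeds=tuple(int(s) for s in seeds),
    )
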