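"""Single-cell dynamics at fixed orientation.

Integrates the coupled bond/filament kinetics under a stretch protocol,
detects collapse (runaway disassembly, interpreted as detachment), and
computes the long-time average filament density ``zeta_bar`` across
orientations — the quantity whose maximum over the orientation angle marks
the preferred cell alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .core import _STRAIN_FLOOR, XI_FLOOR, effective_strain, filament_force, make_rhs
from .params import ModelParams, StretchProtocol

__all__ = [
    "SolverError",
    "CellTrajectory",
    "AngleSweepResult",
    "integrate_cell",
    "long_time_average_density",
    "angle_sweep",
    "default_theta_grid",
]

#: Frequencies at or below this value (Hz) are treated quasi-statically:
#: the state tracks the instantaneous quasi-equilibrium, so one warm-up
#: period followed by one averaged period suffices.
QUASI_STATIC_HZ = 0.05

#: Load ratio u = zeta/xi beyond which the adhesion is irreversibly in the
#: runaway regime: the elastic penalty then outweighs the reinforcement so
#: strongly that bonds dissociate faster than they can reform, u grows
#: further, and the dissociation rate exp(-G) diverges.  Used to classify
#: a step-size underflow at the collapse singularity as detachment.
_RUNAWAY_U_FACTOR = 3.0

_RTOL = 1.0e-6
_ATOL = 1.0e-9


class SolverError(RuntimeError):
    """The ODE solver failed away from a collapse; distinct from detachment."""


@dataclass
class CellTrajectory:
    """Sampled trajectory of one cell at fixed orientation.

    Densities are held at zero past ``collapse_time`` (collapse is
    absorbing: once the bonds are gone there is nothing to rebuild them at
    this orientation).
    """

    tau: np.ndarray
    xi: np.ndarray
    zeta: np.ndarray
    f_hat: np.ndarray
    theta: float
    collapse_time: Optional[float] = None

    @property
    def collapsed(self) -> bool:
        return self.collapse_time is not None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"tau": self.tau, "xi": self.xi, "zeta": self.zeta, "f_hat": self.f_hat}
        )


def _max_step(protocol: StretchProtocol, theta: float, params: ModelParams) -> float:
    """Step cap resolving the forcing; a zero-effective-strain orientation
    follows the same solver path as a static protocol."""
    eps_a = effective_strain(theta, protocol.amplitude, params.nu)
    if protocol.is_static or abs(eps_a) < _STRAIN_FLOOR:
        return 5.0
    return min(protocol.period / 40.0, 5.0)


def _integrate(
    theta: float,
    protocol: StretchProtocol,
    params: ModelParams,
    xi0: float,
    zeta0: float,
    tau_end: float,
    collapse_threshold: float,
    grace_time: float,
) -> Tuple[list, Optional[float]]:
    """Integrate with collapse detection; return (segments, collapse_time).

    The nascency window ``[0, grace_time]`` runs without the collapse
    event: with ``zeta0 = 0`` the bond density necessarily dips to
    ~1/(1+exp(-g0)) before the stress-fiber reinforcement assembles, and
    that dip must not be mistaken for a collapse.  Afterwards collapse is
    declared at the first downward crossing of ``collapse_threshold``, or
    at a step-size underflow with the load ratio in the runaway regime
    (the dissociation rate diverges there and no explicit step survives).
    """
    rhs = make_rhs(theta, protocol, params)
    max_step = _max_step(protocol, theta, params)
    grace = min(grace_time, tau_end)
    sol_a = solve_ivp(
        rhs,
        (0.0, grace),
        [xi0, zeta0],
        method="RK45",
        rtol=_RTOL,
        atol=_ATOL,
        max_step=min(max_step, 1.0),
        dense_output=True,
    )
    if sol_a.status == -1:
        raise SolverError(
            f"integration failed during nascency at theta={theta:g}: {sol_a.message}"
        )
    segments = [sol_a]
    if float(sol_a.y[0, -1]) < collapse_threshold:
        # Never recovered from the nascent dip: unstable from the outset.
        return segments, grace
    if grace >= tau_end:
        return segments, None

    def crossing(t, y):
        return y[0] - collapse_threshold

    crossing.terminal = True
    crossing.direction = -1
    sol_b = solve_ivp(
        rhs,
        (grace, tau_end),
        sol_a.y[:, -1],
        method="RK45",
        rtol=_RTOL,
        atol=_ATOL,
        max_step=max_step,
        events=crossing,
        dense_output=True,
    )
    segments.append(sol_b)
    if sol_b.t_events[0].size:
        return segments, float(sol_b.t_events[0][0])
    if sol_b.status == -1:
        xi_f, zeta_f = sol_b.y[:, -1]
        u_f = zeta_f / max(xi_f, XI_FLOOR)
        if xi_f < collapse_threshold or u_f > _RUNAWAY_U_FACTOR * params.u_ss:
            return segments, float(sol_b.t[-1])
        raise SolverError(
            f"integration failed at theta={theta:g}, tau={sol_b.t[-1]:g} "
            f"(xi={xi_f:g}, u={u_f:g}): {sol_b.message}"
        )
    return segments, None


def _eval_segments(segments, times: np.ndarray) -> np.ndarray:
    """Evaluate the dense solution on a grid (2 x n array)."""
    out = np.empty((2, times.size))
    bound = segments[0].t[-1]
    for i, t in enumerate(times):
        seg = segments[0] if t <= bound else segments[-1]
        out[:, i] = seg.sol(min(t, seg.t[-1]))
    return out


def integrate_cell(
    theta: float,
    protocol: StretchProtocol,
    params: ModelParams,
    xi0: float = 0.3,
    zeta0: float = 0.0,
    tau_end: float = 500.0,
    collapse_threshold: float = 0.02,
    grace_time: float = 10.0,
    n_samples: int = 1001,
) -> CellTrajectory:
    """Integrate one cell's kinetics from attachment to ``tau_end``.

    Attachment starts with nascent bonds only (``zeta0 = 0`` by default;
    stress fibers assemble afterwards) and an unloaded Maxwell branch.
    Returns the trajectory sampled on a uniform grid; densities are held
    at zero past the collapse time of an unstable orientation.
    """
    if not 0.0 < xi0 <= 1.0:
        raise ValueError(f"xi0 must lie in (0, 1], got {xi0}")
    if zeta0 < 0.0:
        raise ValueError(f"zeta0 must be non-negative, got {zeta0}")
    if not tau_end > 0.0:
        raise ValueError(f"tau_end must be positive, got {tau_end}")
    segments, collapse_time = _integrate(
        theta, protocol, params, xi0, zeta0, tau_end, collapse_threshold, grace_time
    )
    tau = np.linspace(0.0, tau_end, n_samples)
    y = _eval_segments(segments, tau)
    xi = np.clip(y[0], 0.0, None)
    zeta = np.clip(y[1], 0.0, None)
    f_hat = np.asarray(filament_force(tau, protocol, theta, params, 0.0), dtype=float)
    if f_hat.ndim == 0:
        f_hat = np.full_like(tau, float(f_hat))
    if collapse_time is not None:
        gone = tau >= collapse_time
        xi[gone] = 0.0
        zeta[gone] = 0.0
        f_hat[gone] = 0.0
    return CellTrajectory(tau, xi, zeta, f_hat, theta, collapse_time)


def long_time_average_density(
    theta: float,
    protocol: StretchProtocol,
    params: ModelParams,
    xi0: float = 0.3,
    zeta0: float = 0.0,
    tau_end: float = 500.0,
    collapse_threshold: float = 0.02,
    grace_time: float = 10.0,
    transient_discard: float = 200.0,
):
    """Long-time average filament density ``zeta_bar`` at one orientation.

    Returns ``(zeta_bar, collapse_time)``.  A collapsed orientation scores
    ``zeta_bar = 0``.  For a static protocol the converged density is
    returned.  For cyclic protocols the mean of ``zeta`` is taken over an
    integer number of complete stretch cycles after discarding the larger
    of ``transient_discard`` and ten periods; quasi-static protocols
    (<= 0.05 Hz, periods of hundreds to thousands of time units) are
    integrated for two periods and averaged over the second, since the
    state then tracks the instantaneous quasi-equilibrium.
    """
    quasi_static = (not protocol.is_static) and protocol.frequency_hz <= QUASI_STATIC_HZ
    if quasi_static:
        tau_end = 2.0 * protocol.period
    segments, collapse_time = _integrate(
        theta, protocol, params, xi0, zeta0, tau_end, collapse_threshold, grace_time
    )
    if collapse_time is not None:
        return 0.0, collapse_time
    if protocol.is_static:
        return float(segments[-1].y[1, -1]), None
    period = protocol.period
    if quasi_static:
        lo, hi = period, 2.0 * period
    else:
        discard = max(transient_discard, 10.0 * period)
        n_cycles = int((tau_end - discard) // period)
        if n_cycles < 1:
            raise ValueError(
                f"tau_end={tau_end:g} leaves no complete cycle after the "
                f"transient discard ({discard:g}); extend the horizon"
            )
        lo, hi = tau_end - n_cycles * period, tau_end
    times = np.linspace(lo, hi, max(1000, int(40 * (hi - lo) / period)))
    zeta = _eval_segments(segments, times)[1]
    return float(np.trapezoid(zeta, times) / (hi - lo)), None


@dataclass
class AngleSweepResult:
    """Per-orientation long-time filament density and stability."""

    theta: np.ndarray
    zeta_bar: np.ndarray
    stable: np.ndarray
    collapse_time: np.ndarray
    protocol: StretchProtocol = None
    params: ModelParams = None

    @property
    def preferred_theta(self) -> float:
        """Orientation maximizing the long-time filament density.

        The model's alignment hypothesis: cells end up oriented where the
        stress-fiber density — and hence cell-substrate attachment — is
        largest.
        """
        return float(self.theta[int(np.argmax(self.zeta_bar))])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta_deg": np.rad2deg(self.theta),
                "zeta_bar": self.zeta_bar,
                "stable": self.stable,
                "collapse_time": self.collapse_time,
            }
        )

    def lookup(self, theta: float):
        """Nearest-grid (stable, collapse_time) for an arbitrary angle.

        The model is even and pi-periodic in the orientation, so the angle
        is folded onto [0, pi/2] first.  ``collapse_time`` is ``None`` for
        a stable orientation.
        """
        folded = abs(math.remainder(theta, math.pi))
        idx = int(np.argmin(np.abs(self.theta - folded)))
        if self.stable[idx]:
            return True, None
        return False, float(self.collapse_time[idx])


def default_theta_grid(step_deg: float = 2.0) -> np.ndarray:
    """Angles 0..90 degrees (inclusive) in radians."""
    return np.deg2rad(np.arange(0.0, 90.0 + 0.5 * step_deg, step_deg))


def angle_sweep(
    protocol: StretchProtocol,
    params: ModelParams,
    thetas: Optional[Sequence[float]] = None,
    **kwargs,
) -> AngleSweepResult:
    """Sweep the long-time average filament density over orientations.

    Keyword arguments are forwarded to :func:`long_time_average_density`
    (initial densities, horizon, collapse threshold).
    """
    thetas = default_theta_grid() if thetas is None else np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("thetas must be non-empty")
    zeta_bar = np.empty(thetas.size)
    collapse = np.full(thetas.size, np.nan)
    stable = np.zeros(thetas.size, dtype=bool)
    for i, th in enumerate(thetas):
        zb, ct = long_time_average_density(float(th), protocol, params, **kwargs)
        zeta_bar[i] = zb
        stable[i] = ct is None
        if ct is not None:
            collapse[i] = ct
    return AngleSweepResult(thetas, zeta_bar, stable, collapse, protocol, params)
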