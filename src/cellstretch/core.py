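"""Normalized model primitives.

The model couples three ingredients:

* first-order kinetics of the receptor-ligand bond density ``xi`` and the
  contracting-filament density ``zeta``,

      dxi/dtau   = (1 - xi) - xi * exp(-G)
      dzeta/dtau = c*xi - d*zeta

  with a Bell-type dissociation rate ``exp(-G)``: the larger the energy
  reduction ``G`` gained by a bond, the slower it dissociates;

* the per-bond energy reduction

      G = g0 + a*u - (beta/s) * (u*F)^2 ,   u = zeta/xi

  combining the bare bond energy ``g0``, reinforcement by plaque proteins
  recruited in proportion to the filament density, and the elastic energy
  stored in the bond-substrate spring under the average per-bond load
  ``u*F`` (all filament forces are shared equally among the bonds);

* a viscoelastic contracting filament: a constant stall force in parallel
  with a Maxwell element (spring ``k_hat`` and dashpot in series), so that
  under cyclic stretch the total normalized force is ``F = 1 + Fv`` with

      dFv/dtau + gamma*Fv = k_hat * d(eps_f)/dtau .

The substrate strain-stiffens above a critical strain ``eps_c`` with a 3/2
power law, which enters through ``s >= 1`` dividing the elastic penalty
(the bond-substrate spring constant is proportional to the substrate
modulus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

from .params import KineticState, ModelParams, StretchProtocol

__all__ = [
    "DetachedCellError",
    "XI_FLOOR",
    "effective_strain",
    "stiffening_factor",
    "filament_force",
    "energy_reduction",
    "kinetics_rhs",
    "steady_state_densities",
    "steady_state_energy",
    "classify_fixed_point",
    "FixedPointReport",
    "find_stability_transition",
]

#: Bond density below which the filament-to-bond ratio is not evaluable;
#: the cell is treated as detached instead.
XI_FLOOR = 1.0e-6

#: Effective strain amplitudes below this are exactly zero stretch: the
#: dynamics at theta = pi/2 (nu = 0) must reduce to the static case on the
#: same solver path, not merely approximately.
_STRAIN_FLOOR = 1.0e-12

#: Cap on -G before exponentiation.  Rates beyond exp(200) are physically
#: indistinguishable from instantaneous, and the cap keeps the solver's
#: error norm finite during a collapse.
_EXP_CAP = 200.0


class DetachedCellError(ValueError):
    """Raised when the bond density is too low to carry the filament load."""


def effective_strain(theta: float, amplitude: float, nu: float = 0.0):
    """Strain amplitude resolved along the cell axis.

    ``eps_a = amplitude * (cos^2 theta - nu * sin^2 theta)``: a cell at
    angle ``theta`` to the stretch axis feels the axial strain reduced by
    the transverse (Poisson) contraction.  Even and pi-periodic in
    ``theta``; negative beyond the zero-strain direction
    ``arctan(1/sqrt(nu))`` when ``nu > 0``.
    """
    theta = np.asarray(theta, dtype=float)
    ct, st = np.cos(theta), np.sin(theta)
    out = amplitude * (ct * ct - nu * st * st)
    return float(out) if out.ndim == 0 else out


def stiffening_factor(eps, eps_c: float):
    """Strain-stiffening factor s >= 1 of the substrate modulus.

    ``s = 1`` below the critical strain and ``(|eps|/eps_c)**1.5`` above it
    (continuous at the threshold).  Depends on the strain magnitude only;
    ``eps_c = inf`` encodes a linear substrate.
    """
    if not eps_c > 0:
        raise ValueError(f"eps_c must be positive, got {eps_c}")
    ae = np.abs(np.asarray(eps, dtype=float))
    if math.isinf(eps_c):
        out = np.ones_like(ae)
    else:
        out = np.where(ae < eps_c, 1.0, (ae / eps_c) ** 1.5)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# Maxwell branch of the filament force
# ----------------------------------------------------------------------

def _steady_coefficients(eps_a: float, omega: float, params: ModelParams) -> Tuple[float, float]:
    """(sin, cos) coefficients of the steady-periodic Maxwell force.

    Solves ``Fv' + gamma*Fv = k_hat * eps_f'`` for the protocol waveform.
    For the offset waveform ``eps_f = (eps_a/2)(1 - cos(Omega tau))``; for
    the signed waveform ``eps_f = eps_a sin(Omega tau)``.
    """
    g, k = params.gamma, params.k_hat
    denom = g * g + omega * omega
    return (
        k * 0.5 * eps_a * g * omega / denom,
        -k * 0.5 * eps_a * omega * omega / denom,
    )


def _steady_coefficients_signed(eps_a: float, omega: float, params: ModelParams) -> Tuple[float, float]:
    g, k = params.gamma, params.k_hat
    denom = g * g + omega * omega
    return (
        k * eps_a * omega * omega / denom,
        k * eps_a * g * omega / denom,
    )


def filament_force(
    tau,
    protocol: StretchProtocol,
    theta: float,
    params: ModelParams,
    initial_viscoelastic_force: float = 0.0,
    mode: str = "transient",
):
    """Total normalized force ``F(tau) = 1 + Fv(tau)`` in one filament.

    ``mode="transient"`` is the initial-value solution with
    ``Fv(0) = initial_viscoelastic_force`` (a freshly attached filament
    starts unloaded, ``Fv(0) = 0``); the transient decays at rate
    ``gamma``.  ``mode="steady"`` is the steady-periodic closed form.  A
    static protocol, or one with zero effective strain at this
    orientation, gives exactly ``F = 1`` for the default initial value:
    given enough time the filament relaxes any held stretch and only the
    stall force remains.
    """
    tau = np.asarray(tau, dtype=float)
    eps_a = effective_strain(theta, protocol.amplitude, params.nu)
    omega = protocol.omega
    fv0 = initial_viscoelastic_force
    if omega == 0.0 or abs(eps_a) < _STRAIN_FLOOR:
        fv = fv0 * np.exp(-params.gamma * tau) if mode == "transient" else 0.0 * tau
        out = 1.0 + fv
        return float(out) if out.ndim == 0 else out
    if protocol.waveform == "signed":
        cs, cc = _steady_coefficients_signed(eps_a, omega, params)
    else:
        cs, cc = _steady_coefficients(eps_a, omega, params)
    steady = cs * np.sin(omega * tau) + cc * np.cos(omega * tau)
    if mode == "steady":
        out = 1.0 + steady
    elif mode == "transient":
        out = 1.0 + steady + (fv0 - cc) * np.exp(-params.gamma * tau)
    else:
        raise ValueError(f"mode must be 'transient' or 'steady', got {mode!r}")
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# Bond energy and kinetics
# ----------------------------------------------------------------------

def energy_reduction(
    xi: float,
    zeta: float,
    f_hat: float,
    s: float,
    params: ModelParams,
) -> float:
    """Energy reduction G of a single bond in the adhesion cluster.

    ``G = g0 + a*u - (beta/s)*(u*f_hat)^2`` with the filament-to-bond ratio
    ``u = zeta/xi``.  Returns ``g0`` exactly when no filaments are present.
    Raises :class:`DetachedCellError` when ``xi <= XI_FLOOR`` while
    ``zeta > 0``: the load per bond is then unbounded and the caller must
    treat the cell as detached.
    """
    if zeta == 0.0:
        return params.g0
    if xi <= XI_FLOOR:
        raise DetachedCellError(
            f"bond density xi={xi:g} below floor {XI_FLOOR:g} with zeta={zeta:g}"
        )
    if s < 1.0:
        raise ValueError(f"stiffening factor must be >= 1, got {s}")
    u = zeta / xi
    return params.g0 + params.a * u - (params.beta / s) * (u * f_hat) ** 2


def kinetics_rhs(
    state: KineticState,
    tau: float,
    theta: float,
    protocol: StretchProtocol,
    params: ModelParams,
) -> Tuple[float, float]:
    """Time derivatives (dxi/dtau, dzeta/dtau) of the coupled kinetics.

    The instantaneous filament force (transient Maxwell solution started
    from ``state.fv`` at tau=0) and stiffening factor (on the magnitude of
    the instantaneous fiber-axis strain) enter the bond energy.
    """
    eps_a = effective_strain(theta, protocol.amplitude, params.nu)
    eps = float(protocol.strain(tau, eps_a))
    s = stiffening_factor(eps, params.eps_c)
    f_hat = filament_force(tau, protocol, theta, params, state.fv, mode="transient")
    g = energy_reduction(state.xi, state.zeta, f_hat, s, params)
    dxi = (1.0 - state.xi) - state.xi * math.exp(min(-g, _EXP_CAP))
    dzeta = params.c * state.xi - params.d * state.zeta
    return dxi, dzeta


def make_rhs(
    theta: float,
    protocol: StretchProtocol,
    params: ModelParams,
    fv0: float = 0.0,
) -> Callable[[float, np.ndarray], list]:
    """Scalar-math right-hand side ``f(tau, [xi, zeta])`` for the solver.

    Precomputes the effective strain and Maxwell coefficients; the hot loop
    uses plain ``math`` calls.
    """
    eps_a = effective_strain(theta, protocol.amplitude, params.nu)
    omega = protocol.omega
    c, d, g0, a, beta = params.c, params.d, params.g0, params.a, params.beta
    eps_c, gamma = params.eps_c, params.gamma
    static = omega == 0.0 or abs(eps_a) < _STRAIN_FLOOR
    signed = protocol.waveform == "signed"
    if static:
        cs = cc = 0.0
    elif signed:
        cs, cc = _steady_coefficients_signed(eps_a, omega, params)
    else:
        cs, cc = _steady_coefficients(eps_a, omega, params)
    half_amp = 0.5 * eps_a

    def rhs(tau: float, y) -> list:
        xi, zeta = y
        if static:
            s = 1.0
            f = 1.0 + fv0 * math.exp(-gamma * tau)
        else:
            w = omega * tau
            sw, cw = math.sin(w), math.cos(w)
            eps = eps_a * sw if signed else half_amp * (1.0 - cw)
            ae = abs(eps)
            s = 1.0 if ae < eps_c else (ae / eps_c) ** 1.5
            f = 1.0 + cs * sw + cc * cw + (fv0 - cc) * math.exp(-gamma * tau)
        u = zeta / xi if xi > XI_FLOOR else zeta / XI_FLOOR
        g = g0 + a * u - (beta / s) * (u * f) ** 2
        return [
            (1.0 - xi) - xi * math.exp(min(-g, _EXP_CAP)),
            c * xi - d * zeta,
        ]

    return rhs


# ----------------------------------------------------------------------
# Static steady state and its stability
# ----------------------------------------------------------------------

def steady_state_energy(params: ModelParams) -> float:
    """Bond energy reduction at the static fixed point (F = 1, s = 1)."""
    u = params.u_ss
    return params.g0 + params.a * u - params.beta * u * u


def steady_state_densities(params: ModelParams) -> Tuple[float, float]:
    """Closed-form static steady state (xi_ss, zeta_ss).

    With ``u_ss = c/d`` and ``G_ss = g0 + a*u_ss - beta*u_ss^2`` the bond
    balance gives the logistic form ``xi_ss = 1/(1 + exp(-G_ss))`` and
    ``zeta_ss = u_ss * xi_ss``.  ``xi_ss`` decreases monotonically with the
    substrate compliance ``beta``.
    """
    g_ss = steady_state_energy(params)
    xi_ss = 1.0 / (1.0 + math.exp(min(-g_ss, _EXP_CAP)))
    return xi_ss, params.u_ss * xi_ss


@dataclass(frozen=True)
class FixedPointReport:
    """Stability of the static fixed point.

    ``label`` is set by the sign of the largest real part of the numerical
    Jacobian eigenvalues.  ``beta_star = a*d/(2c)`` is the compliance at
    which the net density feedback on the bond energy, ``dG/du = a -
    2*beta*u_ss``, changes sign — the reinforcement/penalty criterion; the
    eigenvalue crossing itself occurs at a somewhat larger compliance.
    """

    label: str
    eigenvalues: tuple
    beta_star: float
    xi_ss: float
    zeta_ss: float

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def classify_fixed_point(params: ModelParams, delta: float = 1.0e-7) -> FixedPointReport:
    """Classify the static fixed point via central-difference Jacobian."""
    xi_ss, zeta_ss = steady_state_densities(params)
    protocol = StretchProtocol(amplitude=0.0, frequency_hz=0.0, kon_per_s=params.kon_per_s)
    rhs = make_rhs(0.0, protocol, params)
    y0 = np.array([xi_ss, zeta_ss])
    jac = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = delta
        hi = np.asarray(rhs(0.0, y0 + step))
        lo = np.asarray(rhs(0.0, y0 - step))
        jac[:, j] = (hi - lo) / (2.0 * delta)
    eig = np.linalg.eigvals(jac)
    label = "stable" if float(eig.real.max()) < 0.0 else "unstable"
    beta_star = params.a * params.d / (2.0 * params.c)
    return FixedPointReport(label, tuple(eig), beta_star, xi_ss, zeta_ss)


def find_stability_transition(
    params: ModelParams,
    beta_min: float = 0.5,
    beta_max: float = 1.5,
    tol: float = 1.0e-3,
) -> float:
    """Compliance at which the fixed-point label flips, by bisection."""
    lo, hi = beta_min, beta_max
    if not classify_fixed_point(params.replace(beta=lo)).stable:
        raise ValueError(f"fixed point already unstable at beta={lo}")
    if classify_fixed_point(params.replace(beta=hi)).stable:
        raise ValueError(f"fixed point still stable at beta={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify_fixed_point(params.replace(beta=mid)).stable:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
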