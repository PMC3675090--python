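"""Parameter containers for the coupled focal-adhesion / stress-fiber model.

All quantities are dimensionless.  Time is measured in units of the
receptor-ligand bond association time 1/k_on (one normalized time unit
corresponds to 0.16 s for the default ``kon_per_s``), energies in units of
k_B·T, forces in units of the myosin stall force of a single contracting
filament, and densities relative to their saturation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = ["ModelParams", "StretchProtocol", "ReorientationPolicy", "KineticState"]

Waveform = Literal["offset", "signed"]


@dataclass(frozen=True)
class ModelParams:
    """Normalized constants of the mechanochemical model.

    Parameters
    ----------
    c, d : float
        Association and dissociation rates of contracting filaments
        (stress-fiber kinetics), normalized by the bond association rate.
        Their ratio ``u_ss = c/d`` is the steady-state filament-to-bond
        density ratio.  ``c = 0.1`` models Rho-inhibited cells.
    g0 : float
        Energy reduction gained by recruiting a single receptor-ligand bond
        in the absence of stress fibers.  Negative: membrane fluctuations
        and glycocalyx repulsion make bare bonds unstable.
    a : float
        Interaction energy between a bond and one reinforcing plaque
        protein, whose density is proportional to the filament density.
    beta : float
        Substrate-compliance parameter; larger values mean a softer
        bond-substrate system (physical estimates span 0.03-3).
    k_hat : float
        Stress-fiber spring constant normalized by the filament stall force.
    gamma : float
        Ratio of the elastic to the viscous coefficient of a filament; the
        relaxation rate of the Maxwell branch, per normalized time.
    eps_c : float
        Critical strain above which the substrate strain-stiffens with a
        3/2 power law.  ``math.inf`` encodes a linearly elastic substrate.
    nu : float
        Poisson ratio of the substrate, in [0, 0.5].
    kon_per_s : float
        Bond association rate in 1/s; maps physical stretching frequency to
        the normalized angular frequency ``Omega = 2*pi*f / kon_per_s``.
    """

    c: float = 0.2
    d: float = 0.1
    g0: float = -5.0
    a: float = 3.5
    beta: float = 0.6
    k_hat: float = 15.0
    gamma: float = 0.5
    eps_c: float = 0.04
    nu: float = 0.0
    kon_per_s: float = 6.25

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if self.k_hat < 0:
            raise ValueError(f"k_hat must be non-negative, got {self.k_hat}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.eps_c > 0:
            raise ValueError(f"eps_c must be positive, got {self.eps_c}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"nu must lie in [0, 0.5], got {self.nu}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not self.kon_per_s > 0:
            raise ValueError(f"kon_per_s must be positive, got {self.kon_per_s}")

    @property
    def u_ss(self) -> float:
        """Steady-state filament-to-bond density ratio c/d."""
        return self.c / self.d

    @property
    def linear_substrate(self) -> bool:
        return math.isinf(self.eps_c)

    @classmethod
    def rho_inhibited(cls, **overrides) -> "ModelParams":
        """Defaults for Rho-inhibited cells (SF association rate halved)."""
        overrides.setdefault("c", 0.1)
        return cls(**overrides)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class StretchProtocol:
    """Cyclic uniaxial stretch applied to the substrate.

    The default waveform ``"offset"`` stretches the substrate from its rest
    length up to the amplitude and back each cycle,
    ``eps(tau) = (amplitude/2)*(1 - cos(Omega*tau))``, as in stretch-chamber
    experiments.  ``"signed"`` is the symmetric sinusoid
    ``amplitude*sin(Omega*tau)``.

    ``frequency_hz = 0`` (or zero amplitude) is a static substrate.
    """

    amplitude: float = 0.0
    frequency_hz: float = 0.0
    waveform: Waveform = "offset"
    kon_per_s: float = 6.25

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.frequency_hz < 0:
            raise ValueError(f"frequency_hz must be non-negative, got {self.frequency_hz}")
        if self.waveform not in ("offset", "signed"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not self.kon_per_s > 0:
            raise ValueError(f"kon_per_s must be positive, got {self.kon_per_s}")

    @property
    def omega(self) -> float:
        """Normalized angular frequency Omega = 2*pi*f / kon_per_s."""
        return 2.0 * math.pi * self.frequency_hz / self.kon_per_s

    @property
    def is_static(self) -> bool:
        return self.omega == 0.0 or self.amplitude == 0.0

    @property
    def period(self) -> float:
        """Stretch period in normalized time (inf for a static protocol)."""
        return math.inf if self.is_static else 2.0 * math.pi / self.omega

    def strain(self, tau, eps_a: float):
        """Instantaneous fiber-axis strain for an effective amplitude eps_a."""
        import numpy as np

        if self.is_static:
            return np.zeros_like(np.asarray(tau, dtype=float)) + 0.0
        if self.waveform == "signed":
            return eps_a * np.sin(self.omega * np.asarray(tau, dtype=float))
        return 0.5 * eps_a * (1.0 - np.cos(self.omega * np.asarray(tau, dtype=float)))


@dataclass(frozen=True)
class ReorientationPolicy:
    """Knobs of the whole-cell reorientation search loop.

    ``t0`` is the nucleation time of a nascent focal complex (the hop
    interval), ``dr`` the rotational diffusion coefficient in rad^2 per
    normalized time, and ``trial_time`` the attached assessment window: a
    cell that survives it without collapsing is considered settled.

    ``xi0``/``zeta0`` are the densities at (re)attachment; bonds nucleate
    first, filaments assemble afterwards.  ``collapse_threshold`` declares
    detachment once the bond density falls below it, but only after
    ``grace_time`` so that the nascent build-up (which transiently passes
    through very low bond densities while the reinforcement assembles) is
    not mistaken for a collapse.  ``table_step_deg`` is the resolution of
    the per-orientation stability table used by the population Monte Carlo.
    """

    t0: float = 0.2
    dr: float = 5.0e-3
    trial_time: float = 500.0
    xi0: float = 0.3
    zeta0: float = 0.0
    collapse_threshold: float = 0.02
    grace_time: float = 10.0
    table_step_deg: float = 0.5
    n_grid: int = 200

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")
        if self.dr < 0:
            raise ValueError(f"dr must be non-negative, got {self.dr}")
        if self.trial_time < 50:
            raise ValueError(
                "trial_time must cover several SF relaxation times (>= 50), "
                f"got {self.trial_time}"
            )
        if not 0 < self.xi0 <= 1:
            raise ValueError(f"xi0 must lie in (0, 1], got {self.xi0}")
        if self.zeta0 < 0:
            raise ValueError(f"zeta0 must be non-negative, got {self.zeta0}")

    def replace(self, **changes) -> "ReorientationPolicy":
        return replace(self, **changes)


@dataclass
class KineticState:
    """Instantaneous state of the coupled bond/filament kinetics.

    ``xi`` is the receptor-ligand bond density (relative to saturation),
    ``zeta`` the contracting-filament density, ``tau`` normalized time and
    ``fv`` the viscoelastic (Maxwell-branch) part of the filament force.
    """

    xi: float
    zeta: float
    tau: float = 0.0
    fv: float = 0.0
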