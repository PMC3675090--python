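"""Unit tests of the normalized model primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from cellstretch import (
    DetachedCellError,
    KineticState,
    ModelParams,
    StretchProtocol,
    classify_fixed_point,
    effective_strain,
    energy_reduction,
    filament_force,
    find_stability_transition,
    kinetics_rhs,
    steady_state_densities,
    steady_state_energy,
    stiffening_factor,
)


class TestEffectiveStrain:
    @pytest.mark.parametrize(
        "theta, amplitude, nu, expected",
        [
            (0.0, 0.1, 0.0, 0.1),
            (math.pi / 2, 0.1, 0.0, 0.0),
            (math.pi / 2, 0.1, 0.5, -0.05),
            (math.pi / 4, 0.2, 0.0, 0.1),
        ],
    )
    def test_examples(self, theta, amplitude, nu, expected):
        assert effective_strain(theta, amplitude, nu) == pytest.approx(expected, abs=1e-12)

    def test_zero_strain_direction_is_arctan_sqrt2(self):
        """For nu=1/2 the strain vanishes where cos^2 = nu*sin^2."""
        root = bisect(lambda th: effective_strain(th, 0.1, 0.5), 0.0 + 1e-9, math.pi / 2)
        assert root == pytest.approx(math.atan(math.sqrt(2.0)), abs=1e-9)
        assert math.degrees(root) == pytest.approx(54.7356, abs=1e-3)

    @given(
        theta=st.floats(-10.0, 10.0),
        amplitude=st.floats(0.0, 0.5),
        nu=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_even_and_pi_periodic(self, theta, amplitude, nu):
        ref = effective_strain(theta, amplitude, nu)
        assert effective_strain(-theta, amplitude, nu) == pytest.approx(ref, abs=1e-9)
        assert effective_strain(theta + math.pi, amplitude, nu) == pytest.approx(ref, abs=1e-9)


class TestStiffening:
    @pytest.mark.parametrize(
        "eps, eps_c, expected",
        [
            (0.02, 0.04, 1.0),
            (0.04, 0.04, 1.0),
            (0.16, 0.04, 8.0),  # (4)^{3/2}
            (0.16, math.inf, 1.0),
            (-0.16, 0.04, 8.0),  # magnitude of strain
        ],
    )
    def test_examples(self, eps, eps_c, expected):
        assert stiffening_factor(eps, eps_c) == pytest.approx(expected)

    @given(eps=st.floats(-1.0, 1.0), eps_c=st.floats(1e-3, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_even_and_at_least_one(self, eps, eps_c):
        s = stiffening_factor(eps, eps_c)
        assert s >= 1.0
        assert stiffening_factor(-eps, eps_c) == s

    def test_continuous_at_threshold(self):
        eps_c = 0.04
        below = stiffening_factor(eps_c * (1 - 1e-12), eps_c)
        above = stiffening_factor(eps_c * (1 + 1e-12), eps_c)
        assert above - below == pytest.approx(0.0, abs=1e-9)

    def test_requires_positive_threshold(self):
        with pytest.raises(ValueError):
            stiffening_factor(0.1, 0.0)


class TestFilamentForce:
    """The Maxwell-branch force against an independent ODE integration."""

    def test_static_force_is_exactly_one(self, params, static_protocol):
        tau = np.linspace(0.0, 100.0, 11)
        assert np.all(filament_force(tau, static_protocol, 0.3, params) == 1.0)

    def test_zero_effective_strain_is_static(self, params, protocol_10_1hz):
        f = filament_force(np.linspace(0, 50, 7), protocol_10_1hz, math.pi / 2, params)
        assert np.all(f == 1.0)

    @pytest.mark.parametrize("waveform", ["offset", "signed"])
    def test_transient_matches_numerical_integration(self, params, waveform):
        """Initial-value closed form vs scipy integration of the Maxwell ODE."""
        protocol = StretchProtocol(amplitude=0.10, frequency_hz=1.0, waveform=waveform)
        eps_a = effective_strain(0.0, protocol.amplitude, params.nu)
        om, k, g = protocol.omega, params.k_hat, params.gamma

        def strain_rate(t):
            if waveform == "signed":
                return eps_a * om * math.cos(om * t)
            return 0.5 * eps_a * om * math.sin(om * t)

        sol = solve_ivp(
            lambda t, y: [k * strain_rate(t) - g * y[0]],
            (0.0, 100.0),
            [0.0],
            rtol=1e-11,
            atol=1e-13,
            dense_output=True,
        )
        tau = np.linspace(0.0, 100.0, 401)
        ours = filament_force(tau, protocol, 0.0, params, 0.0, mode="transient")
        oracle = 1.0 + sol.sol(tau)[0]
        assert np.max(np.abs(ours - oracle)) < 1e-6

    def test_steady_matches_transient_after_decay(self, params, protocol_10_1hz):
        tau = np.linspace(20.0 / params.gamma, 20.0 / params.gamma + 50.0, 500)
        tr = filament_force(tau, protocol_10_1hz, 0.0, params, 0.0, mode="transient")
        ss = filament_force(tau, protocol_10_1hz, 0.0, params, mode="steady")
        assert np.max(np.abs(tr - ss)) < 1e-6

    def test_steady_oscillation_amplitude(self, params, protocol_10_1hz):
        """Amplitude k_hat*(eps_a/2)*Omega/sqrt(gamma^2+Omega^2) for the offset stretch."""
        om, g = protocol_10_1hz.omega, params.gamma
        expected = params.k_hat * 0.05 * om / math.hypot(g, om)
        tau = np.linspace(0.0, protocol_10_1hz.period, 4001)
        f = filament_force(tau, protocol_10_1hz, 0.0, params, mode="steady")
        assert 0.5 * (f.max() - f.min()) == pytest.approx(expected, rel=1e-6)

    def test_high_frequency_limit_is_spring_dominated(self, params):
        protocol = StretchProtocol(amplitude=0.10, frequency_hz=1e6)
        tau = np.linspace(0.0, protocol.period, 4001)
        f = filament_force(tau, protocol, 0.0, params, mode="steady")
        assert 0.5 * (f.max() - f.min()) == pytest.approx(params.k_hat * 0.05, rel=1e-6)


class TestEnergyReduction:
    def test_no_filaments_gives_bare_bond_energy(self, params):
        assert energy_reduction(0.7, 0.0, 1.0, 1.0, params) == params.g0

    def test_direct_evaluation(self, params):
        # u=2: -5 + 3.5*2 - 0.6*(2*1)^2 = -0.4
        assert energy_reduction(0.4, 0.8, 1.0, 1.0, params) == pytest.approx(-0.4)
        # u=1: -5 + 3.5 - 0.6 = -2.1
        assert energy_reduction(0.5, 0.5, 1.0, 1.0, params) == pytest.approx(-2.1)

    def test_stiffening_relieves_the_penalty(self, params):
        soft = energy_reduction(0.4, 0.8, 1.0, 1.0, params)
        stiff = energy_reduction(0.4, 0.8, 1.0, 4.0, params)
        assert stiff > soft

    def test_detached_state_is_signalled(self, params):
        with pytest.raises(DetachedCellError):
            energy_reduction(1e-9, 0.5, 1.0, 1.0, params)

    def test_invalid_stiffening_rejected(self, params):
        with pytest.raises(ValueError):
            energy_reduction(0.4, 0.8, 1.0, 0.5, params)


class TestKinetics:
    def test_saturated_bonds_can_only_dissociate(self, params, static_protocol):
        state = KineticState(xi=1.0, zeta=0.5)
        dxi, _ = kinetics_rhs(state, 0.0, 0.0, static_protocol, params)
        g = energy_reduction(1.0, 0.5, 1.0, 1.0, params)
        assert dxi == pytest.approx(-math.exp(-g))
        assert dxi <= 0.0

    def test_fixed_point_has_zero_derivatives(self, params, static_protocol):
        xi_ss, zeta_ss = steady_state_densities(params)
        dxi, dzeta = kinetics_rhs(
            KineticState(xi=xi_ss, zeta=zeta_ss), 0.0, 0.0, static_protocol, params
        )
        assert abs(dxi) < 1e-12
        assert abs(dzeta) < 1e-12

    def test_quasi_steady_filament_ratio(self, params, static_protocol):
        xi = 0.37
        state = KineticState(xi=xi, zeta=params.u_ss * xi)
        _, dzeta = kinetics_rhs(state, 0.0, 0.0, static_protocol, params)
        assert dzeta == pytest.approx(0.0, abs=1e-14)


class TestSteadyState:
    def test_default_compliance(self, params):
        xi_ss, zeta_ss = steady_state_densities(params)
        assert steady_state_energy(params) == pytest.approx(-0.4)
        assert xi_ss == pytest.approx(1.0 / (1.0 + math.exp(0.4)), rel=1e-12)
        assert xi_ss == pytest.approx(0.401, abs=5e-4)
        assert zeta_ss == pytest.approx(0.803, abs=2e-3)

    def test_rigid_substrate(self, params):
        xi_ss, _ = steady_state_densities(params.replace(beta=0.0))
        assert xi_ss == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=1e-12)
        assert xi_ss == pytest.approx(0.881, abs=5e-4)

    def test_rho_inhibited(self, rho_params):
        xi_ss, zeta_ss = steady_state_densities(rho_params)
        assert rho_params.u_ss == 1.0
        assert steady_state_energy(rho_params) == pytest.approx(-2.1)
        assert xi_ss == pytest.approx(0.109, abs=5e-4)
        assert zeta_ss == pytest.approx(xi_ss)

    def test_monotone_decreasing_in_compliance(self, params):
        betas = np.linspace(0.0, 3.0, 61)
        xis = [steady_state_densities(params.replace(beta=float(b)))[0] for b in betas]
        assert np.all(np.diff(xis) < 0.0)


class TestFixedPointStability:
    def test_stiff_substrate_is_stable(self, params):
        rep = classify_fixed_point(params)
        assert rep.stable
        assert max(ev.real for ev in rep.eigenvalues) < 0.0

    def test_soft_substrate_is_unstable(self, params):
        rep = classify_fixed_point(params.replace(beta=1.1))
        assert not rep.stable

    def test_feedback_compliance_threshold(self, params):
        """dG/du changes sign at beta* = a*d/(2c) = 0.875."""
        assert classify_fixed_point(params).beta_star == pytest.approx(0.875)

    def test_eigenvalue_crossing_location(self, params):
        """The numeric stable->unstable flip is a Hopf bifurcation near beta=1.

        The determinant of the Jacobian, d*(1+exp(-G_ss)), is positive for
        every compliance (the dG/du contribution cancels because
        u_ss = c/d), so the fixed point loses stability only through the
        trace — at a compliance somewhat above the feedback threshold
        beta*, and close to 1 for the default kinetics.
        """
        crossing = find_stability_transition(params)
        assert 0.95 < crossing < 1.1

    def test_transition_scan_validates_bracket(self, params):
        with pytest.raises(ValueError):
            find_stability_transition(params, beta_min=1.2, beta_max=1.5)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"c": 0.0},
            {"d": -0.1},
            {"gamma": 0.0},
            {"eps_c": -1.0},
            {"nu": 0.7},
            {"beta": -0.1},
            {"kon_per_s": 0.0},
        ],
    )
    def test_invalid_model_params(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            StretchProtocol(amplitude=-0.1)
        with pytest.raises(ValueError):
            StretchProtocol(waveform="square")

    def test_omega_conversion(self):
        protocol = StretchProtocol(amplitude=0.1, frequency_hz=1.0, kon_per_s=6.25)
        assert protocol.omega == pytest.approx(2.0 * math.pi / 6.25)
        assert protocol.omega == pytest.approx(1.005, abs=1e-3)
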