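"""Closed-form steady-state solutions against independent references.

The independent references here are deliberately written from different
numerics than the library: a banded finite-difference boundary-value
solve for the committor, and the constant-field flux expression coded
directly for flat profiles.
"""

import numpy as np
import pytest

from edchannel import (
    AppliedVoltage,
    beta,
    exact_committor,
    exact_flux,
    exact_iv_curve,
    exact_one_sided_density,
    exact_one_sided_fluxes,
    make_synthetic_pmf,
    solve_steady_state,
    total_energy,
    transition_state,
)
from edchannel.constants import KCAL_MOL_PER_E_MV


def fd_committor(surface, voltage, n=4001):
    """Independent committor: finite-difference solve of ∇·(e^{-βE}∇P) = 0."""
    from scipy.linalg import solve_banded

    z = np.linspace(surface.z_min, surface.z_max, n)
    A = np.interp(z, surface.z, surface.A)
    E = A + surface.q * KCAL_MOL_PER_E_MV * voltage.profile(z)
    b = surface.beta
    wgt = np.exp(-b * 0.5 * (E[:-1] + E[1:]) + b * E.min())
    ab = np.zeros((3, n))
    ab[1, 1:-1] = -(wgt[:-1] + wgt[1:])
    ab[0, 2:] = wgt[1:]
    ab[2, :-2] = wgt[:-1]
    ab[1, 0] = ab[1, -1] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    P = solve_banded((1, 1), ab, rhs)
    return z, P


def test_committor_boundary_values_and_monotonicity(mouth_barriers):
    v = AppliedVoltage.full_window(mouth_barriers, 70.0)
    P = exact_committor(mouth_barriers, v)
    assert P[0] == 0.0
    assert P[-1] == pytest.approx(1.0)
    assert np.all(np.diff(P) >= 0)


def test_committor_linear_for_free_diffusion(flat_surface):
    v = AppliedVoltage.full_window(flat_surface, 0.0)
    P = exact_committor(flat_surface, v)
    x = (flat_surface.z - flat_surface.z_min) / flat_surface.length
    np.testing.assert_allclose(P, x, atol=1e-12)


def test_committor_matches_finite_difference_solve():
    s = make_synthetic_pmf("mouth_barriers", n_points=1025)
    v = AppliedVoltage.full_window(s, 120.0)
    zf, Pf = fd_committor(s, v)
    err = np.max(np.abs(np.interp(s.z, zf, Pf) - exact_committor(s, v)))
    assert err < 2e-4


def test_committor_mirror_symmetry(central_barrier):
    """For a symmetric surface at 0 mV, P(z) + P(-z) = 1."""
    v = AppliedVoltage.full_window(central_barrier, 0.0)
    P = exact_committor(central_barrier, v)
    np.testing.assert_allclose(P + P[::-1], 1.0, atol=1e-10)


def test_flux_free_diffusion_closed_form(flat_surface):
    """J = D (ρ_min − ρ_max)/L for a flat profile."""
    v = AppliedVoltage.full_window(flat_surface, 0.0)
    J = exact_flux(flat_surface, v, 2.0, 0.5)
    expected = flat_surface.D * (2.0 - 0.5) / flat_surface.length
    assert J == pytest.approx(expected, rel=1e-12)


def test_flux_constant_field_matches_ghk_form(flat_surface):
    """Flat PMF + boxcar field is the constant-field (GHK) regime.

    The GHK flux for a flat profile, coded independently:
    J = (D u / L) (ρ_min − ρ_max e^{u}) / (e^{u} − 1), where u is the
    dimensionless energy rise βq e ΔV across the channel.
    """
    dv = 80.0
    z = np.linspace(-15.0, 15.0, 4097)
    flat_surface = make_synthetic_pmf("tabulated", z=z, A=np.zeros_like(z))
    v = AppliedVoltage.full_window(flat_surface, dv)
    u = flat_surface.beta * 1.0 * KCAL_MOL_PER_E_MV * dv
    D, L = flat_surface.D, flat_surface.length
    rmin, rmax = 1.3, 0.4
    expected = D * u / L * (rmin - rmax * np.exp(u)) / (np.exp(u) - 1.0)
    J = exact_flux(flat_surface, v, rmin, rmax)
    assert J == pytest.approx(expected, rel=1e-6)


def test_one_sided_fluxes_sum_to_net(mouth_barriers):
    v = AppliedVoltage.full_window(mouth_barriers, -60.0)
    jf, jb = exact_one_sided_fluxes(mouth_barriers, v, 1.2, 0.7)
    assert jf > 0 and jb > 0
    assert jf - jb == pytest.approx(exact_flux(mouth_barriers, v, 1.2, 0.7),
                                    rel=1e-12)


def test_zero_net_flux_at_equilibrium(central_barrier):
    """Equal reservoirs and zero voltage: detailed balance, J = 0."""
    v = AppliedVoltage.full_window(central_barrier, 0.0)
    assert exact_flux(central_barrier, v, 1.0, 1.0) == pytest.approx(0.0, abs=1e-15)


def test_one_sided_density_boundary_behavior(central_barrier):
    v = AppliedVoltage.full_window(central_barrier, 40.0)
    rf = exact_one_sided_density(central_barrier, v, "forward")
    rb = exact_one_sided_density(central_barrier, v, "backward")
    assert rf[0] == pytest.approx(1.0)
    assert rf[-1] == pytest.approx(0.0, abs=1e-12)
    assert rb[-1] == pytest.approx(1.0)
    assert rb[0] == pytest.approx(0.0, abs=1e-12)


def test_one_sided_density_solves_steady_state_equation(central_barrier):
    """−D(ρ' + βρE') must be constant in z and equal to the one-sided flux."""
    s = make_synthetic_pmf("central_barrier", n_points=2049)
    v = AppliedVoltage.full_window(s, 40.0)
    rf = exact_one_sided_density(s, v, "forward")
    E = total_energy(s, v)
    flux = -s.D * (np.gradient(rf, s.z) + s.beta * rf * np.gradient(E, s.z))
    jf, _ = exact_one_sided_fluxes(s, v, 1.0, 1.0)
    interior = slice(10, -10)
    np.testing.assert_allclose(flux[interior], jf, rtol=5e-3)


def test_tall_barrier_no_overflow():
    s = make_synthetic_pmf("tall_barrier", height=40.0)
    v = AppliedVoltage.full_window(s, 100.0)
    sol = solve_steady_state(s, v, 1.0, 1.0)
    assert np.isfinite(sol.J) and np.isfinite(sol.P).all()
    assert sol.J_f > 0


def test_transition_state_center_for_symmetric_surface(central_barrier):
    v = AppliedVoltage.full_window(central_barrier, 0.0)
    assert transition_state(central_barrier, v) == pytest.approx(0.0, abs=1e-9)


def test_transition_state_shifts_against_applied_bias(central_barrier):
    """Raising the energy of the far side moves the isocommittor point there."""
    v_pos = AppliedVoltage.full_window(central_barrier, 150.0)
    assert transition_state(central_barrier, v_pos) > 0.5


def test_exact_iv_curve_consistency(flat_well):
    win = AppliedVoltage.full_window(flat_well, 0.0)
    Vs = np.linspace(-100, 100, 9)
    curve = exact_iv_curve(flat_well, win, Vs, 1.0, 1.0)
    jf, jb = exact_one_sided_fluxes(flat_well, win.at(Vs[2]), 1.0, 1.0)
    assert curve["Jf"][2] == pytest.approx(jf)
    assert curve["Jb"][2] == pytest.approx(jb)
    # cation: positive applied drop opposes forward flux in this convention
    assert curve["J"][0] > 0 > curve["J"][-1]


def test_flux_warns_when_both_reservoirs_empty(flat_well):
    v = AppliedVoltage.full_window(flat_well, 10.0)
    with pytest.warns(UserWarning):
        assert exact_flux(flat_well, v, 0.0, 0.0) == 0.0
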