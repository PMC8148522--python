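"""Closed-form steady-state solutions of the 1D electrodiffusion model.

For overdamped diffusion on a total energy profile ``E(z)`` with constant
diffusivity ``D`` and absorbing boundaries at ``z_min`` and ``z_max``, the
steady-state Smoluchowski (Nernst-Planck) equation

    J = -D dρ/dz - β D ρ dE/dz

admits closed-form quadrature solutions.  These are the ground truth against
which the stochastic estimators and the PMF-reconstruction formulas are
validated, and the "direct calculation at each voltage" comparator for the
reconstructed I-V curves.

All exponentials of ``βE`` are evaluated with the maximum of ``βE``
subtracted so that tall-barrier surfaces do not overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .constants import PA_PER_E_PER_NS
from .profiles import AppliedVoltage, FreeEnergySurface, total_energy

__all__ = [
    "exact_committor",
    "exact_flux",
    "exact_one_sided_density",
    "exact_one_sided_fluxes",
    "exact_iv_curve",
    "transition_state",
    "SteadyStateSolution",
]


def _exp_beta_E(surface: FreeEnergySurface, voltage: AppliedVoltage):
    """Return (exp(βE - max βE), βE, max βE): overflow-safe weights."""
    bE = surface.beta * total_energy(surface, voltage)
    m = float(np.max(bE))
    return np.exp(bE - m), bE, m


def exact_committor(surface: FreeEnergySurface, voltage: AppliedVoltage) -> np.ndarray:
    """Splitting probability P(z): reach z_max before z_min, on the grid.

    P(z) = ∫_{z_min}^{z} e^{βE}/D dz' / ∫_{z_min}^{z_max} e^{βE}/D dz'.
    P is 0 at z_min, 1 at z_max and monotone non-decreasing.
    """
    w, _, _ = _exp_beta_E(surface, voltage)
    phi = cumulative_trapezoid(w, surface.z, initial=0.0)
    return phi / phi[-1]


def transition_state(surface: FreeEnergySurface, voltage: AppliedVoltage) -> float:
    """z at which the committor crosses 1/2 (linear interpolation)."""
    P = exact_committor(surface, voltage)
    i = int(np.searchsorted(P, 0.5))
    i = min(max(i, 1), P.size - 1)
    z0, z1, p0, p1 = surface.z[i - 1], surface.z[i], P[i - 1], P[i]
    if p1 == p0:
        return float(z1)
    return float(z0 + (0.5 - p0) * (z1 - z0) / (p1 - p0))


def exact_flux(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    rho_min: float,
    rho_max: float,
) -> float:
    """Net steady-state flux (events/ns) for boundary line densities (1/Å).

    J = [ρ(z_min) e^{βE(z_min)} − ρ(z_max) e^{βE(z_max)}] / ∫ e^{βE}/D dz.
    """
    if rho_min < 0 or rho_max < 0:
        raise ValueError("boundary densities must be non-negative")
    if rho_min == 0 and rho_max == 0:
        warnings.warn("both boundary densities are zero; J is identically 0")
        return 0.0
    w, bE, m = _exp_beta_E(surface, voltage)
    denom = trapezoid(w / surface.D, surface.z)
    num = rho_min * np.exp(bE[0] - m) - rho_max * np.exp(bE[-1] - m)
    return float(num / denom)


def exact_one_sided_fluxes(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    rho_min: float,
    rho_max: float,
) -> tuple[float, float]:
    """Forward and backward one-sided fluxes (events/ns, both ≥ 0).

    J_f is the flux of ions entering at z_min (absorbing far boundary, so
    ρ_f(z_max)=0); J_b of ions entering at z_max.  J = J_f − J_b.
    """
    w, bE, m = _exp_beta_E(surface, voltage)
    denom = trapezoid(w / surface.D, surface.z)
    jf = rho_min * np.exp(bE[0] - m) / denom
    jb = rho_max * np.exp(bE[-1] - m) / denom
    return float(jf), float(jb)


def exact_one_sided_density(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    direction: str,
) -> np.ndarray:
    """Steady-state one-sided density on the grid, arbitrary normalization.

    forward:  ρ_f(z) ∝ e^{−βE(z)} ∫_z^{z_max} e^{βE}  (vanishes at z_max)
    backward: ρ_b(z) ∝ e^{−βE(z)} ∫_{z_min}^z e^{βE}  (vanishes at z_min)

    Normalized to 1 at the entry boundary (z_min for forward, z_max for
    backward), i.e. unit reservoir density.  With this normalization the
    pair (ρ_f, ρ_b) is mutually consistent with the one-sided fluxes from
    :func:`exact_one_sided_fluxes` at unit boundary densities, as the
    current-weighted density reconstruction requires.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    w, bE, m = _exp_beta_E(surface, voltage)
    phi = cumulative_trapezoid(w, surface.z, initial=0.0)
    if direction == "forward":
        tail = phi[-1] - phi
    else:
        tail = phi
    # e^{-βE} needs its own shift: use min of βE
    m2 = float(np.min(bE))
    rho = np.exp(-(bE - m2)) * tail
    entry = rho[0] if direction == "forward" else rho[-1]
    return rho / entry


@dataclass(frozen=True)
class SteadyStateSolution:
    """Exact solution bundle at one voltage."""

    delta_v: float
    J: float          # net flux, events/ns
    J_f: float
    J_b: float
    I_pA: float       # charge current q*J in pA
    P: np.ndarray     # committor on the grid
    transition_state_z: float


def solve_steady_state(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    rho_min: float,
    rho_max: float,
) -> SteadyStateSolution:
    jf, jb = exact_one_sided_fluxes(surface, voltage, rho_min, rho_max)
    P = exact_committor(surface, voltage)
    return SteadyStateSolution(
        delta_v=voltage.delta_v,
        J=jf - jb,
        J_f=jf,
        J_b=jb,
        I_pA=surface.q * (jf - jb) * PA_PER_E_PER_NS,
        P=P,
        transition_state_z=transition_state(surface, voltage),
    )


def exact_iv_curve(
    surface: FreeEnergySurface,
    voltage_window: AppliedVoltage,
    voltages_mv: np.ndarray,
    rho_min: float,
    rho_max: float,
) -> dict[str, np.ndarray]:
    """Direct I-V curve: exact fluxes at each listed voltage.

    Returns arrays ``V_mV``, ``Jf``, ``Jb``, ``J`` (events/ns) and ``I_pA``.
    ``voltage_window`` supplies the field window [z_a, z_b]; its own
    ``delta_v`` is ignored.
    """
    voltages_mv = np.asarray(voltages_mv, dtype=float)
    jf = np.empty_like(voltages_mv)
    jb = np.empty_like(voltages_mv)
    for i, dv in enumerate(voltages_mv):
        jf[i], jb[i] = exact_one_sided_fluxes(
            surface, voltage_window.at(dv), rho_min, rho_max
        )
    J = jf - jb
    return {
        "V_mV": voltages_mv,
        "Jf": jf,
        "Jb": jb,
        "J": J,
        "I_pA": surface.q * J * PA_PER_E_PER_NS,
    }
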