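"""Current-voltage curves and reversal potentials from one reference voltage.

Taking the ratio of the integrated ED equation at two voltages gives, for
the one-sided currents,

    J_f(ref)/J_f(V) = R(V)
      = 1 + βq (E_V − E_ref) ∫ f(z) exp[βq(V_V(z) − V_ref(z))] dz,

where ``E_V`` denotes the boxcar field strength at drop ``V`` and the
profile ``f`` is built from reference-voltage data either from the
committor, ``f = 1 − P(z)``, or from the one-sided density,
``f = e^{βΔE(z)} ρ_f(z)/ρ_f(z_min)`` (the two agree exactly on
steady-state input; the committor route is statistically the more precise
one, because P comes from both ensembles).  Backward currents pick up the
boundary factor of the integrating factor:

    J_b(V) = J_b(ref) · exp[βq(ΔV_V − ΔV_ref)] / R(V).

At ``V = ref`` both ratios are exactly 1, so the reconstructed curve passes
through the reference point by construction.

Reversal potentials follow by scaling the forward (cis-side, z_min-entry)
fluxes of all ions by the desired concentration ratio ``r`` and locating
the zero of the total charge current; the Goldman-Hodgkin-Katz voltage
equation then converts a two-ion reversal potential into a permeability
(selectivity) ratio and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import brentq

from .constants import KCAL_MOL_PER_E_MV, PA_PER_E_PER_NS, thermal_voltage_mv
from .errors import NumericalBreakdownError
from .estimators import CommittorProfile, CurrentEstimate
from .oracle import exact_committor, exact_one_sided_fluxes
from .profiles import AppliedVoltage, FreeEnergySurface
from .reconstruct import PMFEstimate
from .simulator import EnsembleStats

__all__ = [
    "FProfile",
    "f_profile",
    "current_ratio",
    "current_at_voltage",
    "IVCurve",
    "reconstruct_iv",
    "IonCurrentModel",
    "reversal_potential",
    "ghk_selectivity",
    "ghk_reversal_potential",
    "nernst_potential",
]


@dataclass(frozen=True)
class FProfile:
    """Reference-voltage weighting profile f(z) for the current ratio."""

    z: np.ndarray
    f: np.ndarray
    mode: str  # committor | density


def f_profile(
    surface: FreeEnergySurface,
    ref_voltage: AppliedVoltage,
    *,
    mode: str = "committor",
    committor: CommittorProfile | None = None,
    pmf: PMFEstimate | None = None,
    stats: EnsembleStats | None = None,
) -> FProfile:
    """Build f(z) from reference-voltage estimates.

    ``mode='committor'`` needs ``committor`` (preferably two-sided):
    f = 1 − P.  ``mode='density'`` needs the reconstructed ``pmf`` and the
    forward one-sided ``stats``: f = e^{βΔE} ρ_f/ρ_f(ref bin).  Both
    profiles are anchored at the exact boundary values f(z_min)=1 and
    f(z_max)=0 (absorbing ends), so the quadrature spans the full channel.
    """
    if mode == "committor":
        if committor is None:
            raise ValueError("committor mode requires a CommittorProfile")
        z = committor.z[committor.valid]
        f = 1.0 - committor.P[committor.valid]
    elif mode == "density":
        if pmf is None or stats is None:
            raise ValueError("density mode requires pmf and forward stats")
        if stats.direction != "forward":
            raise ValueError("density mode uses the forward ensemble")
        valid = pmf.valid & (stats.rho > 0)
        z = pmf.z[valid]
        dE = pmf.delta_A[valid] + surface.q * KCAL_MOL_PER_E_MV * (
            ref_voltage.profile(z) - ref_voltage.profile(np.array([pmf.reference_z]))[0])
        rho = stats.rho[valid].astype(float)
        f = np.exp(surface.beta * dE) * rho / rho[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = np.concatenate([[surface.z_min], z, [surface.z_max]])
    f = np.concatenate([[1.0], f, [0.0]])
    return FProfile(z=z, f=f, mode=mode)


def exact_f_profile(surface: FreeEnergySurface,
                    ref_voltage: AppliedVoltage) -> FProfile:
    """Oracle f(z) = 1 − P_exact(z) on the full grid (for validation)."""
    return FProfile(z=surface.z,
                    f=1.0 - exact_committor(surface, ref_voltage),
                    mode="committor")


def current_ratio(
    f: FProfile,
    surface: FreeEnergySurface,
    ref_voltage: AppliedVoltage,
    target_voltage: AppliedVoltage,
) -> float:
    """R = J_f(ref)/J_f(target) from the reference-voltage profile f."""
    bqu = surface.beta * surface.q * KCAL_MOL_PER_E_MV
    dE_el = target_voltage.field - ref_voltage.field  # mV/Å
    g = np.exp(bqu * (target_voltage.profile(f.z) - ref_voltage.profile(f.z)))
    R = 1.0 + bqu * dE_el * trapezoid(f.f * g, f.z)
    if R <= 0:
        raise NumericalBreakdownError(
            f"current ratio {R:.3g} <= 0 at ΔV={target_voltage.delta_v} mV: "
            "reconstruction breaks down this far from the reference voltage"
        )
    return float(R)


def current_at_voltage(
    J_ref_f: float,
    J_ref_b: float,
    f: FProfile,
    surface: FreeEnergySurface,
    ref_voltage: AppliedVoltage,
    target_voltage: AppliedVoltage,
) -> tuple[float, float]:
    """One-sided currents (events/ns) at the target voltage.

    Exactly reproduces (J_ref_f, J_ref_b) when target equals reference.
    """
    R = current_ratio(f, surface, ref_voltage, target_voltage)
    bqu = surface.beta * surface.q * KCAL_MOL_PER_E_MV
    jf = J_ref_f / R
    jb = J_ref_b * np.exp(bqu * (target_voltage.delta_v - ref_voltage.delta_v)) / R
    return float(jf), float(jb)


@dataclass(frozen=True)
class IVCurve:
    """Per-ion current-voltage table (reconstructed or direct)."""

    ion: str
    method: str                 # committor | density | direct
    ref_delta_v: float
    V_mV: np.ndarray
    Jf: np.ndarray              # events/ns
    Jb: np.ndarray
    J: np.ndarray
    I_pA: np.ndarray
    SE_pA: np.ndarray
    t_S: float = float("nan")   # calibration metadata

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# ion\tV_mV\tJf_pA\tJb_pA\tJnet_pA\tSE_pA\tmethod\n")
            q_pa = PA_PER_E_PER_NS
            for i in range(self.V_mV.size):
                fh.write(
                    f"{self.ion}\t{self.V_mV[i]:.6g}\t{self.Jf[i] * q_pa:.6g}\t"
                    f"{self.Jb[i] * q_pa:.6g}\t{self.I_pA[i]:.6g}\t"
                    f"{self.SE_pA[i]:.6g}\t{self.method}\n"
                )


def reconstruct_iv(
    current_ref: CurrentEstimate,
    f: FProfile,
    surface: FreeEnergySurface,
    ref_voltage: AppliedVoltage,
    voltages_mv: Sequence[float],
) -> IVCurve:
    """Full I-V curve from statistics at the single reference voltage.

    Poisson errors of the reference crossing counts are propagated through
    the (deterministic) voltage scaling.
    """
    if not np.isfinite(current_ref.t_S) or current_ref.t_S <= 0:
        raise ValueError("current estimate lacks a stochastic-time calibration")
    V = np.asarray(list(voltages_mv), dtype=float)
    jf = np.empty_like(V)
    jb = np.empty_like(V)
    for i, dv in enumerate(V):
        jf[i], jb[i] = current_at_voltage(
            current_ref.J_f, current_ref.J_b, f, surface,
            ref_voltage, ref_voltage.at(dv))
    J = jf - jb
    rel_f = current_ref.rel_err_f
    rel_b = current_ref.rel_err_b if current_ref.n_b else 0.0
    se = np.sqrt((jf * rel_f) ** 2 + (jb * rel_b) ** 2)
    return IVCurve(
        ion=surface.ion_label, method=f.mode,
        ref_delta_v=ref_voltage.delta_v,
        V_mV=V, Jf=jf, Jb=jb, J=J,
        I_pA=surface.q * J * PA_PER_E_PER_NS,
        SE_pA=np.abs(surface.q) * se * PA_PER_E_PER_NS,
        t_S=current_ref.t_S,
    )


# ---------------------------------------------------------------------------
# Reversal potential and GHK selectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonCurrentModel:
    """Per-ion one-sided current functions of voltage (events/ns)."""

    label: str
    q: float
    J_f: Callable[[float], float]
    J_b: Callable[[float], float]

    @staticmethod
    def from_reconstruction(
        current_ref: CurrentEstimate,
        f: FProfile,
        surface: FreeEnergySurface,
        ref_voltage: AppliedVoltage,
    ) -> "IonCurrentModel":
        def jf(v: float) -> float:
            return current_at_voltage(current_ref.J_f, current_ref.J_b, f,
                                      surface, ref_voltage, ref_voltage.at(v))[0]

        def jb(v: float) -> float:
            return current_at_voltage(current_ref.J_f, current_ref.J_b, f,
                                      surface, ref_voltage, ref_voltage.at(v))[1]

        return IonCurrentModel(surface.ion_label, surface.q, jf, jb)

    @staticmethod
    def from_oracle(
        surface: FreeEnergySurface,
        window: AppliedVoltage,
        rho0: float = 1.0,
    ) -> "IonCurrentModel":
        def jf(v: float) -> float:
            return exact_one_sided_fluxes(surface, window.at(v), rho0, rho0)[0]

        def jb(v: float) -> float:
            return exact_one_sided_fluxes(surface, window.at(v), rho0, rho0)[1]

        return IonCurrentModel(surface.ion_label, surface.q, jf, jb)


def reversal_potential(
    ions: Sequence[IonCurrentModel],
    r: float,
    *,
    temperature: float | None = None,
    search_margin_mv: float = 20.0,
    xtol_mv: float = 0.01,
) -> float:
    """Applied voltage (mV) at which the total net charge current vanishes.

    The cis-side (z_min-entry, forward) fluxes of *all* ions are scaled by
    the concentration ratio ``r`` — valid in the unsaturated, linear
    concentration-response regime — and the root of
    Σ_i q_i [r J_f,i(V) − J_b,i(V)] is located by Brent bracketing (at
    least bisection-fast) to ``xtol_mv``.  The default search interval is
    the Nernst bound ±(kT/e) ln r widened by ``search_margin_mv``.
    """
    if r <= 0:
        raise ValueError("concentration ratio must be positive")
    vt = thermal_voltage_mv(temperature) if temperature else thermal_voltage_mv()
    half = abs(vt * np.log(r)) + search_margin_mv

    def total(v: float) -> float:
        return sum(m.q * (r * m.J_f(v) - m.J_b(v)) for m in ions)

    lo, hi = -half, half
    if total(lo) * total(hi) > 0:
        raise NumericalBreakdownError(
            f"no sign change of the total current in [{lo:.1f}, {hi:.1f}] mV"
        )
    return float(brentq(total, lo, hi, xtol=xtol_mv))


def ghk_selectivity(v_rev_mv: float, r: float,
                    temperature: float | None = None) -> float:
    """Permeability ratio of the dominant over the opposite-charge ion.

    Inverts the two-ion GHK voltage equation at salt gradient ``r``:
    with u = |V_rev| e/kT,  e^u = (r x + 1)/(x + r)  ⇒
    x = (r e^u − 1)/(r − e^u).  Requires |V_rev| below the Nernst limit
    (kT/e) ln r; V_rev = 0 gives x = 1 (no selectivity).
    """
    if r <= 0 or r == 1:
        raise ValueError("concentration ratio must be positive and != 1")
    if r < 1:
        r = 1.0 / r
    vt = thermal_voltage_mv(temperature) if temperature else thermal_voltage_mv()
    u = abs(v_rev_mv) / vt
    eu = np.exp(u)
    if eu >= r:
        raise ValueError(
            f"|V_rev| = {abs(v_rev_mv):.3g} mV at or beyond the Nernst limit "
            f"{vt * np.log(r):.3g} mV: no finite selectivity"
        )
    return float((r * eu - 1.0) / (r - eu))


def ghk_reversal_potential(selectivity: float, r: float,
                           temperature: float | None = None) -> float:
    """|V_rev| (mV) of a two-ion channel with the given permeability ratio.

    ``selectivity`` is the dominant-over-opposite ratio and must be ≥ 1
    (express the opposite preference by swapping the ion labels): from the
    magnitude of the reversal potential alone, x and 1/x are
    indistinguishable, so only the x ≥ 1 branch round-trips with
    :func:`ghk_selectivity`.
    """
    if selectivity < 1:
        raise ValueError("selectivity is the dominant/opposite ratio, >= 1; "
                         "swap the ion labels for the inverse preference")
    if r <= 0 or r == 1:
        raise ValueError("concentration ratio must be positive and != 1")
    if r < 1:
        r = 1.0 / r
    vt = thermal_voltage_mv(temperature) if temperature else thermal_voltage_mv()
    x = selectivity
    return float(vt * np.log((r * x + 1.0) / (x + r)))


def nernst_potential(r: float, q: float = 1.0,
                     temperature: float | None = None) -> float:
    """Single-ion equilibrium potential (kT/qe) ln r in mV."""
    if r <= 0:
        raise ValueError("concentration ratio must be positive")
    if q == 0:
        raise ValueError("neutral species has no Nernst potential")
    vt = thermal_voltage_mv(temperature) if temperature else thermal_voltage_mv()
    return float(vt * np.log(r) / q)
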