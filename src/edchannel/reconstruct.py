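"""PMF reconstruction from single-voltage nonequilibrium statistics.

Three routes recover the free-energy profile ``ΔA(z, z_min)`` from
steady-state data at one applied voltage:

IEEM (integrated electrodiffusion equation)
    ΔA = −kT [ln ρ(z)/ρ(ref) + J ∫ dz'/(D ρ(z'))] − q[V(z) − V(ref)],
    obtained by integrating J = −D(ρ' + βρE') with 1/ρ as integrating
    factor.  Needs the diffusivity and the net flux; uses the two-sided
    density.

CWDM (current-weighted density method)
    ΔA = −kT ln [J_b ρ_f(z) + J_f ρ_b(z)] + const − q[V(z) − V(ref)].
    Diffusivity-free; only the *ratio* of the one-sided currents and the
    *shapes* of the one-sided densities matter.  Unavailable when either
    direction produced no crossing events.

CPM (committor probability method)
    One-sided:  ΔA = −kT ln [ρ_f(z)/(1−P(z))] + const − qΔV-term
    (forward; the backward form divides ρ_b by P).  The two one-sided
    forms lose validity at opposite ends, so they are merged by a weighted
    histogram combination: with the shifted histograms
    g_f = ρ_f − ρ_f(z_max) and g_b = w(ρ_b − ρ_b(z_min)), whose biases are
    proportional to (1−P) and P with strengths given by the crossing
    counts,

        ΔA = −kT ln [ (g_f + g_b) / (n_f (1−P) + w n_b P) ] + C − qV-term.

    This remains valid across the whole channel, reduces exactly to the
    one-sided forward formula when the backward ensemble is empty, and
    needs no diffusivity.

All reconstructions are referenced so that ΔA = 0 at the first valid bin;
no smoothing is applied (replicate dispersion carries the error bars).
Bins outside the interval between the two injection points are masked: the
one-sided steady-state branch between a boundary and its injection point
differs from the transmitted branch, and those bins would otherwise bias
the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import KB_KCAL_MOL_K, KCAL_MOL_PER_E_MV
from .errors import MethodUnavailableError
from .estimators import CommittorProfile
from .profiles import AppliedVoltage, FreeEnergySurface
from .simulator import EnsembleStats

__all__ = [
    "PMFEstimate",
    "ReplicateSummary",
    "pmf_ieem",
    "ieem_from_stats",
    "pmf_cwdm",
    "cwdm_from_profiles",
    "pmf_cpm_one_sided",
    "cpm_one_sided_from_profiles",
    "pmf_cpm_wham",
    "cpm_wham_from_profiles",
    "replicate_summary",
]


@dataclass(frozen=True)
class PMFEstimate:
    """Reconstructed ΔA(z, z_min) on bin centers, kcal/mol."""

    z: np.ndarray
    delta_A: np.ndarray
    valid: np.ndarray
    method: str
    delta_v: float
    reference_z: float

    def __post_init__(self) -> None:
        if not self.valid.any():
            raise MethodUnavailableError(
                f"{self.method}: no valid bins in the reconstruction")

    @property
    def barrier(self) -> float:
        """ΔA between the outermost valid bins (end-to-end estimate)."""
        idx = np.nonzero(self.valid)[0]
        return float(self.delta_A[idx[-1]] - self.delta_A[idx[0]])


def _voltage_term(z, surface: FreeEnergySurface, voltage: AppliedVoltage):
    return surface.q * KCAL_MOL_PER_E_MV * voltage.profile(z)


def _finish(z, raw, valid, method, surface, voltage) -> PMFEstimate:
    """Subtract the voltage term and re-reference at the first valid bin."""
    dA = raw - _voltage_term(z, surface, voltage)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        raise MethodUnavailableError(f"{method}: no valid bins")
    dA = dA - dA[idx[0]]
    dA = np.where(valid, dA, np.nan)
    return PMFEstimate(z=np.asarray(z, float), delta_A=dA, valid=valid,
                       method=method, delta_v=voltage.delta_v,
                       reference_z=float(z[idx[0]]))


def _interior_mask(stats_f: EnsembleStats | None,
                   stats_b: EnsembleStats | None,
                   z: np.ndarray) -> np.ndarray:
    """Bins between the two injection points (source-free region)."""
    mask = np.ones(z.size, dtype=bool)
    for s in (stats_f, stats_b):
        if s is None or s.n_injected == 0:
            continue
        bw = s.bin_width
        z0 = s.injection_z(z[0] - 0.5 * bw, z[-1] + 0.5 * bw)
        mask &= (z >= z0) if s.direction == "forward" else (z <= z0)
    return mask


# ---------------------------------------------------------------------------
# IEEM
# ---------------------------------------------------------------------------

def pmf_ieem(
    z: np.ndarray,
    rho: np.ndarray,
    J: float,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    valid: np.ndarray | None = None,
) -> PMFEstimate:
    """Integrated-ED reconstruction from a two-sided density and net flux.

    ``rho`` and ``J`` must be in mutually consistent units (e.g. a
    time-integrated line density in steps·ns/Å together with the total net
    crossing-event count, or a steady-state density with the steady flux):
    only the product ``J / (D ρ)`` enters.  Zero-density bins inside the
    range are masked with a warning; the cumulative quadrature then spans
    the remaining valid bins.
    """
    z = np.asarray(z, float)
    rho = np.asarray(rho, float)
    kT = KB_KCAL_MOL_K * surface.T
    ok = rho > 0
    if valid is not None:
        ok = ok & valid
    if valid is None or (valid & ~(rho > 0)).any():
        n_holes = int((~(rho > 0)).sum() if valid is None
                      else (valid & ~(rho > 0)).sum())
        if n_holes:
            warnings.warn(f"IEEM: {n_holes} zero-density bins masked")
    if not ok.any():
        raise MethodUnavailableError("IEEM: density is empty")
    zv = z[ok]
    rv = rho[ok]
    ref = rv[0]
    integral = cumulative_trapezoid(1.0 / (surface.D * rv), zv, initial=0.0)
    raw_v = -kT * (np.log(rv / ref) + J * integral)
    raw = np.full(z.size, np.nan)
    raw[ok] = raw_v
    return _finish(z, raw, ok, "IEEM", surface, voltage)


def ieem_from_stats(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
) -> PMFEstimate:
    """IEEM on simulated ensembles: two-sided histogram plus net crossings.

    The step-weighted histograms are converted to a time-integrated line
    density (counts · dt / bin width) so that the net crossing-event count
    ``n_f − w n_b`` is the matching integrated flux.
    """
    z = stats_f.bin_centers
    rho = (stats_f.rho + w * stats_b.rho) * stats_f.dt / stats_f.bin_width
    J = stats_f.n_cross - w * stats_b.n_cross
    return pmf_ieem(z, rho, J, surface, voltage,
                    valid=_interior_mask(stats_f, stats_b, z))


# ---------------------------------------------------------------------------
# CWDM
# ---------------------------------------------------------------------------

def cwdm_from_profiles(
    z: np.ndarray,
    rho_f: np.ndarray,
    rho_b: np.ndarray,
    J_f: float,
    J_b: float,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    valid: np.ndarray | None = None,
) -> PMFEstimate:
    """Current-weighted density reconstruction from one-sided profiles.

    Invariant to rescaling of (J_f, J_b) jointly and of each density's
    normalization jointly; requires J_f > 0 and J_b > 0.
    """
    if J_f <= 0 or J_b <= 0:
        raise MethodUnavailableError(
            "CWDM requires crossing events in both directions "
            f"(J_f={J_f}, J_b={J_b})"
        )
    z = np.asarray(z, float)
    kT = KB_KCAL_MOL_K * surface.T
    num = J_b * np.asarray(rho_f, float) + J_f * np.asarray(rho_b, float)
    ok = num > 0
    if valid is not None:
        ok &= valid
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = -kT * np.log(np.where(ok, num, np.nan))
    return _finish(z, raw, ok, "CWDM", surface, voltage)


def pmf_cwdm(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
) -> PMFEstimate:
    """CWDM on simulated ensembles, weighting backward data by ``w``.

    The one-sided currents enter only as ratios, so the crossing counts
    (n_f, w·n_b) stand in for (J_f, J_b) directly.
    """
    if stats_f.n_cross == 0 or stats_b.n_cross == 0:
        raise MethodUnavailableError(
            "CWDM unavailable: no crossing events in one direction "
            f"(n_f={stats_f.n_cross}, n_b={stats_b.n_cross})"
        )
    z = stats_f.bin_centers
    return cwdm_from_profiles(
        z, stats_f.rho.astype(float), w * stats_b.rho.astype(float),
        J_f=float(stats_f.n_cross), J_b=float(w * stats_b.n_cross),
        surface=surface, voltage=voltage,
        valid=_interior_mask(stats_f, stats_b, z),
    )


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------

def cpm_one_sided_from_profiles(
    z: np.ndarray,
    rho: np.ndarray,
    rho_far: float,
    P: np.ndarray,
    direction: str,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    valid: np.ndarray | None = None,
) -> PMFEstimate:
    """One-sided committor reconstruction.

    forward:  ΔA ∝ −kT ln[(ρ_f(z) − ρ_f(z_max)) / (1 − P(z))]
    backward: ΔA ∝ −kT ln[(ρ_b(z) − ρ_b(z_min)) / P(z)]

    ``rho_far`` is the density at the far (absorbing) boundary — zero for
    absorbing stochastic ensembles, possibly nonzero for reservoir data.
    Bins where the shifted density or the committor factor are non-positive
    are masked (the method inevitably degrades near the far end).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be forward|backward")
    z = np.asarray(z, float)
    kT = KB_KCAL_MOL_K * surface.T
    g = np.asarray(rho, float) - rho_far
    comm = (1.0 - np.asarray(P, float)) if direction == "forward" else np.asarray(P, float)
    ok = (g > 0) & (comm > 0) & np.isfinite(comm)
    if valid is not None:
        ok &= valid
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = -kT * np.log(np.where(ok, g / np.where(comm > 0, comm, 1.0), np.nan))
    method = "CPM_f" if direction == "forward" else "CPM_b"
    return _finish(z, raw, ok, method, surface, voltage)


def pmf_cpm_one_sided(
    stats: EnsembleStats,
    P: CommittorProfile,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
) -> PMFEstimate:
    """One-sided CPM on a simulated ensemble (absorbing far boundary)."""
    z = stats.bin_centers
    valid = _interior_mask(stats if stats.direction == "forward" else None,
                           stats if stats.direction == "backward" else None,
                           z) & P.valid
    return cpm_one_sided_from_profiles(
        z, stats.rho.astype(float), 0.0, P.P, stats.direction,
        surface, voltage, valid=valid,
    )


def cpm_wham_from_profiles(
    z: np.ndarray,
    g_f: np.ndarray,
    g_b: np.ndarray,
    c_f: float,
    c_b: float,
    P: np.ndarray,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    valid: np.ndarray | None = None,
) -> PMFEstimate:
    """Weighted-histogram combination of the two one-sided reconstructions.

    ``g_f`` and ``g_b`` are the boundary-shifted (and, for backward,
    w-weighted) histograms; their biases are (1−P) and P with strengths
    ``c_f`` and ``c_b`` (the weighted crossing counts):

        ΔA = −kT ln[(g_f + g_b) / (c_f (1−P) + c_b P)] + C − qV(z).
    """
    z = np.asarray(z, float)
    kT = KB_KCAL_MOL_K * surface.T
    h = np.asarray(g_f, float) + np.asarray(g_b, float)
    P = np.asarray(P, float)
    den = c_f * (1.0 - P) + c_b * P
    ok = (h > 0) & (den > 0) & np.isfinite(P)
    if valid is not None:
        ok &= valid
    if not ok.any():
        raise MethodUnavailableError("CPM_wham: combined histogram empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = -kT * np.log(np.where(ok, h / np.where(den > 0, den, 1.0), np.nan))
    return _finish(z, raw, ok, "CPM_wham", surface, voltage)


def pmf_cpm_wham(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
    P: CommittorProfile,
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
) -> PMFEstimate:
    """Two-sided CPM on simulated ensembles.

    Valid across the whole interior even when one direction has few (or no)
    crossings, which is where CWDM fails.
    """
    z = stats_f.bin_centers
    valid = _interior_mask(stats_f, stats_b, z) & P.valid
    return cpm_wham_from_profiles(
        z,
        stats_f.rho.astype(float),
        w * stats_b.rho.astype(float),
        c_f=float(stats_f.n_cross),
        c_b=float(w * stats_b.n_cross),
        P=P.P,
        surface=surface,
        voltage=voltage,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate mean and dispersion of reconstructed PMFs."""

    z: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_valid: np.ndarray
    method: str
    barriers: np.ndarray       # per-replicate end-to-end ΔA
    single_replicate: bool

    @property
    def barrier_mean(self) -> float:
        return float(np.mean(self.barriers))

    @property
    def barrier_sd(self) -> float:
        if self.barriers.size < 2:
            return float("nan")
        return float(np.std(self.barriers, ddof=1))


def replicate_summary(estimates: list[PMFEstimate]) -> ReplicateSummary:
    """Per-bin mean/SD over replicates, computed on valid bins only.

    Each estimate must come from an independent data set (one estimate per
    set, never pooled trajectories).  With a single replicate the SD is
    undefined and flagged.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    z = estimates[0].z
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in replicate set: {sorted(methods)}")
    for e in estimates:
        if e.z.shape != z.shape or not np.allclose(e.z, z):
            raise ValueError("replicates must share the bin grid")
    stack = np.vstack([e.delta_A for e in estimates])
    vstack = np.vstack([e.valid for e in estimates])
    n_valid = vstack.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(vstack, stack, np.nan), axis=0)
        if len(estimates) > 1:
            sd = np.nanstd(np.where(vstack, stack, np.nan), axis=0, ddof=1)
        else:
            sd = np.full(z.size, np.nan)
    barriers = np.array([e.barrier for e in estimates])
    return ReplicateSummary(
        z=z, mean=mean, sd=sd, n_valid=n_valid, method=methods.pop(),
        barriers=barriers, single_replicate=len(estimates) == 1,
    )
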