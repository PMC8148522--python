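"""Committor profiles, crossing-count currents and Poisson error estimates.

Committor estimates follow first-passage counting: of the ``N(z)`` forward
trajectories that ever reached ``z``, the fraction that went on to cross is
``P(z) = N_f(z_max)/N_f(z)``; backward trajectories give
``P(z) = 1 − N_b(z_min)/N_b(z)``.  The two-sided combination weights the
backward counts by the detailed-balance weight ``w`` and is valid wherever
either ensemble visited; it is the preferred estimator because each
one-sided profile loses statistics near its far end.  When no forward
crossing was observed at all (rare-event regime) the backward profile can
be patched onto the forward one at a plane ``z'`` by requiring continuity
(the "alpha-patched" profile).

Bins whose denominators vanish are masked, never interpolated or imputed.
Committor standard errors are binomial; crossing-count errors are Poisson
(relative error ``n**-0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PA_PER_E_PER_NS
from .errors import MethodUnavailableError
from .simulator import EnsembleStats

__all__ = [
    "CommittorProfile",
    "CurrentEstimate",
    "committor_one_sided",
    "committor_two_sided",
    "committor_alpha_patched",
    "poisson_relative_error",
    "time_for_matched_error",
    "stochastic_time",
    "crossing_currents",
]


@dataclass(frozen=True)
class CommittorProfile:
    """Per-bin committor estimate with validity mask and binomial SEs."""

    z: np.ndarray
    P: np.ndarray
    se: np.ndarray
    valid: np.ndarray
    method: str
    alpha: float | None = None
    z_prime: float | None = None
    flagged: bool = False  # zero crossings in the needed direction

    @property
    def transition_state_z(self) -> float:
        """z of the P = 0.5 crossing, interpolated over valid bins (nan if none)."""
        z = self.z[self.valid]
        P = self.P[self.valid]
        if z.size < 2:
            return float("nan")
        above = P >= 0.5
        if not above.any() or above.all():
            return float("nan")
        i = int(np.argmax(above))
        if i == 0:
            return float(z[0])
        p0, p1, z0, z1 = P[i - 1], P[i], z[i - 1], z[i]
        if p1 == p0:
            return float(z1)
        return float(z0 + (0.5 - p0) * (z1 - z0) / (p1 - p0))

    def monotonicity_violations(self) -> int:
        """Number of adjacent valid-bin pairs where P decreases (not repaired)."""
        P = self.P[self.valid]
        return int(np.sum(np.diff(P) < 0))


def _check_same_bins(a: EnsembleStats, b: EnsembleStats) -> None:
    if a.bin_centers.shape != b.bin_centers.shape or not np.allclose(
            a.bin_centers, b.bin_centers):
        raise ValueError("ensembles must share an identical bin grid")


def _one_sided_validity(stats: EnsembleStats) -> np.ndarray:
    """First-passage formulas hold only beyond the injection point."""
    z = stats.bin_centers
    bw = stats.bin_width
    z_min = z[0] - 0.5 * bw
    z_max = z[-1] + 0.5 * bw
    z0 = stats.injection_z(z_min, z_max)
    if stats.direction == "forward":
        return z >= z0
    return z <= z0


def committor_one_sided(stats: EnsembleStats) -> CommittorProfile:
    """Committor from one ensemble's first-passage reach counts.

    Forward: ``P = n_cross / N_reach``; backward: ``P = 1 − n_cross/N_reach``.
    If no crossings were observed the profile is identically 0 (forward) or
    1 (backward) on its valid bins and flagged for the alpha-patched path.
    """
    N = stats.N_reach.astype(float)
    valid = (_one_sided_validity(stats)) & (stats.N_reach > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(valid, stats.n_cross / np.maximum(N, 1.0), np.nan)
    if stats.direction == "forward":
        P = frac
    else:
        P = 1.0 - frac
    se = np.sqrt(np.clip(P * (1.0 - P), 0.0, None) / np.maximum(N, 1.0))
    return CommittorProfile(stats.bin_centers, P, se, valid,
                            method=stats.direction, flagged=stats.n_cross == 0)


def committor_two_sided(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
) -> CommittorProfile:
    """Two-sided committor with backward counts weighted by ``w``.

    P(z) = [N_f(z_max) + w (N_b(z) − N_b(z_min))] / [N_f(z) + w N_b(z)]

    Reduces to the one-sided formulas when one ensemble is empty.
    """
    if w <= 0:
        raise ValueError("detailed-balance weight w must be positive")
    _check_same_bins(stats_f, stats_b)
    Nf = stats_f.N_reach.astype(float)
    Nb = stats_b.N_reach.astype(float)
    num = stats_f.n_cross + w * (Nb - stats_b.n_cross)
    den = Nf + w * Nb
    # outside either injection point only the other ensemble's counts are usable
    vf = _one_sided_validity(stats_f) | (stats_f.n_injected == 0)
    vb = _one_sided_validity(stats_b) | (stats_b.n_injected == 0)
    valid = (den > 0) & vf & vb
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(valid, num / np.where(den > 0, den, 1.0), np.nan)
    se = np.sqrt(np.clip(P * (1.0 - P), 0.0, None) / np.maximum(den, 1.0))
    return CommittorProfile(stats_f.bin_centers, P, se, valid, method="two_sided")


def committor_alpha_patched(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
    z_prime: float | None = None,
    *,
    min_reach: int = 10,
) -> CommittorProfile:
    """Committor patched at ``z'`` when forward crossings are absent.

    With ``N_f(z_max) = 0`` the forward profile is identically zero; writing
    ``P(z) = α N_f(z')/N_f(z)`` below ``z'`` and the backward one-sided form
    above, continuity at ``z'`` fixes ``α = 1 − N_b(z_min)/N_b(z')``:

        P(z) = [α N_f(z') + w(N_b(z) − N_b(z_min))] / [N_f(z) + w N_b(z)]   z < z'
        P(z) = 1 − N_b(z_min)/N_b(z)                                        z ≥ z'

    If ``z_prime`` is not given, the largest bin center with at least
    ``min_reach`` counts in both directions is used.
    """
    if w <= 0:
        raise ValueError("detailed-balance weight w must be positive")
    _check_same_bins(stats_f, stats_b)
    z = stats_f.bin_centers
    Nf = stats_f.N_reach.astype(float)
    Nb = stats_b.N_reach.astype(float)
    ok = (stats_f.N_reach >= min_reach) & (stats_b.N_reach >= min_reach)
    if z_prime is None:
        if not ok.any():
            raise MethodUnavailableError(
                f"no plane with >= {min_reach} reach counts in both directions; "
                "profile cannot be patched"
            )
        ip = int(np.max(np.nonzero(ok)[0]))
    else:
        ip = int(np.argmin(np.abs(z - z_prime)))
        if stats_f.N_reach[ip] == 0 or stats_b.N_reach[ip] == 0:
            raise MethodUnavailableError(
                f"no reach counts at z'={z[ip]:.3g} in one direction"
            )
    zp = float(z[ip])
    alpha = 1.0 - stats_b.n_cross / Nb[ip]
    vf = _one_sided_validity(stats_f)
    vb = _one_sided_validity(stats_b)
    below = np.arange(z.size) < ip
    den = Nf + w * Nb
    with np.errstate(divide="ignore", invalid="ignore"):
        P_below = (alpha * Nf[ip] + w * (Nb - stats_b.n_cross)) / np.where(
            den > 0, den, 1.0)
        P_above = 1.0 - stats_b.n_cross / np.maximum(Nb, 1.0)
    P = np.where(below, P_below, P_above)
    valid = vf & vb & np.where(below, den > 0, Nb > 0)
    se = np.sqrt(np.clip(P * (1 - P), 0, None)
                 / np.maximum(np.where(below, den, Nb), 1.0))
    P = np.where(valid, P, np.nan)
    return CommittorProfile(z, P, se, valid, method="alpha_patched",
                            alpha=float(alpha), z_prime=zp)


# ---------------------------------------------------------------------------
# Crossing counts, errors, currents
# ---------------------------------------------------------------------------

def poisson_relative_error(n: float) -> float:
    """Relative error of a Poisson-distributed crossing count: n**-0.5."""
    if n <= 0:
        raise ValueError("crossing count must be positive")
    return 1.0 / np.sqrt(n)


def time_for_matched_error(
    t_observed: float,
    n_observed: float,
    target_relative_error: float,
) -> float:
    """Simulation time needed for a target Poisson relative error.

    Extrapolates the observed event rate ``n_observed / t_observed``:
    to reach a relative error of ``target_relative_error`` one needs
    ``1/target**2`` events, hence time ``t_observed * n_needed / n_observed``.
    """
    if n_observed <= 0 or t_observed <= 0:
        raise ValueError("observed count and time must be positive")
    if not 0 < target_relative_error < 1:
        raise ValueError("target relative error must lie in (0, 1)")
    n_needed = 1.0 / target_relative_error**2
    return t_observed * n_needed / n_observed


def stochastic_time(t_md: float, m_cross: int, n_cross: int) -> float:
    """Effective duration t_S (ns) of a stochastic ensemble.

    Matches the ensemble's crossing count ``n_cross`` at the reference
    voltage to ``m_cross`` events observed in a reference simulation of
    length ``t_md``: ``t_S = t_md * n_cross / m_cross``.  Use the direction
    with the better statistics.
    """
    if m_cross <= 0:
        raise ValueError("reference crossing count must be positive")
    if t_md <= 0:
        raise ValueError("reference time must be positive")
    return t_md * n_cross / m_cross


@dataclass(frozen=True)
class CurrentEstimate:
    """One-sided and net crossing-count currents at one voltage."""

    delta_v: float
    n_f: int
    n_b: int
    w: float
    t_S: float          # ns
    J_f: float          # events/ns
    J_b: float
    J: float
    I_pA: float         # charge current q*J
    rel_err_f: float
    rel_err_b: float
    se_J: float         # Poisson SE on J, events/ns

    @property
    def se_I_pA(self) -> float:
        return abs(self.I_pA / self.J) * self.se_J if self.J else float("nan")


def crossing_currents(
    stats_f: EnsembleStats,
    stats_b: EnsembleStats,
    w: float,
    t_S: float,
    q: float,
) -> CurrentEstimate:
    """Currents from crossing counts: J = (n_f − w n_b)/t_S.

    ``J`` is a particle flux in events/ns (positive = net forward motion);
    the charge current is ``I = q J`` in pA (1 e/ns = 160.2 pA).
    """
    if t_S <= 0:
        raise ValueError("t_S must be positive")
    nf, nb = stats_f.n_cross, stats_b.n_cross
    jf = nf / t_S
    jb = w * nb / t_S
    J = jf - jb
    se_J = np.sqrt(nf + w**2 * nb) / t_S
    return CurrentEstimate(
        delta_v=stats_f.delta_v,
        n_f=nf, n_b=nb, w=w, t_S=t_S,
        J_f=jf, J_b=jb, J=J,
        I_pA=q * J * PA_PER_E_PER_NS,
        rel_err_f=poisson_relative_error(nf) if nf else float("inf"),
        rel_err_b=poisson_relative_error(nb) if nb else float("inf"),
        se_J=float(se_J),
    )
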