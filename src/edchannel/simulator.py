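"""Stochastic trajectory ensembles on a total-energy profile.

Overdamped (Euler-Maruyama) trajectories are propagated on
``E(z) = A(z) + qV(z)`` with constant diffusivity and absorbing boundaries
at both channel ends.  Trajectories are injected just inside one boundary
(``forward``: near ``z_min``; ``backward``: near ``z_max``) and run until
absorbed at either end.  Each ensemble accumulates

* crossing outcomes (absorbed at the far vs. the near boundary),
* first-passage reach counts ``N(z)`` — how many trajectories visited each
  histogram bin at least once (the raw material of committor estimates), and
* a step-weighted residence histogram ``ρ(z)`` — each recorded position adds
  one count to its bin, so with a fixed time step the histogram is
  proportional to the residence-time density.

The integrator uses drift ``−βD E'(z) dt`` and Gaussian noise of variance
``2 D dt``; no spurious-drift correction is needed because ``D`` is
constant.  The first discrete step landing on or beyond a boundary
terminates the trajectory; the terminal point is classified but not added
to the histogram (absorbing-boundary semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import CalibrationError, DiscretizationError
from .oracle import exact_committor
from .profiles import AppliedVoltage, FreeEnergySurface, total_energy

__all__ = [
    "SimulationConfig",
    "EnsembleStats",
    "DetailedBalanceWeight",
    "run_ensemble",
    "calibrate_detailed_balance",
    "run_campaign",
    "ENSEMBLE_LEVELS",
]

#: Named ensemble sizes (trajectories injected per direction per data set).
ENSEMBLE_LEVELS = {"N6": 10**6, "N7": 10**7, "N8": 10**8}

_TRUNCATION_WARN = 1e-6
_TRUNCATION_FAIL = 1e-3


def default_bin_width(surface: FreeEnergySurface) -> float:
    """Bin width giving ~1 Å bins, clipped to [16, 64] bins per channel."""
    n = int(np.clip(round(surface.length), 16, 64))
    return surface.length / n


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble parameters.

    ``dt`` defaults to ``bin_width**2 / (32 D)`` so that the per-step RMS
    displacement sqrt(2 D dt) equals a quarter of a histogram bin; the run
    is refused if it exceeds two bins.  ``epsilon`` (injection offset from
    the boundary) defaults to one bin width and is reported in the outputs
    because crossing fractions scale with it.
    """

    n_traj: int
    direction: str = "forward"
    dt: float | None = None
    epsilon: float | None = None
    bin_width: float | None = None
    seed: int = 0
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward|backward, got {self.direction!r}")
        if self.n_traj < 0:
            raise ValueError("n_traj must be non-negative")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")

    def resolve(self, surface: FreeEnergySurface) -> "_ResolvedConfig":
        bin_width = self.bin_width if self.bin_width is not None else default_bin_width(surface)
        n_bins = int(round(surface.length / bin_width))
        if n_bins < 16 or abs(n_bins * bin_width - surface.length) > 1e-6 * bin_width:
            raise DiscretizationError(
                f"bin_width {bin_width} must divide the channel into >= 16 bins"
            )
        dt = self.dt if self.dt is not None else bin_width**2 / (32.0 * surface.D)
        if dt <= 0:
            raise DiscretizationError("dt must be positive")
        rms = np.sqrt(2.0 * surface.D * dt)
        if rms > 2.0 * bin_width:
            raise DiscretizationError(
                f"per-step RMS displacement {rms:.3g} Å exceeds 2 bins "
                f"({2 * bin_width:.3g} Å): reduce dt"
            )
        eps = self.epsilon if self.epsilon is not None else bin_width
        if not 0 < eps < surface.length / 4:
            raise DiscretizationError(
                f"epsilon must lie in (0, {surface.length / 4:.3g}) Å, got {eps}"
            )
        return _ResolvedConfig(self, dt, eps, bin_width, n_bins)


@dataclass(frozen=True)
class _ResolvedConfig:
    base: SimulationConfig
    dt: float
    epsilon: float
    bin_width: float
    n_bins: int


@dataclass(frozen=True)
class EnsembleStats:
    """Accumulated statistics of one injected ensemble.

    ``N_reach`` and ``rho`` are per-bin arrays on ``bin_centers``;
    ``n_cross`` counts trajectories absorbed at the far boundary and
    ``n_return`` at the near (injection-side) boundary.
    """

    direction: str
    n_injected: int
    n_cross: int
    n_return: int
    n_truncated: int
    bin_centers: np.ndarray
    N_reach: np.ndarray
    rho: np.ndarray
    seed: int
    delta_v: float
    dt: float
    epsilon: float
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_cross + self.n_return + self.n_truncated != self.n_injected:
            raise ValueError("outcome counts must sum to n_injected")
        if np.any(np.asarray(self.rho) < 0):
            raise ValueError("rho must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def crossing_fraction(self) -> float:
        return self.n_cross / self.n_injected if self.n_injected else np.nan

    def injection_z(self, z_min: float, z_max: float) -> float:
        return z_min + self.epsilon if self.direction == "forward" else z_max - self.epsilon


#: Continuity correction for discrete-time absorption and first passage
#: (Broadie-Glasserman-Kou): shifting thresholds by -ζ(1/2)·σ per step
#: compensates the mean overshoot / intra-step excursion of the walk.
_BGK = 0.5825971579390107


@njit(cache=True)
def _propagate(n_traj, z0, zmin, zmax, grid_h, n_grid, force, drift_pref, sigma,
               inv_bin, n_bins, max_steps, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    rho = np.zeros(n_bins, dtype=np.int64)
    reach_lo = np.zeros(n_bins, dtype=np.int64)  # traj with min z <= center+corr
    reach_hi = np.zeros(n_bins, dtype=np.int64)  # traj with max z >= center-corr
    n_abs_min = 0
    n_abs_max = 0
    n_trunc = 0
    corr = _BGK * sigma
    lo_abs = zmin + corr  # effective absorbing thresholds of the discrete walk
    hi_abs = zmax - corr
    half_bin = 0.5 / inv_bin
    for _traj in range(n_traj):
        zpos = z0
        z_lo = z0
        z_hi = z0
        b0 = int((zpos - zmin) * inv_bin)
        if b0 >= n_bins:
            b0 = n_bins - 1
        rho[b0] += 1
        absorbed = False
        for _step in range(max_steps):
            x = (zpos - zmin) / grid_h
            j = int(x)
            if j >= n_grid - 1:
                j = n_grid - 2
            f = force[j] + (x - j) * (force[j + 1] - force[j])
            zpos = zpos + drift_pref * f + sigma * np.random.normal(0.0, 1.0)
            if zpos < z_lo:
                z_lo = zpos
            elif zpos > z_hi:
                z_hi = zpos
            if zpos <= lo_abs:
                n_abs_min += 1
                absorbed = True
                break
            if zpos >= hi_abs:
                n_abs_max += 1
                absorbed = True
                break
            b = int((zpos - zmin) * inv_bin)
            if b >= n_bins:
                b = n_bins - 1
            rho[b] += 1
        if not absorbed:
            n_trunc += 1
        # first-passage reach per bin center, overshoot-corrected
        k_hi = int((z_hi + corr - zmin - half_bin) * inv_bin + 1.0)
        if k_hi > n_bins:
            k_hi = n_bins
        for b in range(k_hi):
            reach_hi[b] += 1
        k_lo = int((z_lo - corr - zmin - half_bin) * inv_bin + 1.0)
        if k_lo < 0:
            k_lo = 0
        for b in range(k_lo, n_bins):
            reach_lo[b] += 1
    return n_abs_min, n_abs_max, n_trunc, reach_lo, reach_hi, rho


def run_ensemble(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    config: SimulationConfig,
) -> EnsembleStats:
    """Propagate one ensemble and accumulate its statistics.

    Fully reproducible from ``config.seed`` (one RNG stream per ensemble).
    """
    rc = config.resolve(surface)
    centers = surface.z_min + rc.bin_width * (np.arange(rc.n_bins) + 0.5)
    if config.n_traj == 0:
        zero = np.zeros(rc.n_bins, dtype=np.int64)
        return EnsembleStats(config.direction, 0, 0, 0, 0, centers, zero,
                             zero.copy(), config.seed, voltage.delta_v,
                             rc.dt, rc.epsilon, rc.bin_width)

    E = total_energy(surface, voltage)
    force = np.ascontiguousarray(np.gradient(E, surface.spacing))
    drift_pref = -surface.beta * surface.D * rc.dt
    sigma = np.sqrt(2.0 * surface.D * rc.dt)
    z0 = (surface.z_min + rc.epsilon if config.direction == "forward"
          else surface.z_max - rc.epsilon)
    seed32 = int(config.seed) % (2**32)

    n_min, n_max, n_trunc, reach_lo, reach_hi, rho = _propagate(
        config.n_traj, z0, surface.z_min, surface.z_max, surface.spacing,
        surface.z.size, force, drift_pref, sigma, 1.0 / rc.bin_width,
        rc.n_bins, config.max_steps, seed32,
    )
    # A bin below the injection point is "reached" when the trajectory's
    # minimum got there, above it when the maximum did; the other condition
    # is trivially satisfied, so the elementwise minimum selects the right one.
    reach = np.minimum(reach_lo, reach_hi)
    if config.direction == "forward":
        n_cross, n_return = n_max, n_min
    else:
        n_cross, n_return = n_min, n_max

    frac = n_trunc / config.n_traj
    if frac > _TRUNCATION_FAIL:
        raise DiscretizationError(
            f"{frac:.1%} of trajectories hit max_steps={config.max_steps}; "
            "increase max_steps"
        )
    if frac > _TRUNCATION_WARN:
        warnings.warn(
            f"{n_trunc} of {config.n_traj} trajectories truncated at "
            f"max_steps={config.max_steps}"
        )
    return EnsembleStats(config.direction, config.n_traj, n_cross, n_return,
                         n_trunc, centers, reach, rho, config.seed,
                         voltage.delta_v, rc.dt, rc.epsilon, rc.bin_width)


# ---------------------------------------------------------------------------
# Detailed balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetailedBalanceWeight:
    """Backward-injection weight ``w`` with its Monte-Carlo uncertainty.

    ``w`` multiplies all backward counts so that, at zero applied voltage,
    the weighted backward crossing flux equals the forward one:
    ``w * (n_cross_b / n_inj_b) = n_cross_f / n_inj_f``.
    """

    w: float
    sigma: float
    n_cross_forward: int
    n_cross_backward: int


def calibrate_detailed_balance(
    surface: FreeEnergySurface,
    config_forward: SimulationConfig,
    config_backward: SimulationConfig,
    window: AppliedVoltage | None = None,
) -> DetailedBalanceWeight:
    """Establish the backward/forward injection weight at zero voltage.

    Runs both calibration ensembles at ΔV = 0 and returns the ratio of
    per-injection crossing probabilities, with a binomial error estimate.
    """
    if window is None:
        window = AppliedVoltage.full_window(surface, 0.0)
    v0 = window.at(0.0)
    sf = run_ensemble(surface, v0, replace(config_forward, direction="forward"))
    sb = run_ensemble(surface, v0, replace(config_backward, direction="backward"))
    for s in (sf, sb):
        if s.n_cross == 0:
            rc = (config_forward if s.direction == "forward" else config_backward
                  ).resolve(surface)
            P = exact_committor(surface, v0)
            z0 = s.injection_z(surface.z_min, surface.z_max)
            p = np.interp(z0, surface.z, P)
            p_cross = p if s.direction == "forward" else 1.0 - p
            need = int(100 / max(p_cross, 1e-300))
            raise CalibrationError(
                f"no {s.direction} crossings in {s.n_injected} calibration "
                f"trajectories; expected crossing probability is ~{p_cross:.3g}, "
                f"use at least ~{need} trajectories"
            )
    pf = sf.n_cross / sf.n_injected
    pb = sb.n_cross / sb.n_injected
    w = pf / pb
    sigma = w * np.sqrt(1.0 / sf.n_cross + 1.0 / sb.n_cross)
    return DetailedBalanceWeight(float(w), float(sigma), sf.n_cross, sb.n_cross)


# ---------------------------------------------------------------------------
# Replicate campaigns
# ---------------------------------------------------------------------------

def _level_size(level: int | str) -> int:
    if isinstance(level, str):
        try:
            return ENSEMBLE_LEVELS[level]
        except KeyError:
            raise ValueError(
                f"unknown level {level!r}; use one of {sorted(ENSEMBLE_LEVELS)} "
                "or an integer"
            ) from None
    return int(level)


def run_campaign(
    surface: FreeEnergySurface,
    voltage: AppliedVoltage,
    level: int | str,
    n_sets: int,
    seeds: list[int] | None = None,
    *,
    root_seed: int = 0,
    **config_kwargs,
) -> list[tuple[EnsembleStats, EnsembleStats]]:
    """Generate independent replicate data sets of paired ensembles.

    Each data set injects ``level`` trajectories per direction with its own
    RNG stream; estimators are meant to be applied per data set (one
    estimate per set), never to the pooled trajectories.  Seeds must be
    distinct; if not given they are derived from ``root_seed`` by stream
    splitting.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    n_traj = _level_size(level)
    if seeds is None:
        seeds = [int(s) for s in
                 np.random.SeedSequence(root_seed).generate_state(n_sets)]
    if len(seeds) != n_sets:
        raise ValueError(f"need {n_sets} seeds, got {len(seeds)}")
    if len(set(seeds)) != n_sets:
        raise ValueError("seeds must be distinct")

    out = []
    for seed in seeds:
        kf, kb = (int(s) for s in np.random.SeedSequence(seed).generate_state(2))
        sf = run_ensemble(surface, voltage, SimulationConfig(
            n_traj=n_traj, direction="forward", seed=kf, **config_kwargs))
        sb = run_ensemble(surface, voltage, SimulationConfig(
            n_traj=n_traj, direction="backward", seed=kb, **config_kwargs))
        out.append((sf, sb))
    return out
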