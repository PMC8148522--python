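"""Free-energy surfaces and applied-voltage ramps.

A channel is described by a one-dimensional potential of mean force (PMF)
``A(z)`` on a uniform grid spanning the channel axis between two absorbing
boundaries ``z_min`` and ``z_max``, together with a constant average
diffusion coefficient ``D``, the ion charge ``q`` and the temperature.
An applied voltage enters as a boxcar field: the potential ``V(z)`` is zero
below ``z_a``, rises linearly to the full drop ``delta_v`` at ``z_b`` and is
constant beyond, so the total energy of the ion is ``E(z) = A(z) + q V(z)``.

Synthetic PMF archetypes emulate the qualitative shapes seen in simple
channels: a flat-well profile (wide featureless pore, weakly
cation-attractive), a single central barrier (Born barrier for an anion in a
featureless pore), barriers at the channel mouths (charged residues at the
entrances) and a single tall barrier (low-conductance channel).  They are
shape templates, not fits to any particular channel structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KCAL_MOL_PER_E_MV, beta as _beta

__all__ = [
    "FreeEnergySurface",
    "AppliedVoltage",
    "make_synthetic_pmf",
    "load_pmf_table",
    "save_pmf_table",
    "total_energy",
    "ARCHETYPES",
]

_MIN_GRID_POINTS = 16
_MAX_SPACING = 1.0  # Å; coarser grids cannot resolve barrier shapes


@dataclass(frozen=True)
class FreeEnergySurface:
    """PMF ``A(z)`` on a uniform grid plus the ion/thermodynamic metadata.

    Parameters
    ----------
    z : ndarray
        Grid positions in Å, uniform and strictly increasing.  The first and
        last points are the absorbing channel boundaries.
    A : ndarray
        PMF in kcal/mol on ``z``.
    D : float
        Average diffusion coefficient, Å²/ns.
    q : float
        Ion charge in elementary charges (signed).
    T : float
        Temperature, K.
    ion_label : str
        Free-text label used in outputs.
    """

    z: np.ndarray
    A: np.ndarray
    D: float
    q: float
    T: float = DEFAULT_TEMPERATURE
    ion_label: str = "ion"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "A", A)
        if z.ndim != 1 or A.shape != z.shape:
            raise ValueError("z and A must be 1-D arrays of equal length")
        if z.size < _MIN_GRID_POINTS:
            raise ValueError(
                f"grid must have at least {_MIN_GRID_POINTS} points, got {z.size}"
            )
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValueError("z must be strictly increasing")
        h = dz[0]
        if np.any(np.abs(dz - h) > 1e-6 * h):
            raise ValueError("z grid must be uniform (tolerance 1e-6 of spacing)")
        if not np.all(np.isfinite(A)):
            raise ValueError("A must be finite everywhere")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")

    @property
    def z_min(self) -> float:
        return float(self.z[0])

    @property
    def z_max(self) -> float:
        return float(self.z[-1])

    @property
    def spacing(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def length(self) -> float:
        return self.z_max - self.z_min

    @property
    def beta(self) -> float:
        """1/(kB T), mol/kcal."""
        return _beta(self.T)

    def with_ion(self, *, q: float | None = None, D: float | None = None,
                 ion_label: str | None = None) -> "FreeEnergySurface":
        """Copy of this surface with ion parameters replaced."""
        kw = {}
        if q is not None:
            kw["q"] = q
        if D is not None:
            kw["D"] = D
        if ion_label is not None:
            kw["ion_label"] = ion_label
        return replace(self, **kw)

    def interp_A(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation of the PMF between grid points."""
        return np.interp(z, self.z, self.A)

    def dA_dz(self) -> np.ndarray:
        """Central-difference PMF derivative on the grid (one-sided at ends)."""
        return np.gradient(self.A, self.spacing)


@dataclass(frozen=True)
class AppliedVoltage:
    """Boxcar applied field: total drop ``delta_v`` across ``[z_a, z_b]``.

    ``V(z)`` is 0 for ``z <= z_a``, linear inside the window, and equal to
    ``delta_v`` for ``z >= z_b`` (Å and mV).
    """

    delta_v: float
    z_a: float
    z_b: float

    def __post_init__(self) -> None:
        if not self.z_a < self.z_b:
            raise ValueError(f"need z_a < z_b, got [{self.z_a}, {self.z_b}]")

    @property
    def field(self) -> float:
        """Field strength inside the window, mV/Å."""
        return self.delta_v / (self.z_b - self.z_a)

    def profile(self, z: np.ndarray) -> np.ndarray:
        """V(z) in mV: clamped linear ramp."""
        z = np.asarray(z, dtype=float)
        frac = np.clip((z - self.z_a) / (self.z_b - self.z_a), 0.0, 1.0)
        return self.delta_v * frac

    def at(self, delta_v: float) -> "AppliedVoltage":
        """Same window at a different total drop."""
        return AppliedVoltage(delta_v, self.z_a, self.z_b)

    @staticmethod
    def full_window(surface: FreeEnergySurface, delta_v: float) -> "AppliedVoltage":
        """Ramp spanning the whole channel of ``surface``."""
        return AppliedVoltage(delta_v, surface.z_min, surface.z_max)


def total_energy(surface: FreeEnergySurface, voltage: AppliedVoltage) -> np.ndarray:
    """Total energy profile ``E(z) = A(z) + q V(z)`` in kcal/mol on the grid.

    The voltage term converts via 1 e·mV = 0.0230605 kcal/mol.  Positive
    ``delta_v`` raises the energy of a cation at the ``z_max`` side (so it
    drives anions forward and cations backward).
    """
    if voltage.z_a < surface.z_min - 1e-9 or voltage.z_b > surface.z_max + 1e-9:
        raise ValueError(
            f"voltage window [{voltage.z_a}, {voltage.z_b}] outside channel "
            f"domain [{surface.z_min}, {surface.z_max}]"
        )
    return surface.A + surface.q * KCAL_MOL_PER_E_MV * voltage.profile(surface.z)


# ---------------------------------------------------------------------------
# Synthetic archetypes
# ---------------------------------------------------------------------------

def _grid(z_min: float, z_max: float, n_points: int) -> np.ndarray:
    if n_points < _MIN_GRID_POINTS:
        raise ValueError(f"need at least {_MIN_GRID_POINTS} grid points")
    z = np.linspace(z_min, z_max, n_points)
    if z[1] - z[0] > _MAX_SPACING + 1e-12:
        raise ValueError(
            f"grid too coarse: spacing {z[1] - z[0]:.3f} Å exceeds {_MAX_SPACING} Å"
        )
    return z


def _gaussian(z: np.ndarray, center: float, width: float) -> np.ndarray:
    # width is the full width at half maximum converted to a Gaussian sigma
    sigma = width / 2.35482
    return np.exp(-0.5 * ((z - center) / sigma) ** 2)


def _flat_well(z: np.ndarray, plateau_width: float, depth: float,
               edge_width: float) -> np.ndarray:
    """Flat plateau of given width centered in the channel, cosine edges."""
    zc = 0.5 * (z[0] + z[-1])
    half = plateau_width / 2.0
    x = np.abs(z - zc)
    A = np.zeros_like(z)
    inside = x <= half
    ramp = (x > half) & (x < half + edge_width)
    A[inside] = -depth
    A[ramp] = -depth * 0.5 * (1.0 + np.cos(np.pi * (x[ramp] - half) / edge_width))
    return A


ARCHETYPES = ("flat_well", "central_barrier", "mouth_barriers", "tall_barrier",
              "tabulated")


def make_synthetic_pmf(
    archetype: str,
    *,
    z_min: float = -15.0,
    z_max: float = 15.0,
    n_points: int = 61,
    height: float | None = None,
    width: float | None = None,
    depth: float = 0.5,
    plateau_width: float = 18.0,
    edge_width: float = 3.0,
    mouth_offset: float = 4.0,
    z: np.ndarray | None = None,
    A: np.ndarray | None = None,
    D: float = 50.0,
    q: float = 1.0,
    T: float = DEFAULT_TEMPERATURE,
    ion_label: str | None = None,
) -> FreeEnergySurface:
    """Build a named synthetic PMF archetype.

    Archetypes
    ----------
    ``flat_well``
        PMF flat (at ``-depth`` kcal/mol) over a plateau of ``plateau_width``
        Å in the channel center, rising to 0 at the boundaries over
        ``edge_width`` Å.  Emulates a wide featureless pore that is weakly
        attractive for the permeant ion.
    ``central_barrier``
        Single Gaussian barrier of ``height`` kcal/mol (default 2) and FWHM
        ``width`` Å (default 4) at the channel midpoint.
    ``mouth_barriers``
        Two Gaussian barriers of ``height`` kcal/mol (default 2) located
        ``mouth_offset`` Å inside either boundary, with a shallow well
        (``-depth``) in between.
    ``tall_barrier``
        Like ``central_barrier`` but high (default 7 kcal/mol, must be
        ≥ 5) and wide (default ``width`` 6 Å): the rare-crossing regime.
    ``tabulated``
        Arbitrary ``z``/``A`` arrays supplied by the caller.

    All archetypes are referenced so that ``A(z_min) = 0``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")

    if archetype == "tabulated":
        if z is None or A is None:
            raise ValueError("tabulated archetype requires z and A arrays")
        grid = np.asarray(z, dtype=float)
        prof = np.asarray(A, dtype=float)
    else:
        grid = _grid(z_min, z_max, n_points)
        zc = 0.5 * (z_min + z_max)
        if archetype == "flat_well":
            if plateau_width <= 0 or edge_width <= 0:
                raise ValueError("plateau_width and edge_width must be positive")
            if plateau_width + 2 * edge_width > (z_max - z_min):
                raise ValueError("plateau plus edges wider than the channel")
            prof = _flat_well(grid, plateau_width, depth, edge_width)
        elif archetype == "central_barrier":
            h = 2.0 if height is None else height
            w = 4.0 if width is None else width
            if w <= 0:
                raise ValueError("width must be positive")
            prof = h * _gaussian(grid, zc, w)
        elif archetype == "mouth_barriers":
            h = 2.0 if height is None else height
            w = 2.5 if width is None else width
            if w <= 0 or mouth_offset <= 0:
                raise ValueError("width and mouth_offset must be positive")
            prof = (h * _gaussian(grid, z_min + mouth_offset, w)
                    + h * _gaussian(grid, z_max - mouth_offset, w)
                    - depth * _gaussian(grid, zc, (z_max - z_min) / 3.0))
        else:  # tall_barrier
            h = 7.0 if height is None else height
            if h < 5.0:
                raise ValueError("tall_barrier height must be at least 5 kcal/mol")
            w = 6.0 if width is None else width
            if w <= 0:
                raise ValueError("width must be positive")
            prof = h * _gaussian(grid, zc, w)

    prof = prof - prof[0]  # reference convention A(z_min) = 0
    label = ion_label if ion_label is not None else archetype
    return FreeEnergySurface(z=grid, A=prof, D=D, q=q, T=T, ion_label=label)


# ---------------------------------------------------------------------------
# Plain-text PMF tables
# ---------------------------------------------------------------------------

def save_pmf_table(surface: FreeEnergySurface, path: Union[str, Path]) -> None:
    """Write the PMF as a two-column text table (`#`-prefixed header)."""
    header = (
        "z_angstrom  A_kcal_per_mol\n"
        f"ion={surface.ion_label} D={surface.D!r} q={surface.q!r} T={surface.T!r}"
    )
    np.savetxt(path, np.column_stack([surface.z, surface.A]),
               fmt="%.17g", header=header)


def load_pmf_table(
    path: Union[str, Path],
    *,
    D: float,
    q: float,
    T: float = DEFAULT_TEMPERATURE,
    ion_label: str = "ion",
) -> FreeEnergySurface:
    """Load a two-column z/A text table (Å, kcal/mol).

    Lines starting with ``#`` are ignored.  The ion metadata (``D``, ``q``,
    ``T``) is not part of the table and must be supplied by the caller.
    """
    try:
        data = np.loadtxt(path, comments="#")
    except ValueError as exc:
        raise ValueError(f"non-numeric data in PMF table {path}: {exc}") from exc
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"PMF table {path} must have two columns (z, A)")
    return FreeEnergySurface(z=data[:, 0], A=data[:, 1], D=D, q=q, T=T,
                             ion_label=ion_label)
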