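"""Discrete beta emission spectra from allowed-decay (Fermi) theory.

A beta branch is described by its endpoint (maximum) kinetic energy ``Q`` in
MeV, the daughter atomic number (positive for beta-minus, negative for
beta-plus by convention), and its intensity in emissions per decay.  The
differential emission probability on a kinetic-energy grid follows the
allowed-transition phase-space shape

    dn/dE  propto  F(Z, W) * p * W * (W0 - W)^2 * C(E)

with ``W``/``p`` the total energy/momentum of the electron in units of
``m_e c^2`` and ``C(E)`` an optional spectral shape factor (unity for allowed
transitions; ``p^2 + q^2`` for unique first-forbidden ones).  The Coulomb
correction ``F`` uses the standard nonrelativistic point-charge approximation
``F = 2 pi eta / (1 - exp(-2 pi eta))``, ``eta = +- alpha Z W / p`` — adequate
for regenerating desk-scale emission spectra; it skews beta-minus spectra
toward low energies as the relativistic form does.

Spectra are held on strictly increasing kinetic-energy grids as densities in
(per decay per MeV); all integrals are trapezoidal on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS_MEV",
    "FINE_STRUCTURE",
    "InvalidBranchError",
    "SpectrumParseError",
    "BetaBranch",
    "BetaSpectrum",
    "Nuclide",
    "unique_first_forbidden_factor",
    "fermi_function",
    "fermi_branch_spectrum",
    "combine_branches",
    "mean_energy",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_nuclide_library",
]

ELECTRON_MASS_MEV = 0.51099895
FINE_STRUCTURE = 7.2973525693e-3

#: default number of kinetic-energy bins for generated spectra
DEFAULT_N_BINS = 500

SPECTRUM_HEADER = ("energy_MeV", "intensity_per_MeV")


class InvalidBranchError(ValueError):
    """Raised for unphysical branch parameters (Q <= 0, intensity out of (0,1])."""


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum CSV files; carries the offending line."""


class UndefinedMeanError(ZeroDivisionError):
    """Raised when a spectrum has zero total yield."""


@dataclass(frozen=True)
class BetaBranch:
    """One beta transition: endpoint energy, daughter Z, intensity, shape."""

    endpoint_energy: float  # Q, MeV
    daughter_z: int  # signed: >0 beta-minus, <0 beta-plus
    intensity: float  # emissions per decay, (0, 1]
    shape_factor: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.endpoint_energy > 0.0):
            raise InvalidBranchError(
                f"endpoint energy {self.endpoint_energy!r} must be > 0 MeV"
            )
        if not (0.0 < self.intensity <= 1.0):
            raise InvalidBranchError(
                f"intensity {self.intensity!r} must be in (0, 1]"
            )


@dataclass(frozen=True)
class BetaSpectrum:
    """Discrete spectrum: density dn/dE (per decay per MeV) on an energy grid."""

    energy_grid: np.ndarray
    intensity_density: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        d = np.asarray(self.intensity_density, dtype=float)
        if e.ndim != 1 or e.shape != d.shape or e.size < 2:
            raise ValueError("energy grid and density must be equal-length 1-D arrays")
        if not np.all(e > 0.0) or not np.all(np.diff(e) > 0.0):
            raise ValueError("energies must be strictly increasing and positive")
        if np.any(d < 0.0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "intensity_density", d)

    @property
    def total_yield(self) -> float:
        """Emissions per decay: trapezoidal integral of the density."""
        return float(np.trapezoid(self.intensity_density, self.energy_grid))

    @property
    def endpoint(self) -> float:
        return float(self.energy_grid[-1])


def unique_first_forbidden_factor(q_mev: float) -> Callable[[np.ndarray], np.ndarray]:
    """Shape factor ``p^2 + q^2`` for unique first-forbidden transitions.

    ``p`` is the electron momentum and ``q = (W0 - W)`` the neutrino momentum,
    both in units of ``m_e c``.
    """

    w0 = 1.0 + q_mev / ELECTRON_MASS_MEV

    def factor(energy_mev: np.ndarray) -> np.ndarray:
        w = 1.0 + np.asarray(energy_mev, dtype=float) / ELECTRON_MASS_MEV
        p2 = np.clip(w * w - 1.0, 0.0, None)
        return p2 + (w0 - w) ** 2

    return factor


def fermi_function(daughter_z: int, energy_mev: np.ndarray) -> np.ndarray:
    """Nonrelativistic Coulomb correction F(Z, W).

    ``eta = alpha Z W / p`` for beta-minus (Z > 0); the sign of Z carries the
    beta-minus/beta-plus convention.  ``F -> 1`` as ``Z -> 0``.
    """
    e = np.asarray(energy_mev, dtype=float)
    if daughter_z == 0:
        return np.ones_like(e)
    w = 1.0 + e / ELECTRON_MASS_MEV
    p = np.sqrt(np.clip(w * w - 1.0, 1e-300, None))
    eta = FINE_STRUCTURE * daughter_z * w / p
    x = 2.0 * math.pi * eta
    # stable evaluation of x / (1 - exp(-x)) for either sign of x
    with np.errstate(over="ignore"):
        out = np.where(
            np.abs(x) < 1e-9, 1.0 + x / 2.0, x / (-np.expm1(-x))
        )
    return out


def _phase_space_density(branch: BetaBranch, energies: np.ndarray) -> np.ndarray:
    """Unnormalized allowed-shape density on the given kinetic energies."""
    q = branch.endpoint_energy
    e = np.asarray(energies, dtype=float)
    w = 1.0 + e / ELECTRON_MASS_MEV
    w0 = 1.0 + q / ELECTRON_MASS_MEV
    p = np.sqrt(np.clip(w * w - 1.0, 0.0, None))
    density = fermi_function(branch.daughter_z, e) * p * w * (w0 - w) ** 2
    if branch.shape_factor is not None:
        density = density * branch.shape_factor(e)
    density[e >= q] = 0.0
    return np.clip(density, 0.0, None)


def _branch_grid(q_max: float, n_bins: int) -> np.ndarray:
    # open at zero (the density limit there needs special casing), closed at
    # the endpoint where the (W0 - W)^2 factor kills the density exactly;
    # the lower edge is fixed at 1e-6 Q so grid refinement changes only the
    # discretization, never the integration domain
    return np.linspace(q_max * 1e-6, q_max, n_bins)


def fermi_branch_spectrum(branch: BetaBranch, n_bins: int = DEFAULT_N_BINS) -> BetaSpectrum:
    """Discretized Fermi-theory spectrum of one branch.

    Uniform kinetic-energy grid on ``(0, Q]``; normalized so the trapezoidal
    integral of the density equals the branch intensity.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    grid = _branch_grid(branch.endpoint_energy, n_bins)
    density = _phase_space_density(branch, grid)
    norm = np.trapezoid(density, grid)
    if norm <= 0.0:
        raise InvalidBranchError("branch density integrates to zero")
    return BetaSpectrum(grid, density * (branch.intensity / norm))


@dataclass(frozen=True)
class Nuclide:
    """A named beta emitter: one or more branches; mean energy is derived."""

    name: str
    branches: tuple[BetaBranch, ...]
    _mean_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.branches:
            raise InvalidBranchError(f"nuclide {self.name!r} has no branches")
        object.__setattr__(self, "branches", tuple(self.branches))

    @property
    def mean_energy(self) -> float:
        """Mean kinetic energy (MeV) of the combined emission spectrum."""
        if "mean" not in self._mean_cache:
            self._mean_cache["mean"] = mean_energy(combine_branches(self))
        return self._mean_cache["mean"]

    @property
    def max_endpoint(self) -> float:
        return max(b.endpoint_energy for b in self.branches)

    @property
    def total_intensity(self) -> float:
        return sum(b.intensity for b in self.branches)


def combine_branches(nuclide: Nuclide, n_bins: int = DEFAULT_N_BINS) -> BetaSpectrum:
    """Total emission spectrum: sum of branch densities on a common grid.

    The common grid spans ``(0, max Q]``; each branch density is evaluated
    directly on it and normalized there, so the total yield is the sum of the
    branch intensities to trapezoid accuracy.
    """
    grid = _branch_grid(nuclide.max_endpoint, n_bins)
    total = np.zeros_like(grid)
    for branch in nuclide.branches:
        density = _phase_space_density(branch, grid)
        norm = np.trapezoid(density, grid)
        if norm <= 0.0:
            raise InvalidBranchError(
                f"branch Q={branch.endpoint_energy} of {nuclide.name!r} has zero density on the common grid"
            )
        total += density * (branch.intensity / norm)
    return BetaSpectrum(grid, total)


def mean_energy(spectrum: BetaSpectrum) -> float:
    """Yield-weighted mean energy ``int E (dn/dE) dE / int (dn/dE) dE`` (MeV)."""
    e, d = spectrum.energy_grid, spectrum.intensity_density
    norm = np.trapezoid(d, e)
    if norm <= 0.0:
        raise UndefinedMeanError("spectrum has zero total yield")
    return float(np.trapezoid(e * d, e) / norm)


# ---------------------------------------------------------------------------
# spectrum CSV I/O
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: BetaSpectrum, path: str | Path) -> None:
    """Write a two-column CSV ``energy_MeV,intensity_per_MeV``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(SPECTRUM_HEADER) + "\n")
        for e, d in zip(spectrum.energy_grid, spectrum.intensity_density):
            fh.write(f"{e:.12g},{d:.12g}\n")


def read_spectrum_csv(path: str | Path) -> BetaSpectrum:
    """Read a two-column spectrum CSV, validating order and positivity."""
    path = Path(path)
    energies: list[float] = []
    densities: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if [h.strip() for h in header.split(",")] != list(SPECTRUM_HEADER):
            raise SpectrumParseError(
                f"{path}: line 1: expected header {','.join(SPECTRUM_HEADER)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                e, d = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise SpectrumParseError(f"{path}: line {lineno}: malformed row {line!r}") from exc
            if e <= 0.0:
                raise SpectrumParseError(f"{path}: line {lineno}: non-positive energy {e}")
            if d < 0.0:
                raise SpectrumParseError(f"{path}: line {lineno}: negative density {d}")
            if energies and e <= energies[-1]:
                raise SpectrumParseError(f"{path}: line {lineno}: energies not strictly increasing")
            energies.append(e)
            densities.append(d)
    if len(energies) < 2:
        raise SpectrumParseError(f"{path}: need at least two rows")
    return BetaSpectrum(np.array(energies), np.array(densities))


# ---------------------------------------------------------------------------
# nuclide library
# ---------------------------------------------------------------------------

def load_nuclide_library(path: str | Path | None = None) -> Mapping[str, Nuclide]:
    """Load the branch-level decay library CSV into Nuclide objects.

    Columns: ``nuclide,branch,Q_MeV,daughter_Z,intensity,forbiddenness``.
    Branches tagged ``1u`` get the unique first-forbidden shape factor;
    everything else is treated as allowed (unity shape factor).
    """
    import pandas as pd

    if path is None:
        from importlib.resources import files

        path = files("betadose.data") / "nuclides.csv"
        frame = pd.read_csv(str(path), comment="#")
    else:
        frame = pd.read_csv(path, comment="#")
    library: dict[str, Nuclide] = {}
    for name, group in frame.groupby("nuclide", sort=False):
        branches = []
        for row in group.itertuples():
            shape = (
                unique_first_forbidden_factor(float(row.Q_MeV))
                if str(row.forbiddenness).strip() == "1u"
                else None
            )
            branches.append(
                BetaBranch(
                    endpoint_energy=float(row.Q_MeV),
                    daughter_z=int(row.daughter_Z),
                    intensity=float(row.intensity),
                    shape_factor=shape,
                )
            )
        library[str(name)] = Nuclide(str(name), tuple(branches))
    return library
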