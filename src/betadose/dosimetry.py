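"""MIRD self-dose for beta emitters uniformly distributed in a target.

For a mono-energetic emission the mean self-dose is

    D = A_tilde * n * E * phi / m

with ``A_tilde`` the time-integrated activity (decays), ``n`` the emission
yield per decay, ``E`` the particle energy, ``phi`` the absorbed fraction and
``m`` the target mass.  For a full beta spectrum the product ``n E phi`` is
replaced by the integral ``int (dn/dE) E phi(E) dE`` over the spectrum.

Public interfaces use cm / g / MeV / MBq.s / uGy; every conversion goes
through the UNIT constants below (Gy = J/kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import Ellipsoid, ellipsoid_volume, generalized_radius
from .phi_model import EnergyParamModel, phi as phi_eval
from .spectrum import BetaSpectrum

__all__ = [
    "UNIT",
    "Material",
    "DoseResult",
    "soft_tissue",
    "mass_from_volume",
    "self_dose_mono",
    "self_dose_spectrum",
]

#: centralized unit-conversion constants
UNIT = {
    "J_per_MeV": 1.602176634e-13,
    "decays_per_MBq_s": 1.0e6,
    "kg_per_g": 1.0e-3,
    "uGy_per_Gy": 1.0e6,
}

#: atomic number and standard atomic weight of the tissue elements
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Si": (14, 28.085),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "K": (19, 39.098), "Ca": (20, 40.078), "Fe": (26, 55.845),
    "Zn": (30, 65.38), "Rb": (37, 85.468), "Zr": (40, 91.224),
}


@dataclass(frozen=True)
class Material:
    """Elemental composition (percent by weight) and density (g/cm^3)."""

    mass_fractions: Mapping[str, float]
    density: float

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"mass fractions sum to {total}, expected 100 +- 0.01")
        if not (self.density > 0.0):
            raise ValueError(f"density {self.density!r} must be > 0 g/cm^3")
        object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))

    @property
    def z_over_a(self) -> float:
        """Mean ratio of atomic number to atomic weight, mass-weighted."""
        return sum(
            (w / 100.0) * ELEMENTS[el][0] / ELEMENTS[el][1]
            for el, w in self.mass_fractions.items()
            if el in ELEMENTS
        )


_SOFT_TISSUE_CACHE: list = []


def soft_tissue() -> Material:
    """The packaged soft-tissue composition (density 1.04 g/cm^3)."""
    if not _SOFT_TISSUE_CACHE:
        from .fixtures import load_fixture

        fixture = load_fixture(1)
        frame = fixture.data
        fractions = dict(zip(frame["element"], frame["percent_by_weight"]))
        _SOFT_TISSUE_CACHE.append(Material(fractions, fixture.meta["density_g_cm3"]))
    return _SOFT_TISSUE_CACHE[0]


@dataclass(frozen=True)
class DoseResult:
    """Self-dose per unit time-integrated activity with its provenance."""

    dose_per_tia: float  # uGy per MBq.s
    mass: float  # g
    effective_phi: float
    energy_integral: float  # MeV per decay, int (dn/dE) E dE
    metadata: dict = field(default_factory=dict)


def mass_from_volume(volume: float, material: Material) -> float:
    """Target mass in g: volume (cm^3) times density (g/cm^3)."""
    if not (volume > 0.0):
        raise ValueError(f"volume {volume!r} must be > 0 cm^3")
    return volume * material.density


def self_dose_mono(
    tia: float, mass: float, energy: float, yield_n: float, phi: float
) -> float:
    """Mono-energetic MIRD self-dose in uGy.

    ``tia`` in MBq.s, ``mass`` in g, ``energy`` in MeV, ``yield_n`` per decay,
    ``phi`` dimensionless in [0, 1].
    """
    if mass <= 0.0:
        raise ValueError("mass must be > 0 g")
    if tia < 0.0 or energy < 0.0 or yield_n < 0.0 or not (0.0 <= phi <= 1.0):
        raise ValueError("tia, energy, yield must be >= 0 and phi in [0, 1]")
    energy_j = tia * UNIT["decays_per_MBq_s"] * yield_n * energy * phi * UNIT["J_per_MeV"]
    gray = energy_j / (mass * UNIT["kg_per_g"])
    return gray * UNIT["uGy_per_Gy"]


def self_dose_spectrum(
    tia: float,
    shape: Ellipsoid,
    spectrum: BetaSpectrum,
    model: EnergyParamModel,
    material: Material,
    metadata: dict | None = None,
) -> DoseResult:
    """Spectrum-integrated MIRD self-dose.

    ``D = (A_tilde / m) int (dn/dE) E phi(E, rho(shape)) dE`` with the
    trapezoidal rule on the spectrum grid; the absorbed fraction at each grid
    energy comes from the energy-parameterized phi(rho) model.
    """
    volume = ellipsoid_volume(shape)
    mass = mass_from_volume(volume, material)
    rho = generalized_radius(shape)
    e = spectrum.energy_grid
    d = spectrum.intensity_density
    energy_integral = float(np.trapezoid(d * e, e))
    if energy_integral <= 0.0:
        raise ValueError("spectrum has zero energy integral")
    lo, hi = model.energy_range
    if e[-1] > hi or e[0] < lo:
        model._check_range(float(e[-1] if e[-1] > hi else e[0]))
    phis = np.array(
        [phi_eval(rho, model.params_at(float(ei), check=False)) for ei in e]
    )
    absorbed_integral = float(np.trapezoid(d * e * phis, e))
    per_tia = self_dose_mono(1.0, mass, 1.0, 1.0, 1.0) * absorbed_integral
    meta = {
        "rho_cm": rho,
        "volume_cm3": volume,
        "model": model.provenance,
        "total_dose_uGy": per_tia * tia,
        "tia_MBq_s": tia,
    }
    if metadata:
        meta.update(metadata)
    return DoseResult(
        dose_per_tia=per_tia,
        mass=mass,
        effective_phi=absorbed_integral / energy_integral,
        energy_integral=energy_integral,
        metadata=meta,
    )
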