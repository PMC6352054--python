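"""Analytical absorbed-fraction model phi(rho).

The self-absorbed fraction of beta energy in an ellipsoid of soft tissue is
modelled as a sigmoid in the generalized radius ``rho = 3V/S``:

    phi(rho) = (1 + (rho0 / rho)^s)^(-(1 + p))

``rho0`` (cm) is the cutoff radius separating the escape-dominated from the
containment-dominated regime, ``s`` controls the steepness of the transition
and ``p`` the approach to saturation.  For ``rho >> rho0`` the absorbed
fraction tends to one; for ``rho << rho0`` it falls off as the power law
``(rho / rho0)^(s (1 + p))``.

Nuclide-to-nuclide variation is captured by letting the three parameters
depend on the mean beta energy ``E`` of the emitter: ``rho0(E) = k E``
(the cutoff radius scales with the beta range, roughly proportional to the
energy in this regime) while ``s(E)`` and ``p(E)`` are low-order polynomials
with no imposed monotonicity.  Energy-weighted averaging over an emission
spectrum then gives an effective absorbed fraction for a full beta spectrum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectrum import BetaSpectrum

__all__ = [
    "PhiModelParams",
    "EnergyParamModel",
    "EnergyRangeWarning",
    "phi",
    "phi_mono",
    "phi_spectrum_effective",
]

logger = logging.getLogger("betadose")


class EnergyRangeWarning(UserWarning):
    """Emitted when the energy-parameter model is evaluated outside its range."""


@dataclass(frozen=True)
class PhiModelParams:
    """The (s, rho0, p) triple of the phi(rho) sigmoid.

    ``phi_exponent_p`` is named to avoid collision with the Thomsen surface
    exponent.  ``1 + p > 0`` and ``s > 0`` are required so that phi is
    strictly increasing in rho.
    """

    s: float
    rho0: float
    phi_exponent_p: float
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if not (self.s > 0.0):
            raise ValueError(f"s={self.s!r} must be > 0")
        if not (self.rho0 > 0.0):
            raise ValueError(f"rho0={self.rho0!r} must be > 0 cm")
        if not (1.0 + self.phi_exponent_p > 0.0):
            raise ValueError(f"1 + p must be > 0, got p={self.phi_exponent_p!r}")


def phi(rho, params: PhiModelParams):
    """Absorbed fraction at generalized radius ``rho`` (cm); vectorized.

    Evaluated in log space for numerical robustness at extreme rho.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0.0):
        raise ValueError("rho must be > 0 cm")
    # log1p((rho0/rho)^s) guards against overflow for rho << rho0
    log_ratio = params.s * (np.log(params.rho0) - np.log(rho_arr))
    out = np.exp(-(1.0 + params.phi_exponent_p) * np.logaddexp(0.0, log_ratio))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnergyParamModel:
    """s(E), rho0(E), p(E) versus mean beta energy E (MeV).

    ``rho0_slope`` gives ``rho0(E) = rho0_slope * E`` (cm/MeV, through the
    origin); ``s_coeffs`` and ``p_coeffs`` are polynomial coefficients in
    ascending order.  ``energy_range`` records the span of the calibration
    data; evaluation outside it warns but proceeds.
    """

    rho0_slope: float
    s_coeffs: tuple[float, ...]
    p_coeffs: tuple[float, ...]
    energy_range: tuple[float, float]
    provenance: str = "user-supplied"

    def _check_range(self, energy: float) -> None:
        lo, hi = self.energy_range
        if not (lo <= energy <= hi):
            message = (
                f"energy {energy:.4g} MeV outside model validity range "
                f"[{lo:.4g}, {hi:.4g}] MeV; extrapolating"
            )
            logger.warning(message)
            warnings.warn(message, EnergyRangeWarning, stacklevel=3)

    def s_of(self, energy: float) -> float:
        return float(np.polynomial.polynomial.polyval(energy, self.s_coeffs))

    def rho0_of(self, energy: float) -> float:
        return float(self.rho0_slope * energy)

    def p_of(self, energy: float) -> float:
        return float(np.polynomial.polynomial.polyval(energy, self.p_coeffs))

    def params_at(self, energy: float, check: bool = True) -> PhiModelParams:
        """Model parameters at one energy.

        Above the calibration range the parameters are frozen at their
        upper-edge values (the polynomial forms are not trustworthy there);
        below it they extrapolate smoothly toward rho0 -> 0 (full
        absorption).  Either case emits an EnergyRangeWarning unless
        ``check`` is false (used by spectrum integrals that warn once for
        the whole support).  s and p are clamped to the model's admissible
        domain for numerical safety.
        """
        if check:
            self._check_range(energy)
        e_eval = min(energy, self.energy_range[1])
        return PhiModelParams(
            s=max(self.s_of(e_eval), 1e-6),
            rho0=max(self.rho0_of(e_eval), 1e-30),
            phi_exponent_p=max(self.p_of(e_eval), -0.989),
            provenance=f"{self.provenance} @ E={energy:.6g} MeV",
        )


def phi_mono(rho: float, energy: float, model: EnergyParamModel) -> float:
    """Absorbed fraction for mono-energetic electrons of the given energy."""
    return phi(rho, model.params_at(energy))


def phi_spectrum_effective(
    spectrum: BetaSpectrum, rho: float, model: EnergyParamModel
) -> float:
    """Energy-weighted effective absorbed fraction for a full beta spectrum.

    ``phi_eff = int (dn/dE) E phi(E, rho) dE / int (dn/dE) E dE`` by the
    trapezoidal rule on the spectrum grid.  Reduces to ``phi_mono`` for a
    delta-like spectrum, and to 1 when phi(E) is 1 over the support.
    """
    e = spectrum.energy_grid
    d = spectrum.intensity_density
    denom = np.trapezoid(d * e, e)
    if denom <= 0.0:
        raise ValueError("spectrum has zero energy integral")
    lo, hi = model.energy_range
    if e[-1] > hi or e[0] < lo:
        model._check_range(float(e[-1] if e[-1] > hi else e[0]))
    phis = np.array(
        [phi(rho, model.params_at(float(ei), check=False)) for ei in e]
    )
    return float(np.trapezoid(d * e * phis, e) / denom)
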