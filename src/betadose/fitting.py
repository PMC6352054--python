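"""Nonlinear least-squares estimation of the phi(rho) model parameters.

``fit_phi`` estimates the (s, rho0, p) triple from a set of (rho, phi)
observations by bounded trust-region least squares; ``goodness`` reports the
standard R^2 and SSE diagnostics; ``fit_energy_dependence`` regresses the
per-nuclide parameters on the mean beta energy to produce the s(E), rho0(E),
p(E) model used for arbitrary spectra.

Initialization is deterministic and documented: ``rho0`` starts at the rho
where the data cross phi = 0.5 by linear interpolation (falling back to the
geometric mean of the rho range), ``s`` at 1.13 (a representative literature
value for beta emitters in tissue) and ``p`` at 0.1.  On non-convergence the
fit restarts from three fixed multiplicative perturbations of that start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phi_model import EnergyParamModel, PhiModelParams, phi

__all__ = [
    "PhiDataset",
    "FitResult",
    "UnderdeterminedError",
    "fit_phi",
    "goodness",
    "fit_energy_dependence",
]

# bound constraints for (s, rho0, p); rho0 may approach zero because the
# model degenerates smoothly into the stretched-exponential limit
# phi ~ exp(-(1+p)(rho0/rho)^s) there, which the data often prefer
_LOWER = np.array([1e-6, 1e-30, -0.99])
_UPPER = np.array([10.0, 100.0, 10.0])
_S_INIT = 1.13
_P_INIT = 0.1
# internal optimization runs on (s, ln rho0, ln(1+p)) so the rho0 decades
# and the (rho0, p) trade-off are well scaled for the trust region
_T_LOWER = np.array([_LOWER[0], np.log(_LOWER[1]), np.log1p(_LOWER[2])])
_T_UPPER = np.array([_UPPER[0], np.log(_UPPER[1]), np.log1p(_UPPER[2])])


class UnderdeterminedError(ValueError):
    """Raised when fewer distinct observations than free parameters."""


@dataclass(frozen=True)
class PhiDataset:
    """(rho, phi) observations with optional absolute uncertainties."""

    rho: np.ndarray
    phi: np.ndarray
    sigma_phi: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        phi_ = np.asarray(self.phi, dtype=float)
        if rho.shape != phi_.shape or rho.ndim != 1:
            raise ValueError("rho and phi must be equal-length 1-D arrays")
        if np.any(rho <= 0.0):
            raise ValueError("all rho must be > 0 cm")
        if np.any((phi_ <= 0.0) | (phi_ > 1.0)):
            raise ValueError("all phi must lie in (0, 1]")
        sigma = self.sigma_phi
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != rho.shape or np.any(sigma < 0.0):
                raise ValueError("sigma_phi must be non-negative and match rho")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "phi", phi_)
        object.__setattr__(self, "sigma_phi", sigma)

    def __len__(self) -> int:
        return self.rho.size


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics."""

    params: PhiModelParams
    r_squared: float
    sse: float
    n_points: int
    converged: bool
    covariance: np.ndarray | None

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(self.sse / self.n_points))


def _initial_guess(rho: np.ndarray, phi_obs: np.ndarray) -> np.ndarray:
    order = np.argsort(rho)
    r_sorted, f_sorted = rho[order], phi_obs[order]
    rho0 = None
    for i in range(len(r_sorted) - 1):
        f0, f1 = f_sorted[i], f_sorted[i + 1]
        if (f0 - 0.5) * (f1 - 0.5) <= 0.0 and f0 != f1:
            t = (0.5 - f0) / (f1 - f0)
            rho0 = r_sorted[i] + t * (r_sorted[i + 1] - r_sorted[i])
            break
    if rho0 is None or rho0 <= 0.0:
        rho0 = float(np.sqrt(r_sorted[0] * r_sorted[-1]))
    return np.array([_S_INIT, rho0, _P_INIT])


def _start_points(rho: np.ndarray, phi_obs: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start schedule in (s, rho0, p).

    Besides the documented default start, estimate ``s`` and the amplitude
    ``A`` of the stretched-exponential limit ``-ln phi ~ A rho^(-s)`` by
    linear regression of ``ln(-ln phi)`` on ``ln rho``, and seed starts with
    ``rho0 = (A / (1 + p))^(1/s)`` for several p.
    """
    starts = [_initial_guess(rho, phi_obs)]
    safe = np.clip(phi_obs, 1e-12, 1.0 - 1e-12)
    y = np.log(-np.log(safe))
    x = np.log(rho)
    slope, intercept = np.polyfit(x, y, 1)
    s_est = float(np.clip(-slope, _LOWER[0], _UPPER[0]))
    amplitude = float(np.exp(intercept))
    for p0 in (0.1, 1.0, 9.0):
        rho0 = (amplitude / (1.0 + p0)) ** (1.0 / s_est)
        starts.append(np.array([s_est, rho0, p0]))
    return [np.clip(s, _LOWER, _UPPER) for s in starts]


def _default_weights(data: PhiDataset) -> np.ndarray | None:
    if data.sigma_phi is not None and np.all(data.sigma_phi > 0.0):
        return 1.0 / data.sigma_phi**2
    return None


def fit_phi(data: PhiDataset, weights: np.ndarray | None = None) -> FitResult:
    """Weighted least-squares fit of phi(rho; s, rho0, p).

    Minimizes ``sum_i w_i (phi_i - phi(rho_i))^2`` over the bounded box
    s in (0, 10], rho0 in (0, 100] cm, p in (-0.99, 10].  Weights default to
    ``1/sigma_phi^2`` when uncertainties are available, else unity.
    Deterministic: fixed start, fixed restart schedule.
    """
    if len(np.unique(data.rho)) < 4:
        raise UnderdeterminedError(
            "need >= 4 points with distinct rho to fit 3 parameters"
        )
    if weights is None:
        weights = _default_weights(data)
    sqrt_w = np.sqrt(weights) if weights is not None else np.ones(len(data))

    def residuals(theta_t: np.ndarray) -> np.ndarray:
        params = PhiModelParams(
            theta_t[0], math.exp(theta_t[1]), math.expm1(theta_t[2]),
            provenance="fit",
        )
        return sqrt_w * (phi(data.rho, params) - data.phi)

    def transform(theta: np.ndarray) -> np.ndarray:
        return np.clip(
            np.array([theta[0], np.log(theta[1]), np.log1p(theta[2])]),
            _T_LOWER, _T_UPPER,
        )

    best = None
    for start in _start_points(data.rho, data.phi):
        sol = least_squares(
            residuals, transform(start), bounds=(_T_LOWER, _T_UPPER),
            method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and best.cost < 1e-16:
            break

    params = PhiModelParams(
        best.x[0], math.exp(best.x[1]), math.expm1(best.x[2]), provenance="fit"
    )
    r2, sse = goodness(data, params)
    cov = None
    dof = len(data) - 3
    if dof > 0:
        jac = best.jac
        try:
            cov_t = np.linalg.pinv(jac.T @ jac) * (2.0 * best.cost / dof)
            # map back from (s, ln rho0, ln(1+p)) to (s, rho0, p)
            scale = np.diag([1.0, params.rho0, 1.0 + params.phi_exponent_p])
            cov = scale @ cov_t @ scale
        except np.linalg.LinAlgError:
            cov = None
    return FitResult(
        params=params,
        r_squared=r2,
        sse=sse,
        n_points=len(data),
        converged=bool(best.success),
        covariance=cov,
    )


def goodness(data: PhiDataset, params: PhiModelParams) -> tuple[float, float]:
    """(R^2, SSE) of the model against the data, unweighted.

    ``SSE = sum (phi_i - phi_hat_i)^2``; ``R^2 = 1 - SSE / SS_tot`` with
    ``SS_tot`` the variance of the observations about their mean.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    predicted = phi(data.rho, params)
    residuals = data.phi - predicted
    sse = float(np.sum(residuals**2))
    ss_tot = float(np.sum((data.phi - np.mean(data.phi)) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError("R^2 undefined: zero variance in phi")
    return 1.0 - sse / ss_tot, sse


def fit_energy_dependence(
    calibrations: list[tuple[float, PhiModelParams]],
    s_degree: int = 2,
    p_degree: int = 2,
) -> EnergyParamModel:
    """Regress per-nuclide (s, rho0, p) on mean beta energy E (MeV).

    ``rho0(E) = k E`` is fitted through the origin (the cutoff radius scales
    with the beta range); ``s(E)`` and ``p(E)`` are ordinary polynomial
    least-squares fits of the given degree.
    """
    n = len(calibrations)
    needed = max(s_degree, p_degree) + 1
    if n < max(needed, 3):
        raise UnderdeterminedError(
            f"need >= {max(needed, 3)} calibration points, got {n}"
        )
    energies = np.array([e for e, _ in calibrations], dtype=float)
    s_vals = np.array([p.s for _, p in calibrations])
    rho0_vals = np.array([p.rho0 for _, p in calibrations])
    p_vals = np.array([p.phi_exponent_p for _, p in calibrations])

    slope = float(np.sum(energies * rho0_vals) / np.sum(energies**2))
    s_coeffs = np.polynomial.polynomial.polyfit(energies, s_vals, s_degree)
    p_coeffs = np.polynomial.polynomial.polyfit(energies, p_vals, p_degree)
    return EnergyParamModel(
        rho0_slope=slope,
        s_coeffs=tuple(float(c) for c in s_coeffs),
        p_coeffs=tuple(float(c) for c in p_coeffs),
        energy_range=(float(energies.min()), float(energies.max())),
        provenance=f"energy-fit over {n} calibrations",
    )
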