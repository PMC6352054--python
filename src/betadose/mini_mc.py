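"""Simplified Monte Carlo validator for beta absorbed fractions.

This is an explicitly approximate estimator used to sanity-check the
analytical phi(rho) model, not a general-purpose electron transport code:
each history starts at a point sampled uniformly in the ellipsoid, travels in
a straight line along an isotropic direction, and loses energy continuously
at the collision stopping-power rate (CSDA) until it either slows below the
cutoff (remaining energy deposited) or crosses the boundary (remaining energy
escapes).  There is no multiple scattering, no bremsstrahlung and no
secondary-electron transport, so it underestimates absorption for
high-energy betas whose real trajectories curl back into the volume; it is
quantitatively meaningful only in the low-energy / strong-escape regime and
qualitatively (ordering, monotonicity) elsewhere.

The absorbed fraction estimate is energy-weighted:
``phi_hat = sum(deposited) / sum(emitted)`` over histories, with the standard
error from history-level batching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dosimetry import Material, soft_tissue
from .geometry import Ellipsoid
from .spectrum import BetaSpectrum

__all__ = [
    "McConfig",
    "McEstimate",
    "collision_stopping_power",
    "load_stopping_power_table",
    "sample_point_uniform",
    "sample_direction_isotropic",
    "sample_energies",
    "estimate_phi",
]

#: maximum fractional energy loss per transport step
MAX_STEP_ENERGY_FRACTION = 0.02


def collision_stopping_power(
    energy_mev: np.ndarray,
    z_over_a: float = 0.5513,
    mean_excitation_ev: float = 75.0,
) -> np.ndarray:
    """Electron collision mass stopping power (MeV cm^2/g), Berger-Seltzer form.

    ``S/rho = 0.153536 (Z/A) / beta^2 [ ln( tau^2 (tau+2) / 2 (I/mc^2)^2 )
    + F(tau) ]`` with ``F(tau) = 1 - beta^2 + (tau^2/8 - (2 tau + 1) ln 2)
    / (tau + 1)^2``.  The density-effect correction is omitted (it is small
    below a few MeV in unit-density tissue).
    """
    e = np.asarray(energy_mev, dtype=float)
    mc2 = 0.51099895
    tau = e / mc2
    beta2 = tau * (tau + 2.0) / (tau + 1.0) ** 2
    i_ratio = mean_excitation_ev * 1e-6 / mc2
    bracket = (
        np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio**2))
        + 1.0
        - beta2
        + (tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (tau + 1.0) ** 2
    )
    return 0.153536 * z_over_a / beta2 * bracket


def load_stopping_power_table() -> tuple[np.ndarray, np.ndarray]:
    """The packaged soft-tissue stopping-power table (energy MeV, MeV cm^2/g)."""
    import pandas as pd
    from importlib.resources import files

    path = files("betadose.data") / "stopping_power_soft_tissue.csv"
    frame = pd.read_csv(str(path), comment="#")
    return (
        frame["energy_MeV"].to_numpy(dtype=float),
        frame["mass_stopping_power_MeV_cm2_g"].to_numpy(dtype=float),
    )


@dataclass(frozen=True)
class McConfig:
    """Transport settings: histories, seed, cutoff, stopping powers, medium."""

    n_histories: int = 100_000
    seed: int = 0
    energy_cutoff: float = 0.001  # MeV
    stopping_power_table: tuple[np.ndarray, np.ndarray] | None = None
    material: Material | None = None
    n_batches: int = 20

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if not (self.energy_cutoff > 0.0):
            raise ValueError("energy cutoff must be > 0 MeV")
        if self.n_batches < 20:
            raise ValueError("need >= 20 batches for the error estimate")

    def resolved(self) -> "McConfig":
        table = self.stopping_power_table or load_stopping_power_table()
        if np.any(table[1] <= 0.0):
            raise ValueError("stopping powers must be positive over the table")
        material = self.material or soft_tissue()
        return McConfig(
            n_histories=self.n_histories,
            seed=self.seed,
            energy_cutoff=self.energy_cutoff,
            stopping_power_table=table,
            material=material,
            n_batches=self.n_batches,
        )


@dataclass(frozen=True)
class McEstimate:
    """Estimated absorbed fraction with batch-based standard error."""

    phi_hat: float
    std_error: float
    n_histories: int
    mean_deposited: float  # MeV per history
    mean_emitted: float  # MeV per history
    seed: int


def sample_point_uniform(shape: Ellipsoid, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Uniform points in the ellipsoid by rejection from the bounding box.

    Returns an ``(n, 3)`` array in cm.
    """
    axes = np.array([shape.a, shape.b, shape.c])
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        draw = max(n - filled, 1)
        # pi/6 acceptance in the box; oversample to limit iterations
        candidates = rng.uniform(-1.0, 1.0, size=(int(draw * 2.2) + 16, 3))
        inside = np.sum(candidates**2, axis=1) <= 1.0
        accepted = candidates[inside]
        take = min(len(accepted), n - filled)
        out[filled : filled + take] = accepted[:take] * axes
        filled += take
    return out


def sample_direction_isotropic(rng: np.random.Generator, n: int) -> np.ndarray:
    """Isotropic unit vectors, ``(n, 3)``."""
    mu = rng.uniform(-1.0, 1.0, size=n)
    az = rng.uniform(0.0, 2.0 * math.pi, size=n)
    sin_theta = np.sqrt(1.0 - mu**2)
    return np.column_stack(
        (sin_theta * np.cos(az), sin_theta * np.sin(az), mu)
    )


def sample_energies(
    spectrum: BetaSpectrum, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Kinetic energies (MeV) by inverse-CDF sampling of the discrete spectrum.

    The CDF is the cumulative trapezoid of the density; energies interpolate
    linearly inside grid bins.
    """
    e = spectrum.energy_grid
    d = spectrum.intensity_density
    bin_mass = 0.5 * (d[1:] + d[:-1]) * np.diff(e)
    cdf = np.concatenate(([0.0], np.cumsum(bin_mass)))
    if cdf[-1] <= 0.0:
        raise ValueError("spectrum has zero total yield")
    cdf /= cdf[-1]
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf, e)


def _distance_to_boundary(
    points: np.ndarray, directions: np.ndarray, shape: Ellipsoid
) -> np.ndarray:
    """Ray length from interior points to the ellipsoid surface (cm)."""
    axes = np.array([shape.a, shape.b, shape.c])
    ps = points / axes
    us = directions / axes
    a_coef = np.sum(us**2, axis=1)
    b_coef = np.sum(ps * us, axis=1)
    c_coef = np.sum(ps**2, axis=1) - 1.0
    disc = np.sqrt(np.clip(b_coef**2 - a_coef * c_coef, 0.0, None))
    return (disc - b_coef) / a_coef


def estimate_phi(
    shape: Ellipsoid,
    spectrum: BetaSpectrum,
    config: McConfig,
    return_histories: bool = False,
):
    """Straight-path CSDA estimate of the self-absorbed fraction.

    Per history: uniform origin, isotropic direction, spectrum-sampled
    energy; energy is deposited along the ray at the local linear stopping
    power (mass stopping power times density) in steps capped at 2% of the
    current energy, until the electron slows below the cutoff (remainder
    deposited) or reaches the boundary (remainder escapes).
    """
    config = config.resolved()
    sp_energy, sp_values = config.stopping_power_table
    if spectrum.endpoint > sp_energy[-1] or config.energy_cutoff < sp_energy[0]:
        raise ValueError(
            "spectrum support or cutoff outside the stopping-power table range "
            f"[{sp_energy[0]}, {sp_energy[-1]}] MeV"
        )
    log_e = np.log(sp_energy)
    log_s = np.log(sp_values)
    density = config.material.density

    rng = np.random.default_rng(config.seed)
    n = config.n_histories
    origins = sample_point_uniform(shape, rng, n)
    directions = sample_direction_isotropic(rng, n)
    energies = sample_energies(spectrum, rng, n)
    emitted = energies.copy()
    boundary = _distance_to_boundary(origins, directions, shape)

    remaining = energies.copy()
    path_left = boundary.copy()
    deposited = np.zeros(n)
    escaped = np.zeros(n)
    active = remaining > config.energy_cutoff
    # below-cutoff emissions deposit locally in full
    deposited[~active] = remaining[~active]
    remaining[~active] = 0.0

    while np.any(active):
        idx = np.flatnonzero(active)
        e_act = remaining[idx]
        # linear stopping power MeV/cm, log-log interpolation of the table
        s_lin = np.exp(np.interp(np.log(e_act), log_e, log_s)) * density
        de = np.minimum(MAX_STEP_ENERGY_FRACTION * e_act, e_act - config.energy_cutoff / 2.0)
        de = np.maximum(de, config.energy_cutoff * 0.5)
        ds = de / s_lin
        pl = path_left[idx]
        reach = ds >= pl
        # partial step up to the boundary: only the in-volume share deposits
        de_inside = np.where(reach, pl * s_lin, de)
        new_remaining = e_act - de
        deposited[idx] += de_inside
        path_left[idx] = pl - ds
        # boundary crossers: everything not deposited inside escapes
        escaped[idx[reach]] += new_remaining[reach] + (de[reach] - de_inside[reach])
        remaining[idx] = np.where(reach, 0.0, new_remaining)
        # slowed-down electrons deposit their remainder where they stop
        slowed = ~reach & (new_remaining <= config.energy_cutoff)
        deposited[idx[slowed]] += new_remaining[slowed]
        remaining[idx[slowed]] = 0.0
        active[idx[reach | slowed]] = False

    total_emitted = float(np.sum(emitted))
    total_deposited = float(np.sum(deposited))
    phi_hat = total_deposited / total_emitted

    # batch standard error on the ratio estimator
    batches = np.array_split(np.arange(n), config.n_batches)
    ratios = np.array(
        [np.sum(deposited[b]) / np.sum(emitted[b]) for b in batches if len(b)]
    )
    std_error = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))

    estimate = McEstimate(
        phi_hat=phi_hat,
        std_error=std_error,
        n_histories=n,
        mean_deposited=total_deposited / n,
        mean_emitted=total_emitted / n,
        seed=config.seed,
    )
    if return_histories:
        detail = {
            "emitted": emitted,
            "deposited": deposited,
            "escaped": escaped,
            "origins": origins,
            "directions": directions,
        }
        return estimate, detail
    return estimate
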