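"""Packaged reference tables and synthetic-data generation.

The package ships machine-readable transcriptions of the reference tables it
validates against: the soft-tissue composition (table 1), the Y-90 sphere
validation absorbed fractions (table 2), the full spectrum-vs-mean absorbed
fraction grid (table 3: 11 nuclides x 3 shapes x 4 volumes), and the
self-dose comparisons against a prior analytical model (table 5) and the
OLINDA/EXM sphere model (table 6).  Values are stored exactly as printed in
the source tabulations, including suspected typos; a ``flags`` column marks
cells whose sign or value does not recompute cleanly (``sign_suspect``,
``recompute_mismatch``, ``monotonicity_suspect``) rather than silently
correcting them.

``generate_synthetic_phi`` produces noisy synthetic (rho, phi) datasets from
known model parameters for estimator-recovery studies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd

from .fitting import PhiDataset
from .phi_model import PhiModelParams, phi

__all__ = [
    "ReferenceTable",
    "SyntheticPhiSpec",
    "TABLE_FILES",
    "load_fixture",
    "fixture_checksums",
    "table3_phi_dataset",
    "generate_synthetic_phi",
]

TABLE_FILES = {
    1: "soft_tissue.csv",
    2: "table2_y90_validation.csv",
    3: "table3_absorbed_fractions.csv",
    5: "table5_dose_vs_amato.csv",
    6: "table6_dose_vs_olinda.csv",
}

#: Table 3 sphere/ellipsoid volumes in cm^3
TABLE3_VOLUMES = (0.01, 1.0, 100.0, 200.0)
TABLE3_SHAPES = ("sphere", "prolate", "oblate")


@dataclass(frozen=True)
class ReferenceTable:
    """One transcribed reference table with per-cell flags."""

    table_id: int
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def flagged(self) -> pd.DataFrame:
        if "flags" not in self.data.columns:
            return self.data.iloc[0:0]
        return self.data[self.data["flags"].astype(str).str.len() > 0]


def _data_path(name: str):
    return files("betadose.data") / name


def load_fixture(table_id: int) -> ReferenceTable:
    """Load a packaged reference table by its id (1, 2, 3, 5 or 6)."""
    if table_id not in TABLE_FILES:
        raise KeyError(
            f"unknown table id {table_id!r}; available: {sorted(TABLE_FILES)}"
        )
    path = _data_path(TABLE_FILES[table_id])
    frame = pd.read_csv(str(path), comment="#")
    if "flags" in frame.columns:
        frame["flags"] = frame["flags"].fillna("")
    meta: dict = {}
    if table_id == 1:
        meta["density_g_cm3"] = 1.04
        total = frame["percent_by_weight"].sum()
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"tissue fractions sum to {total}, expected 100")
    if table_id == 3:
        expected = 11 * len(TABLE3_SHAPES) * len(TABLE3_VOLUMES)
        if len(frame) != expected:
            raise ValueError(f"table 3 has {len(frame)} rows, expected {expected}")
    return ReferenceTable(table_id=table_id, data=frame, meta=meta)


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of every packaged data file (fixture-integrity contract)."""
    out = {}
    data_dir = files("betadose.data")
    for entry in sorted(data_dir.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".csv"):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out


def table3_phi_dataset(nuclide: str, energy_mode: str = "spectrum") -> PhiDataset:
    """The 12 (rho, phi) points of one nuclide from the reference grid.

    ``rho`` is the generalized radius recomputed from shape class + volume;
    ``energy_mode`` selects the full-spectrum or mean-energy column.
    """
    from .geometry import generalized_radius, semi_axes_for

    if energy_mode not in ("spectrum", "mean"):
        raise ValueError(f"energy_mode must be 'spectrum' or 'mean', got {energy_mode!r}")
    frame = load_fixture(3).data
    rows = frame[frame["nuclide"] == nuclide]
    if rows.empty:
        raise KeyError(f"nuclide {nuclide!r} not in the reference grid")
    col = f"phi_{energy_mode}"
    unc = f"unc_{energy_mode}"
    rho = np.array(
        [
            generalized_radius(semi_axes_for(shape, vol))
            for shape, vol in zip(rows["shape"], rows["volume_cm3"])
        ]
    )
    labels = tuple(
        f"{shape}/{vol:g}cm3" for shape, vol in zip(rows["shape"], rows["volume_cm3"])
    )
    return PhiDataset(
        rho=rho,
        phi=rows[col].to_numpy(dtype=float),
        sigma_phi=rows[unc].to_numpy(dtype=float),
        labels=labels,
    )


@dataclass(frozen=True)
class SyntheticPhiSpec:
    """Generator settings for synthetic absorbed-fraction datasets."""

    s: float
    rho0: float
    p: float
    rho_grid: np.ndarray
    noise_sigma: float = 0.0  # multiplicative Gaussian, as a fraction
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.rho_grid, dtype=float)
        if np.any(grid <= 0.0):
            raise ValueError("rho grid must be positive")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "rho_grid", grid)

    @property
    def true_params(self) -> PhiModelParams:
        return PhiModelParams(self.s, self.rho0, self.p, provenance="synthetic-truth")


def generate_synthetic_phi(spec: SyntheticPhiSpec) -> PhiDataset:
    """Noisy observations ``phi_i = clip(phi(rho_i) (1 + eps_i), tiny, 1]``.

    ``eps_i ~ N(0, noise_sigma^2)`` with a fixed seed; regeneration with the
    same spec is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    truth = phi(spec.rho_grid, spec.true_params)
    eps = rng.normal(0.0, spec.noise_sigma, size=spec.rho_grid.shape) if spec.noise_sigma else 0.0
    noisy = np.clip(truth * (1.0 + eps), np.finfo(float).tiny, 1.0)
    sigma = spec.noise_sigma * truth if spec.noise_sigma else None
    return PhiDataset(rho=spec.rho_grid, phi=noisy, sigma_phi=sigma)
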