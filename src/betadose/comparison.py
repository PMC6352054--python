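"""Deviation statistics between absorbed-fraction / dose tabulations.

Two conventions coexist in the dosimetry literature and both are provided
under distinct names:

* ``sigma_absolute``: 100 x (value - reference), an absolute difference in
  percent-points (used for validation tables of absorbed fractions, where
  the quantities compared are themselves fractions);
* ``percent_rel_diff``: 100 x (value - reference) / reference, the ordinary
  relative percent difference (used for spectrum-vs-mean absorbed fraction
  comparisons and dose comparisons).

``sweep_extrema`` scans a table of comparison records for the extreme
absolute deviation, which is how headline agreement figures are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ComparisonRecord",
    "sigma_absolute",
    "percent_rel_diff",
    "sweep_extrema",
    "table2_records",
    "table3_records",
    "table5_records",
    "table6_records",
]


def sigma_absolute(value: float, reference: float) -> float:
    """Absolute deviation in percent-points: ``100 (value - reference)``."""
    return 100.0 * (value - reference)


def percent_rel_diff(value: float, reference: float) -> float:
    """Relative percent difference: ``100 (value - reference) / reference``."""
    if reference == 0.0:
        raise ZeroDivisionError("reference must be nonzero for a relative difference")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class ComparisonRecord:
    """One (this-work, reference) pair with both deviation statistics."""

    label: str
    value: float
    reference: float
    sigma_abs: float
    rel_pct: float

    @classmethod
    def make(cls, label: str, value: float, reference: float) -> "ComparisonRecord":
        return cls(
            label=label,
            value=value,
            reference=reference,
            sigma_abs=sigma_absolute(value, reference),
            rel_pct=percent_rel_diff(value, reference),
        )


def sweep_extrema(
    records: Sequence[ComparisonRecord],
    statistic: str = "rel_pct",
    mode: str = "max_abs",
) -> tuple[float, str]:
    """Extremum of |statistic| over a table of records.

    Returns ``(|statistic| at the extremum, label)``; ties broken by first
    occurrence in table order.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record table")
    if statistic not in ("sigma_abs", "rel_pct"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if mode not in ("max_abs", "min_abs"):
        raise ValueError(f"unknown mode {mode!r}")
    pick = max if mode == "max_abs" else min
    best = pick(records, key=lambda r: abs(getattr(r, statistic)))
    return abs(getattr(best, statistic)), best.label


# ---------------------------------------------------------------------------
# record builders over the packaged reference tables
# ---------------------------------------------------------------------------

def table2_records() -> list[ComparisonRecord]:
    """Y-90 sphere validation: this-work phi vs previously published phi."""
    from .fixtures import load_fixture

    frame = load_fixture(2).data
    return [
        ComparisonRecord.make(
            label=f"Y-90 {row.energy_mode} r={row.radius_cm:g}cm V={row.volume_cm3:g}cm3 vs {row.reference_source}",
            value=row.phi_this_work,
            reference=row.phi_reference,
        )
        for row in frame.itertuples()
    ]


def table3_records() -> list[ComparisonRecord]:
    """Spectrum-energy phi vs mean-energy phi, all nuclides/shapes/volumes."""
    from .fixtures import load_fixture

    frame = load_fixture(3).data
    return [
        ComparisonRecord.make(
            label=f"{row.nuclide} {row.shape} {row.volume_cm3:g}cm3",
            value=row.phi_spectrum,
            reference=row.phi_mean,
        )
        for row in frame.itertuples()
    ]


def table5_records(volume: float | None = None) -> list[ComparisonRecord]:
    """Spectrum-integrated dose vs the mono-energetic-parameterization doses.

    ``volume`` restricts to one of the tabulated volumes (cm^3).
    """
    from .fixtures import load_fixture

    frame = load_fixture(5).data
    if volume is not None:
        frame = frame[frame["volume_cm3"] == volume]
        if frame.empty:
            raise ValueError(f"no reference rows at volume {volume!r} cm^3")
    return [
        ComparisonRecord.make(
            label=f"{row.nuclide} {row.volume_cm3:g}cm3",
            value=row.dose_this_study,
            reference=row.dose_amato,
        )
        for row in frame.itertuples()
    ]


def table6_records(comparison: str = "this_study") -> list[ComparisonRecord]:
    """Doses vs the OLINDA/EXM sphere model (this study or the prior model)."""
    from .fixtures import load_fixture

    frame = load_fixture(6).data
    frame = frame[frame["comparison"] == comparison]
    if frame.empty:
        raise ValueError(f"unknown comparison {comparison!r}")
    return [
        ComparisonRecord.make(
            label=f"{row.nuclide} {row.volume_cm3:g}cm3",
            value=row.dose,
            reference=row.dose_olinda,
        )
        for row in frame.itertuples()
    ]
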