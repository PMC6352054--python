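"""Ellipsoid geometry for self-absorption targets.

Targets are axis-aligned ellipsoids of soft tissue specified either by their
semi-axes ``(a, b, c)`` in cm or by a shape class (sphere, prolate, oblate)
plus a volume.  The quantity that organizes absorbed-fraction systematics is
the *generalized radius* ``rho = 3 V / S``: three times the volume-to-surface
ratio, which reduces to the radius for a sphere.

The surface area of a general ellipsoid has no elementary closed form; the
Thomsen approximation

    S ~= 4 pi [ ((a b)^q + (a c)^q + (b c)^q) / 3 ]^(1/q),   q = 1.6075

is accurate to ~1.1% worst case and is used throughout.  An adaptive
quadrature of the exact surface integral is provided as an oracle for tests.

Note on symbols: the Thomsen exponent is called ``SURFACE_EXPONENT_Q`` here to
avoid collision with the absorbed-fraction model's outer exponent ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate

__all__ = [
    "SURFACE_EXPONENT_Q",
    "SHAPE_CLASSES",
    "InvalidGeometryError",
    "Ellipsoid",
    "ellipsoid_volume",
    "ellipsoid_surface",
    "surface_quadrature",
    "generalized_radius",
    "semi_axes_for",
]

#: Thomsen surface-approximation exponent (dimensionless).
SURFACE_EXPONENT_Q = 1.6075

#: Supported shape classes and their fixed axis ratios (a : b : c).
#: prolate has one long axis (a = b = c/2); oblate one short axis (a = b = 2c).
SHAPE_CLASSES = {
    "sphere": (1.0, 1.0, 1.0),
    "prolate": (1.0, 1.0, 2.0),
    "oblate": (2.0, 2.0, 1.0),
}


class InvalidGeometryError(ValueError):
    """Raised for non-positive semi-axes or volumes."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with semi-axes ``a``, ``b``, ``c`` in cm."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise InvalidGeometryError(
                    f"semi-axis {name}={value!r} must be positive and finite"
                )

    @property
    def is_sphere(self) -> bool:
        return self.a == self.b == self.c


def ellipsoid_volume(shape: Ellipsoid) -> float:
    """Volume ``(4/3) pi a b c`` in cm^3."""
    return 4.0 / 3.0 * math.pi * shape.a * shape.b * shape.c


def ellipsoid_surface(shape: Ellipsoid) -> float:
    """Thomsen approximate surface area in cm^2 (exact for a sphere)."""
    q = SURFACE_EXPONENT_Q
    ab, ac, bc = shape.a * shape.b, shape.a * shape.c, shape.b * shape.c
    return 4.0 * math.pi * (((ab**q) + (ac**q) + (bc**q)) / 3.0) ** (1.0 / q)


def surface_quadrature(shape: Ellipsoid, rel_tol: float = 1e-8) -> float:
    """Exact surface area by adaptive quadrature (test oracle, cm^2).

    Integrates the first fundamental form over the parametric angles:
    ``S = int_0^pi int_0^2pi |r_theta x r_phi| dphi dtheta`` with
    ``r = (a sin t cos f, b sin t sin f, c cos t)``.
    """
    a, b, c = shape.a, shape.b, shape.c

    def integrand(phi: float, theta: float) -> float:
        st, ct = math.sin(theta), math.cos(theta)
        sp, cp = math.sin(phi), math.cos(phi)
        inner = (
            (b * c * st * cp) ** 2
            + (a * c * st * sp) ** 2
            + (a * b * ct) ** 2
        )
        return st * math.sqrt(inner)

    value, _ = integrate.dblquad(
        integrand, 0.0, math.pi, 0.0, 2.0 * math.pi,
        epsabs=0.0, epsrel=rel_tol,
    )
    return value


def generalized_radius(shape: Ellipsoid) -> float:
    """Generalized radius ``rho = 3 V / S`` in cm (equals R for a sphere)."""
    return 3.0 * ellipsoid_volume(shape) / ellipsoid_surface(shape)


def semi_axes_for(kind: str, volume: float) -> Ellipsoid:
    """The unique ellipsoid of a shape class with the requested volume (cm^3).

    The class fixes the axis ratios up to one scale factor ``t``:
    ``V = (4/3) pi (r_a r_b r_c) t^3`` is solved for ``t`` analytically.
    """
    if kind not in SHAPE_CLASSES:
        raise InvalidGeometryError(
            f"unknown shape class {kind!r}; expected one of {sorted(SHAPE_CLASSES)}"
        )
    if not (volume > 0.0) or not math.isfinite(volume):
        raise InvalidGeometryError(f"volume {volume!r} must be positive and finite")
    ra, rb, rc = SHAPE_CLASSES[kind]
    t = (volume / (4.0 / 3.0 * math.pi * ra * rb * rc)) ** (1.0 / 3.0)
    return Ellipsoid(ra * t, rb * t, rc * t)
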