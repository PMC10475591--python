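"""Spherical shell geometry and incompressible centrosymmetric kinematics.

The left ventricle is idealised as a thick-walled sphere. Lengths are
normalised by the endocardial radius of the stress-free reference
configuration, and cavity volumes by the reference cavity volume ``V0``.
A material point is identified by its normalised depth ``delta`` in the
wall, ``delta = (R - R_endo)/R_endo in [0, Delta]``, where ``Delta`` is the
normalised wall thickness.

Because the wall is incompressible and the deformation centrosymmetric,
the whole kinematic state at a depth is determined by the normalised
cavity volume ``v_hat = V/V0``:

* deformed normalised radius  ``r_hat**3 = (1 + delta)**3 + v_hat - 1``
* radial stretch              ``lambda_rho = (1 + delta)**2 / r_hat**2``
* tangential stretch          ``lambda_theta = r_hat / (1 + delta)``
* first invariant             ``I1 = lambda_rho**2 + 2/lambda_rho``

with ``lambda_rho * lambda_theta**2 = 1`` holding identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "ShellGeometry",
    "DeformationPoint",
    "normalized_radius",
    "radial_stretch",
    "tangential_stretch",
    "first_invariant",
]


@dataclass(frozen=True)
class ShellGeometry:
    """Reference geometry of the spherical ventricle wall.

    Parameters
    ----------
    delta_wall : float
        Normalised wall thickness ``Delta = (R_epi - R_endo)/R_endo``
        (dimensionless, > 0). A healthy human left ventricle has
        ``Delta ~ 0.27``.
    v0 : float, optional
        Reference (stress-free) cavity volume in mL. Only needed to map
        normalised volumes back to absolute mL.
    """

    delta_wall: float
    v0: float | None = None

    def __post_init__(self):
        if not self.delta_wall > 0:
            raise DomainError(f"delta_wall must be > 0, got {self.delta_wall}")
        if self.v0 is not None and not self.v0 > 0:
            raise DomainError(f"v0 must be > 0 when given, got {self.v0}")


def normalized_radius(delta, v_hat):
    """Deformed normalised radius at wall depth ``delta`` for cavity volume ratio ``v_hat``.

    Shell-volume conservation of the incompressible wall gives
    ``r_hat = ((1 + delta)**3 + v_hat - 1)**(1/3)``; at the reference
    volume (``v_hat = 1``) this reduces to ``1 + delta`` at every depth.
    """
    delta = np.asarray(delta, dtype=float)
    v_hat = np.asarray(v_hat, dtype=float)
    if np.any(delta < 0):
        raise DomainError(f"depth delta must be >= 0, got {delta}")
    radicand = (1.0 + delta) ** 3 + v_hat - 1.0
    if np.any(radicand <= 0):
        raise DomainError(
            f"non-positive radicand (1+delta)^3 + v_hat - 1 for delta={delta}, v_hat={v_hat}"
        )
    out = np.cbrt(radicand)
    return out if out.ndim else float(out)


def radial_stretch(delta, v_hat):
    """Radial stretch ``lambda_rho = (1 + delta)**2 / r_hat**2``.

    Equals 1 at the reference volume; < 1 for inflation (wall thinning),
    > 1 for deflation below the reference volume.
    """
    delta = np.asarray(delta, dtype=float)
    r_hat = np.asarray(normalized_radius(delta, v_hat))
    out = (1.0 + delta) ** 2 / r_hat**2
    return out if out.ndim else float(out)


def tangential_stretch(delta, v_hat):
    """Tangential stretch ``lambda_theta = r_hat/(1 + delta)``; equals ``lambda_rho**-0.5``."""
    delta = np.asarray(delta, dtype=float)
    r_hat = np.asarray(normalized_radius(delta, v_hat))
    out = r_hat / (1.0 + delta)
    return out if out.ndim else float(out)


def first_invariant(lambda_rho):
    """First invariant of the right Cauchy-Green tensor for this symmetry.

    ``I1 = lambda_rho**2 + 2/lambda_rho >= 3`` with equality exactly at
    the undeformed state ``lambda_rho = 1``.
    """
    lambda_rho = np.asarray(lambda_rho, dtype=float)
    if np.any(lambda_rho <= 0):
        raise DomainError(f"lambda_rho must be > 0, got {lambda_rho}")
    out = lambda_rho**2 + 2.0 / lambda_rho
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DeformationPoint:
    """Immutable kinematic state of one material point of the wall.

    Constructed from ``(delta, v_hat)`` via :meth:`from_state`; all other
    fields are derived and satisfy the incompressibility identity
    ``lambda_rho * lambda_theta**2 = 1`` to machine precision.
    """

    delta: float
    v_hat: float
    r_hat: float = field(repr=False)
    lambda_rho: float = field(repr=False)
    lambda_theta: float = field(repr=False)
    i1: float = field(repr=False)

    @classmethod
    def from_state(cls, delta: float, v_hat: float) -> "DeformationPoint":
        r = normalized_radius(delta, v_hat)
        lr = radial_stretch(delta, v_hat)
        return cls(
            delta=float(delta),
            v_hat=float(v_hat),
            r_hat=float(r),
            lambda_rho=float(lr),
            lambda_theta=float(r / (1.0 + delta)),
            i1=first_invariant(lr),
        )
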