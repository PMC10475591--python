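"""Passive and active constitutive laws of the myocardium.

Passive response: isotropic exponential strain-energy density

    Psi_p(I1) = a/(2b) * (exp(b*(I1 - 3)) - 1)          [kPa]

with stiffness-like parameter ``a`` (kPa) and dimensionless stiffening
exponent ``b``. For ``b -> 0`` the law reduces to an incompressible
neo-Hookean solid, ``Psi_p -> (a/2)(I1 - 3)``; a series branch keeps the
map ``b -> Psi_p`` continuous there.

Active response: contraction is modelled as an additive active stress
acting in the tangential plane of the wall. With the structure tensor
``H_a = I - e_r (x) e_r`` the sarcomere stretch is
``lam = sqrt(C : H_a) = sqrt(2/lambda_rho)`` and the active energy is

    Psi_a(lam) = T_a * (lam**2/2 - lambda0*lam)
               = T_a * (1/lambda_rho - lambda0*sqrt(2/lambda_rho))   [kPa]

where ``T_a`` (kPa) is the maximum active stress and
``lambda0 = l_0/l_r`` the reference sarcomere stretch, the ratio of the
smallest sarcomere length (1.58 um) to the rest length (1.85 um).

The derivative of either energy with respect to the radial stretch is
what enters the work-balance pressure integral:

    dPsi_p/dlambda_rho = a*(lambda_rho - lambda_rho**-2)*exp(b*(I1-3))
    dPsi_a/dlambda_rho = T_a*(-lambda_rho**-2
                              + (lambda0/sqrt(2))*lambda_rho**-1.5)

Substituting these into the pressure integral reproduces the closed
passive and active pressure expressions used in :mod:`pvshell.pv`; the
test suite checks both derivatives against finite differences of the
energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .geometry import first_invariant

__all__ = [
    "SARCOMERE_MIN_LENGTH_UM",
    "SARCOMERE_REST_LENGTH_UM",
    "DEFAULT_LAMBDA0",
    "PassiveLaw",
    "ActiveLaw",
    "passive_energy_density",
    "active_energy_density",
    "passive_dpsi_dlambda",
    "active_dpsi_dlambda",
]

#: Smallest and rest sarcomere lengths (micrometres).
SARCOMERE_MIN_LENGTH_UM = 1.58
SARCOMERE_REST_LENGTH_UM = 1.85

#: Default reference sarcomere stretch l_0/l_r, stored at full precision.
DEFAULT_LAMBDA0 = SARCOMERE_MIN_LENGTH_UM / SARCOMERE_REST_LENGTH_UM

# below this, the exponential law is evaluated through its small-b series
# to avoid the 0/0 of a/(2b)*(e^0 - 1)
_SMALL_B = 1e-8


@dataclass(frozen=True)
class PassiveLaw:
    """Isotropic exponential passive law with stiffness ``a`` (kPa) and exponent ``b``."""

    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0:
            raise DomainError(f"passive stiffness a must be > 0 kPa, got {self.a}")
        if self.b < 0:
            raise DomainError(f"exponential stiffening b must be >= 0, got {self.b}")


@dataclass(frozen=True)
class ActiveLaw:
    """Tangential active-stress law.

    Parameters
    ----------
    t_a : float
        Maximum active stress ``T_a`` in kPa (>= 0; 0 disables contraction).
    lambda0 : float
        Reference sarcomere stretch ``l_0/l_r`` in (0, 1). Defaults to
        1.58/1.85 ~ 0.854; the literature frequently rounds it to 0.85.
    """

    t_a: float
    lambda0: float = DEFAULT_LAMBDA0

    def __post_init__(self):
        if self.t_a < 0:
            raise DomainError(f"maximum active stress t_a must be >= 0 kPa, got {self.t_a}")
        if not 0 < self.lambda0 < 1:
            raise DomainError(f"lambda0 must lie in (0, 1), got {self.lambda0}")


def passive_energy_density(i1, law: PassiveLaw):
    """Passive strain-energy density Psi_p(I1) in kPa.

    Uses the analytic small-``b`` series (second order in ``b``) below
    b = 1e-8 so the energy is continuous in ``b`` down to the
    neo-Hookean limit.
    """
    i1 = np.asarray(i1, dtype=float)
    if np.any(i1 < 3.0 - 1e-12):
        raise DomainError(f"I1 must be >= 3 under incompressibility, got {i1}")
    x = np.maximum(i1 - 3.0, 0.0)
    if law.b < _SMALL_B:
        out = 0.5 * law.a * x * (1.0 + 0.5 * law.b * x)
    else:
        out = law.a / (2.0 * law.b) * np.expm1(law.b * x)
    return out if out.ndim else float(out)


def passive_dpsi_dlambda(lambda_rho, law: PassiveLaw):
    """dPsi_p/dlambda_rho in kPa; zero at the reference stretch lambda_rho = 1."""
    lambda_rho = np.asarray(lambda_rho, dtype=float)
    i1 = np.asarray(first_invariant(lambda_rho))
    out = law.a * (lambda_rho - lambda_rho**-2) * np.exp(law.b * (i1 - 3.0))
    return out if out.ndim else float(out)


def active_energy_density(lambda_rho, law: ActiveLaw):
    """Active strain-energy density Psi_a in kPa as a function of the radial stretch."""
    lambda_rho = np.asarray(lambda_rho, dtype=float)
    if np.any(lambda_rho <= 0):
        raise DomainError(f"lambda_rho must be > 0, got {lambda_rho}")
    out = law.t_a * (1.0 / lambda_rho - law.lambda0 * np.sqrt(2.0 / lambda_rho))
    return out if out.ndim else float(out)


def active_dpsi_dlambda(lambda_rho, law: ActiveLaw):
    """dPsi_a/dlambda_rho in kPa.

    ``T_a * (-lambda_rho**-2 + (lambda0/sqrt(2)) * lambda_rho**-1.5)``;
    changes sign at ``lambda_rho = 2/lambda0**2``, where the sarcomere
    stretch equals its reference value ``lambda0``.
    """
    lambda_rho = np.asarray(lambda_rho, dtype=float)
    if np.any(lambda_rho <= 0):
        raise DomainError(f"lambda_rho must be > 0, got {lambda_rho}")
    out = law.t_a * (-(lambda_rho**-2) + (law.lambda0 / math.sqrt(2.0)) * lambda_rho**-1.5)
    return out if out.ndim else float(out)
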